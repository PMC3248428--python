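"""Non-specific ("sticky") protein filtering and the experiment-similarity graph.

Abundant contaminants — heat-shock proteins, ribosomal proteins,
hnRNPs — co-purify in most pull-downs regardless of bait and would
otherwise dominate co-occurrence scores. They are removed from the
count matrix before scoring. Pull-down experiments are related to one
another through the Jaccard distance between their identified-protein
lists; experiments with JD below a threshold (default 0.7) are linked,
and isolated experiments are dropped from the graph.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Set

import networkx as nx

from .io import ExperimentTable, SpectralCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "apply_sticky_filter",
    "jaccard_distance",
    "build_similarity_graph",
    "derive_sticky_list",
]


def apply_sticky_filter(
    matrix: SpectralCountMatrix, sticky: Set[str] | Iterable[str]
) -> SpectralCountMatrix:
    """Drop rows whose protein id is on the sticky list.

    Sticky ids absent from the matrix are ignored (counted in the log);
    the experiment columns are untouched. Idempotent.
    """
    sticky = set(sticky)
    present = set(matrix.protein_ids)
    removed = sticky & present
    ignored = len(sticky - present)
    if ignored:
        logger.info("sticky list: %d ids not in matrix, ignored", ignored)
    logger.info("sticky filter removed %d of %d proteins", len(removed), len(present))
    out = matrix.subset_proteins(present - removed)
    if out.spc.shape[0] == 0:
        logger.warning("sticky filter removed every protein; matrix is empty")
    return out


def jaccard_distance(set_a: Set, set_b: Set) -> float:
    """``1 - |A∩B| / |A∪B|``; a metric on non-empty finite sets."""
    union = len(set_a | set_b)
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(set_a & set_b) / union


def build_similarity_graph(
    experiments: ExperimentTable, threshold: float = 0.7
) -> nx.Graph:
    """Link experiments whose protein lists have Jaccard distance < threshold.

    Nodes carry a ``list_size`` attribute; experiments without any
    qualifying edge are dropped (a node is preserved only if it has at
    least one edge).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ids = sorted(experiments.protein_sets)
    g = nx.Graph()
    for i, a in enumerate(ids):
        sa = experiments.protein_sets[a]
        for b in ids[i + 1 :]:
            sb = experiments.protein_sets[b]
            if not sa and not sb:
                continue
            jd = jaccard_distance(sa, sb)
            if jd < threshold:
                g.add_edge(a, b, jaccard_distance=jd)
    for n in g.nodes:
        g.nodes[n]["list_size"] = len(experiments.protein_sets[n])
    return g


def derive_sticky_list(
    matrix: SpectralCountMatrix, max_fraction: float = 0.5
) -> frozenset[str]:
    """Flag proteins present in more than ``max_fraction`` of experiments.

    A data-driven stand-in for a curated non-specific list; the cutoff
    is a package choice, not an established convention.
    """
    if not 0.0 < max_fraction <= 1.0:
        raise ValueError("max_fraction must be in (0, 1]")
    frac = matrix.presence.mean(axis=1)
    return frozenset(frac.index[frac > max_fraction])
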