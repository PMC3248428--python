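"""Prediction networks and complex extraction.

High-confidence predicted interactions are assembled into an
undirected network whose nodes are proteins (annotated bait or prey)
and whose edges carry a recall class against the literature. Complex
extraction keeps only edges that participate in at least one
three-node clique (triangle) — a topological proxy for densely
supported co-complex membership — and reports the connected components
of the filtered network as candidate protein complexes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .evaluation import classify_edges
from .io import ExperimentTable, ReferenceInteractions

__all__ = [
    "Complex",
    "build_network",
    "triangle_filter",
    "extract_complexes",
    "complex_overlap",
]


def build_network(
    pair_set: Iterable,
    experiments: ExperimentTable | None = None,
    known: ReferenceInteractions | None = None,
) -> nx.Graph:
    """Assemble predicted pairs into an annotated undirected graph.

    Node attribute ``role`` is ``"bait"`` for proteins used as bait in
    at least one experiment, otherwise ``"prey"``. When a reference set
    is supplied, each edge gets a ``class`` attribute in
    {recalled, indirect, novel}.
    """
    edges = sorted({tuple(sorted(p)) for p in pair_set})
    g = nx.Graph()
    g.add_edges_from(edges)
    baits = experiments.baits if experiments is not None else frozenset()
    for n in g.nodes:
        g.nodes[n]["role"] = "bait" if n in baits else "prey"
    if known is not None:
        for edge, label in zip(edges, classify_edges(edges, known)):
            g.edges[edge]["class"] = label
    return g


def triangle_filter(graph: nx.Graph) -> nx.Graph:
    """Keep only edges that belong to at least one triangle.

    Nodes left without edges are dropped. Idempotent: triangles
    survive their own filtering.
    """
    out = nx.Graph()
    for u, v, data in graph.edges(data=True):
        if not set(graph[u]).isdisjoint(set(graph[v]) - {u}):
            out.add_edge(u, v, **data)
    for n in out.nodes:
        out.nodes[n].update(graph.nodes[n])
    return out


@dataclass(frozen=True)
class Complex:
    name: str
    members: frozenset
    n_edges: int
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def extract_complexes(graph: nx.Graph, method: str = "components") -> list[Complex]:
    """Candidate complexes from a triangle-filtered prediction network.

    ``components`` (default) reports connected components of the
    triangle-filtered graph; ``k_clique`` uses 3-clique percolation,
    which splits components whose triangles do not share edges. The
    triangle filter is (re)applied first, so every returned complex
    has size >= 3 and every edge sits in a triangle. Complexes are
    ordered by size descending, then by sorted membership.
    """
    g = triangle_filter(graph)
    if method == "components":
        groups = [set(c) for c in nx.connected_components(g)]
    elif method == "k_clique":
        groups = [set(c) for c in nx.community.k_clique_communities(g, 3)]
    else:
        raise ValueError("method must be 'components' or 'k_clique'")
    groups.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    out = []
    for i, members in enumerate(groups, 1):
        sub = g.subgraph(members)
        n = len(members)
        n_edges = sub.number_of_edges()
        density = 2 * n_edges / (n * (n - 1)) if n > 1 else 0.0
        out.append(
            Complex(
                name=f"complex_{i:03d}",
                members=frozenset(members),
                n_edges=n_edges,
                density=density,
            )
        )
    return out


def complex_overlap(
    complexes: Sequence[Complex],
    reference_complexes: Mapping[str, Iterable],
    denominator: str = "predicted",
) -> pd.DataFrame:
    """Percent membership overlap between predicted and reference complexes.

    Rows are predicted complexes, columns reference complexes; each
    cell is ``100 * |A∩B| / |A|`` with A the predicted set when
    ``denominator="predicted"``, or the reference set when
    ``denominator="reference"``.
    """
    if not reference_complexes:
        raise ValueError("reference complex set is empty")
    if denominator not in ("predicted", "reference"):
        raise ValueError("denominator must be 'predicted' or 'reference'")
    ref = {name: set(members) for name, members in reference_complexes.items()}
    data = {}
    for rname, rset in sorted(ref.items()):
        col = []
        for cx in complexes:
            inter = len(cx.members & rset)
            denom = len(cx.members) if denominator == "predicted" else len(rset)
            col.append(100.0 * inter / denom if denom else 0.0)
        data[rname] = col
    return pd.DataFrame(data, index=[cx.name for cx in complexes])
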