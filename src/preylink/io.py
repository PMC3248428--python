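"""Readers, writers and the shared data model for IP-MS pull-down tables.

The canonical interchange formats are plain delimited text:

* spectral-count matrix — TSV/CSV, first column protein ids, remaining
  columns one per experiment, cells are integer spectral counts (SPC);
* molecular weights — two columns, ``protein_id`` and ``mw`` (one
  consistent unit, kDa by convention, recorded on the matrix);
* pair lists — two (optionally three, with an evidence tag) columns, or
  the SIF dialect ``a <relation> b``;
* domain annotations — one row per (protein, domain accession)
  occurrence; repeated rows mean a domain occurs more than once in the
  protein;
* networks — SIF, GraphML or an edge-list TSV with attribute columns.

Spectral counts are accepted as integers only; fractional counts (e.g.
from shared-peptide apportioning) are rejected at load time.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SpectralCountMatrix",
    "ExperimentTable",
    "DomainAnnotation",
    "ReferenceInteractions",
    "read_spc_matrix",
    "write_spc_matrix",
    "read_pair_set",
    "write_pair_set",
    "read_domain_annotation",
    "write_domain_annotation",
    "read_sticky_list",
    "write_sticky_list",
    "write_network",
    "read_network",
    "write_complexes_gmt",
]


class FormatError(ValueError):
    """A delimited input file violates the documented dialect."""


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralCountMatrix:
    """Proteins x experiments matrix of raw spectral counts.

    Parameters
    ----------
    spc
        Integer DataFrame, rows indexed by protein id, columns by
        experiment id. Zero means the protein was not identified in
        that experiment.
    mw
        Molecular weight of the largest isoform per protein, aligned
        with ``spc.index``. One consistent unit for the whole matrix.
    mw_unit
        Unit label recorded for provenance; the default is kDa.

    The derived abundance ``q = spc / mw`` normalises counts for the
    number of peptides a protein is expected to yield (an NSAF-like
    quantity, not rescaled per experiment).
    """

    spc: pd.DataFrame
    mw: pd.Series
    mw_unit: str = "kDa"

    def __post_init__(self) -> None:
        if self.spc.index.has_duplicates:
            raise FormatError("duplicate protein ids in spectral-count matrix")
        if self.spc.columns.has_duplicates:
            raise FormatError("duplicate experiment ids in spectral-count matrix")
        values = self.spc.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise FormatError("spectral counts must be integers")
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative spectral count at protein {self.spc.index[bad[0]]!r}, "
                f"experiment {self.spc.columns[bad[1]]!r}"
            )
        missing = self.spc.index.difference(self.mw.index)
        if len(missing):
            raise FormatError(
                "missing molecular weight for: " + ", ".join(map(str, missing))
            )
        mw = self.mw.reindex(self.spc.index)
        with_counts = values.sum(axis=1) > 0 if values.size else np.array([], bool)
        if values.size and (mw.to_numpy()[with_counts] <= 0).any():
            raise FormatError("non-positive molecular weight for a detected protein")
        object.__setattr__(self, "mw", mw.astype(float))

    @property
    def protein_ids(self) -> pd.Index:
        return self.spc.index

    @property
    def experiment_ids(self) -> pd.Index:
        return self.spc.columns

    @property
    def q(self) -> pd.DataFrame:
        """Abundance matrix, spectral counts divided by molecular weight."""
        return self.spc.div(self.mw, axis=0)

    @property
    def presence(self) -> pd.DataFrame:
        return self.spc.gt(0)

    def protein_set(self, experiment_id: str) -> frozenset[str]:
        col = self.spc[experiment_id]
        return frozenset(col.index[col > 0])

    def subset_proteins(self, keep: Iterable[str]) -> "SpectralCountMatrix":
        keep_idx = self.spc.index.intersection(pd.Index(keep))
        # preserve original row order
        keep_idx = self.spc.index[self.spc.index.isin(keep_idx)]
        return SpectralCountMatrix(
            self.spc.loc[keep_idx], self.mw.loc[keep_idx], self.mw_unit
        )


@dataclass
class ExperimentTable:
    """Per-experiment metadata plus the identified-protein sets.

    ``meta`` is indexed by experiment id with (at least) columns
    ``bait``, ``antibody``, ``cell_line`` and ``condition``;
    ``protein_sets`` maps each experiment id to the proteins with
    nonzero spectral count in that column.
    """

    meta: pd.DataFrame
    protein_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    META_COLUMNS = ("bait", "antibody", "cell_line", "condition")

    def __post_init__(self) -> None:
        for col in self.META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = ""

    @classmethod
    def from_matrix(
        cls, matrix: SpectralCountMatrix, meta: pd.DataFrame | None = None
    ) -> "ExperimentTable":
        if meta is None:
            meta = pd.DataFrame(index=matrix.experiment_ids.copy())
        else:
            missing = matrix.experiment_ids.difference(meta.index)
            if len(missing):
                raise FormatError(
                    "experiments without metadata: " + ", ".join(map(str, missing))
                )
            meta = meta.loc[matrix.experiment_ids].copy()
        sets = {e: matrix.protein_set(e) for e in matrix.experiment_ids}
        return cls(meta=meta, protein_sets=sets)

    @property
    def experiment_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def baits(self) -> frozenset[str]:
        vals = self.meta["bait"]
        return frozenset(v for v in vals if isinstance(v, str) and v)

    def validate_against(self, matrix: SpectralCountMatrix) -> None:
        for e in matrix.experiment_ids:
            if self.protein_sets.get(e) != matrix.protein_set(e):
                raise ValueError(f"protein_set inconsistent with matrix for {e!r}")


class DomainAnnotation:
    """Protein id -> multiset of Pfam domain accessions.

    A domain may occur more than once within the same protein, so the
    mapping stores multiplicities.
    """

    def __init__(self, mapping: Mapping[str, Mapping[str, int]] | None = None):
        self._map: dict[str, Counter] = {}
        for prot, doms in (mapping or {}).items():
            if not isinstance(prot, str) or not prot:
                raise FormatError("protein ids must be non-empty strings")
            c = Counter(dict(doms)) if not isinstance(doms, Counter) else Counter(doms)
            if any(not d for d in c):
                raise FormatError(f"empty domain accession for protein {prot!r}")
            self._map[prot] = c

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "DomainAnnotation":
        out = cls()
        for prot, dom in rows:
            out.add(prot, dom)
        return out

    def add(self, protein_id: str, domain: str, count: int = 1) -> None:
        if not protein_id:
            raise FormatError("protein ids must be non-empty strings")
        if not domain:
            raise FormatError(f"empty domain accession for protein {protein_id!r}")
        self._map.setdefault(protein_id, Counter())[domain] += count

    def domains(self, protein_id: str) -> Counter:
        """Multiset of domains for a protein; empty if unannotated."""
        return Counter(self._map.get(protein_id, Counter()))

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, DomainAnnotation) and self._map == other._map


class ReferenceInteractions:
    """Undirected, deduplicated set of identifier pairs (PPIs or DDIs)."""

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]] = (),
        evidence: Mapping[frozenset, str] | None = None,
    ):
        self._pairs: set[frozenset] = set()
        self.evidence: dict[frozenset, str] = dict(evidence or {})
        dropped = 0
        for a, b in pairs:
            if a == b:
                dropped += 1
                continue
            self._pairs.add(frozenset((a, b)))
        if dropped:
            logger.info("dropped %d self-pairs", dropped)
        self.n_self_dropped = dropped

    @property
    def pairs(self) -> frozenset:
        return frozenset(self._pairs)

    def __contains__(self, pair) -> bool:
        if isinstance(pair, frozenset):
            return pair in self._pairs
        a, b = pair
        return frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceInteractions) and self._pairs == other._pairs
        )

    def restrict_to(self, universe: Iterable[str]) -> "ReferenceInteractions":
        """Keep only pairs whose both members are in ``universe``."""
        uni = set(universe)
        kept = [tuple(p) for p in self._pairs if set(p) <= uni]
        return ReferenceInteractions(kept)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(tuple(p) for p in self._pairs)
        return g


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_spc_matrix(
    path: str | Path,
    mw_path: str | Path,
    id_map: Mapping[str, str] | None = None,
    mw_unit: str = "kDa",
) -> SpectralCountMatrix:
    """Load a spectral-count matrix and its molecular-weight table.

    ``id_map`` optionally renames protein ids at load time (e.g. a
    user-supplied cross-species mapping); unmapped ids pass through.
    """
    path, mw_path = Path(path), Path(mw_path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in df.columns:
        s = pd.to_numeric(df[col], errors="coerce")
        if s.isna().any():
            row = df.index[s.isna().argmax()]
            raise FormatError(
                f"non-numeric spectral count at protein {row!r}, experiment {col!r}"
            )
        if not np.allclose(s, np.round(s)):
            row = df.index[(~np.isclose(s, np.round(s))).argmax()]
            raise FormatError(
                f"fractional spectral count at protein {row!r}, experiment {col!r}; "
                "counts must be integers"
            )
        if (s < 0).any():
            row = df.index[(s < 0).argmax()]
            raise FormatError(
                f"negative spectral count at protein {row!r}, experiment {col!r}"
            )
        df[col] = s.astype(np.int64)
    df.index = df.index.astype(str)
    mw_df = pd.read_csv(mw_path, sep=_sep_for(mw_path))
    if mw_df.shape[1] < 2:
        raise FormatError("molecular-weight table needs two columns: id, mw")
    mw = pd.Series(
        pd.to_numeric(mw_df.iloc[:, 1]).to_numpy(),
        index=mw_df.iloc[:, 0].astype(str),
    )
    if id_map:
        df.index = pd.Index([id_map.get(i, i) for i in df.index])
        mw.index = pd.Index([id_map.get(i, i) for i in mw.index])
        mw = mw[~mw.index.duplicated()]
    return SpectralCountMatrix(spc=df, mw=mw, mw_unit=mw_unit)


def write_spc_matrix(
    matrix: SpectralCountMatrix, path: str | Path, mw_path: str | Path
) -> None:
    path, mw_path = Path(path), Path(mw_path)
    matrix.spc.to_csv(path, sep=_sep_for(path), index_label="protein_id")
    mw = matrix.mw.rename("mw").rename_axis("protein_id")
    mw.to_csv(mw_path, sep=_sep_for(mw_path))


def read_pair_set(path: str | Path) -> ReferenceInteractions:
    """Read a two/three-column pair list (TSV/CSV or SIF dialect)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    evidence: dict[frozenset, str] = {}
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep) if sep in line else line.split()
            if path.suffix.lower() == ".sif" or (
                len(fields) == 3 and not _looks_like_tag(fields[2])
            ):
                # SIF: source relation target [target...]
                if len(fields) < 3:
                    raise FormatError(f"{path.name}:{lineno}: SIF row needs 3 columns")
                for tgt in fields[2:]:
                    pairs.append((fields[0], tgt))
                continue
            if len(fields) < 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected at least two columns"
                )
            a, b = fields[0], fields[1]
            pairs.append((a, b))
            if len(fields) >= 3 and a != b:
                evidence[frozenset((a, b))] = fields[2]
    return ReferenceInteractions(pairs, evidence)


def _looks_like_tag(token: str) -> bool:
    """Heuristic: third columns that are evidence tags, not SIF targets."""
    return token.lower() in {
        "known", "predicted", "pdb", "literature", "direct", "indirect",
    } or token.isdigit()


def write_pair_set(ref: ReferenceInteractions, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    rows = sorted(tuple(sorted(p)) for p in ref)
    with open(path, "w", newline="") as fh:
        for a, b in rows:
            tag = ref.evidence.get(frozenset((a, b)))
            fh.write(sep.join((a, b) if tag is None else (a, b, tag)) + "\n")


def read_domain_annotation(path: str | Path) -> DomainAnnotation:
    path = Path(path)
    sep = _sep_for(path)
    annot = DomainAnnotation()
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2 or not fields[1]:
                raise FormatError(
                    f"{path.name}:{lineno}: expected protein_id{sep!r}domain"
                )
            annot.add(fields[0], fields[1])
    return annot


def write_domain_annotation(annot: DomainAnnotation, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        for prot in sorted(dict(annot.items())):
            for dom in sorted(annot.domains(prot).elements()):
                fh.write(f"{prot}{sep}{dom}\n")


def read_sticky_list(path: str | Path) -> frozenset[str]:
    """One protein id per line; '#' starts a comment."""
    ids = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return frozenset(ids)


def write_sticky_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(graph: nx.Graph, path: str | Path, format: str = "sif") -> None:
    """Export a network for Cytoscape and friends.

    ``sif`` writes the interaction file plus sidecar node/edge
    attribute tables; ``graphml`` is self-contained; ``tsv`` is an
    edge list with one column per edge attribute.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {NETWORK_FORMATS}")
    if format == "graphml":
        nx.write_graphml(graph, path)
        return
    edges = sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))
    if format == "tsv":
        attr_keys = sorted({k for *_, d in edges for k in d})
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", *attr_keys])
            for u, v, d in edges:
                w.writerow([u, v, *[d.get(k, "") for k in attr_keys]])
        return
    # SIF + attribute sidecars
    with open(path, "w") as fh:
        for u, v, _ in edges:
            fh.write(f"{u}\tpp\t{v}\n")
        for n in sorted(graph.nodes):
            if graph.degree(n) == 0:
                fh.write(f"{n}\n")
    edge_attr_path = path.with_suffix(path.suffix + ".edge_attrs.tsv")
    with open(edge_attr_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        attr_keys = sorted({k for *_, d in edges for k in d})
        w.writerow(["source", "target", *attr_keys])
        for u, v, d in edges:
            w.writerow([u, v, *[d.get(k, "") for k in attr_keys]])
    node_attr_path = path.with_suffix(path.suffix + ".node_attrs.tsv")
    with open(node_attr_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        attr_keys = sorted({k for _, d in graph.nodes(data=True) for k in d})
        w.writerow(["node", *attr_keys])
        for n in sorted(graph.nodes):
            d = graph.nodes[n]
            w.writerow([n, *[d.get(k, "") for k in attr_keys]])


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if len(fields) >= 3:
                    for tgt in fields[2:]:
                        g.add_edge(fields[0], tgt)
                elif len(fields) == 1:
                    g.add_node(fields[0])
        return g
    if format == "tsv":
        g = nx.Graph()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                attrs = {
                    k: v for k, v in row.items() if k not in ("source", "target") and v
                }
                g.add_edge(row["source"], row["target"], **attrs)
        return g
    raise ValueError(f"unknown network format {format!r}")


def write_complexes_gmt(complexes, path: str | Path) -> None:
    """GMT-style text: one complex per line, name then tab-separated members."""
    with open(path, "w") as fh:
        for cx in complexes:
            members = "\t".join(sorted(cx.members))
            fh.write(f"{cx.name}\t{members}\n")
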