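"""Benchmarking ranked interaction predictions against reference sets.

The tools here mirror the standard ways a ranked prediction list is
judged against literature-derived interactions:

* a GSEA-style running sum (random walk) that rises by
  ``sqrt((u - t) / t)`` on a known interaction and falls by
  ``sqrt(t / (u - t))`` otherwise, where ``u`` is the length of the
  ranked list and ``t`` the number of known interactions it contains —
  the walk ends at exactly zero by construction, and its peak
  deviation summarises how early the hits concentrate;
* ROC curves and AUC (Mann–Whitney tie convention);
* a trailing sliding-window recall (moving average of hit indicators);
* a shuffled-rank null: the same walk over randomly permuted lists.

Reference pairs are always restricted to the prediction universe
before ``t`` is counted, so recall is measured against what the data
could in principle recover.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .io import ReferenceInteractions

logger = logging.getLogger(__name__)

__all__ = [
    "RunningSumCurve",
    "RocCurve",
    "NullEnvelope",
    "hit_vector",
    "running_sum",
    "roc_auc",
    "sliding_recall",
    "shuffled_null",
    "classify_edges",
]

Pair = tuple[str, str]


def hit_vector(ranked_pairs: Sequence[Pair], known: ReferenceInteractions) -> np.ndarray:
    """Boolean indicator per rank position: is the pair a known interaction."""
    return np.fromiter((p in known for p in ranked_pairs), dtype=bool,
                       count=len(ranked_pairs))


@dataclass(frozen=True)
class RunningSumCurve:
    values: np.ndarray  # cumulative sum, one entry per rank position
    u: int  # total predictions in the ranked list
    t: int  # known interactions present in the list
    peak: float  # maximum absolute deviation (signed)
    peak_rank: int  # 1-based rank of the peak

    @property
    def final(self) -> float:
        return float(self.values[-1])


def running_sum(
    ranked_pairs: Sequence[Pair], known: ReferenceInteractions
) -> RunningSumCurve:
    """Random walk over a ranked list: up on hits, down on misses.

    Step sizes ``sqrt((u-t)/t)`` and ``-sqrt(t/(u-t))`` make the walk
    terminate at exactly zero; the peak (largest absolute excursion,
    reported with its sign) measures enrichment of hits near the top.
    """
    hits = hit_vector(ranked_pairs, known)
    u = len(hits)
    t = int(hits.sum())
    if t == 0 or t == u:
        raise ValueError(
            f"degenerate walk: t={t} of u={u}; need both hits and misses"
        )
    up = math.sqrt((u - t) / t)
    down = math.sqrt(t / (u - t))
    steps = np.where(hits, up, -down)
    values = np.cumsum(steps)
    peak_idx = int(np.argmax(np.abs(values)))
    return RunningSumCurve(
        values=values,
        u=u,
        t=t,
        peak=float(values[peak_idx]),
        peak_rank=peak_idx + 1,
    )


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(
    ranked_pairs: Sequence[Pair],
    known: ReferenceInteractions,
    scores: Sequence[float] | None = None,
) -> RocCurve:
    """ROC curve and AUC for a ranked list against known interactions.

    If ``scores`` are given, tied scores are handled by the standard
    grouping (equivalent to averaged ranks); otherwise the list order
    is taken as strict.
    """
    hits = hit_vector(ranked_pairs, known)
    if hits.all() or not hits.any():
        raise ValueError("ROC needs both known and unknown pairs in the list")
    if scores is None:
        y_score = -np.arange(len(hits), dtype=float)
    else:
        y_score = np.asarray(scores, dtype=float)
        if y_score.shape[0] != hits.shape[0]:
            raise ValueError("scores and ranked_pairs lengths differ")
    fpr, tpr, _ = _roc_curve(hits.astype(int), y_score)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def sliding_recall(
    ranked_pairs: Sequence[Pair],
    known: ReferenceInteractions,
    window: int = 2000,
) -> np.ndarray:
    """Trailing moving average of hit indicators along the ranking.

    Returns an array of shape (u, 2): rank (1-based) and the fraction
    of known interactions within the trailing window ending at that
    rank (window truncated at the list start). A window longer than
    the list yields the single full-list point.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hits = hit_vector(ranked_pairs, known).astype(float)
    u = len(hits)
    if window > u:
        warnings.warn(
            f"window {window} exceeds list length {u}; returning one full-list point",
            stacklevel=2,
        )
        return np.array([[u, hits.mean() if u else 0.0]])
    csum = np.concatenate(([0.0], np.cumsum(hits)))
    ranks = np.arange(1, u + 1)
    starts = np.maximum(0, ranks - window)
    recall = (csum[ranks] - csum[starts]) / (ranks - starts)
    return np.column_stack([ranks, recall])


@dataclass(frozen=True)
class NullEnvelope:
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_shuffles: int


def shuffled_null(
    ranked_pairs: Sequence[Pair],
    known: ReferenceInteractions,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> NullEnvelope:
    """Running-sum null distribution from rank-shuffled lists.

    The hit/miss labels are permuted ``n_shuffles`` times (seeded) and
    the walk recomputed; returns the pointwise mean and min/max
    envelope.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible nulls")
    hits = hit_vector(ranked_pairs, known)
    u = len(hits)
    t = int(hits.sum())
    if t == 0 or t == u:
        raise ValueError("degenerate walk: need both hits and misses")
    up = math.sqrt((u - t) / t)
    down = math.sqrt(t / (u - t))
    rng = np.random.default_rng(seed)
    total = np.zeros(u)
    lo = np.full(u, np.inf)
    hi = np.full(u, -np.inf)
    labels = hits.copy()
    for _ in range(n_shuffles):
        rng.shuffle(labels)
        walk = np.cumsum(np.where(labels, up, -down))
        total += walk
        np.minimum(lo, walk, out=lo)
        np.maximum(hi, walk, out=hi)
    return NullEnvelope(mean=total / n_shuffles, lo=lo, hi=hi, n_shuffles=n_shuffles)


def classify_edges(
    pairs: Sequence[Pair], known: ReferenceInteractions
) -> list[str]:
    """Label each predicted pair against the known interaction graph.

    ``recalled`` — the pair is a known direct interaction; ``indirect``
    — not direct, but the two proteins share a neighbour (a path of
    length two) in the known graph; ``novel`` — neither.
    """
    g = known.to_graph()
    labels = []
    for a, b in pairs:
        if (a, b) in known:
            labels.append("recalled")
        elif (
            a in g
            and b in g
            and not set(g[a]).isdisjoint(g[b])
        ):
            labels.append("indirect")
        else:
            labels.append("novel")
    return labels
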