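"""Prey-prey interaction scoring from aggregated spectral counts.

Four complementary scores are computed for every unordered pair of
prey proteins (A, B) across a collection of pull-down experiments:

* **Sørensen** — set overlap of the experiments where each protein is
  present, ``2|M_AB| / (|M_A| + |M_B|)``; purely presence/absence.
* **Pearson** — correlation of the abundance profiles (Q = SPC/MW)
  across all experiments, zeros included.
* **E3** — per experiment j where both proteins are detected,
  ``(SPC_Aj + SPC_Bj) / (|rank_Aj - rank_Bj| + 1)`` with ranks by
  descending SPC among the proteins detected in that experiment;
  averaged over experiments. Rewards pairs sitting high, and close in
  rank, on the same lists. The ``+1`` in the denominator keeps the
  ratio finite when the two proteins tie in rank.
* **AB** — ``mean_j(SPC_Aj * SPC_Bj) / (mean_j SPC_Aj + mean_j SPC_Bj)``;
  a co-abundance product normalised by overall abundance.

Each base score can be combined multiplicatively with the Sørensen
coefficient (Pearson is affinely mapped to [0, 1] first so the product
stays monotone). Pairs whose score is undefined (protein never
detected, zero-variance profile, both profiles all-zero) are excluded
from a method's ranking rather than imputed.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import SpectralCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "sorensen",
    "pearson",
    "e3",
    "ab_correlation",
    "score_all_pairs",
    "add_ranks",
    "combine_with_sorensen",
    "top_fraction_intersection",
    "pair_key",
]

METHODS = ("sor", "pr", "e3", "ab")

_COMBINABLE = ("e3", "ab", "pr")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically sorted."""
    return (a, b) if a <= b else (b, a)


def _spc_row(matrix: SpectralCountMatrix, p: str) -> np.ndarray:
    return matrix.spc.loc[p].to_numpy(dtype=float)


def sorensen(matrix: SpectralCountMatrix, a: str, b: str) -> float:
    """Sørensen–Dice overlap of the experiment sets where A and B appear."""
    if a == b:
        raise ValueError("self-pairs are not scored")
    pa = _spc_row(matrix, a) > 0
    pb = _spc_row(matrix, b) > 0
    na, nb = int(pa.sum()), int(pb.sum())
    if na == 0 or nb == 0:
        return math.nan
    return 2.0 * int((pa & pb).sum()) / (na + nb)


def pearson(matrix: SpectralCountMatrix, a: str, b: str) -> float:
    """Pearson correlation of the two abundance (SPC/MW) profiles."""
    if a == b:
        raise ValueError("self-pairs are not scored")
    qa = matrix.q.loc[a].to_numpy(dtype=float)
    qb = matrix.q.loc[b].to_numpy(dtype=float)
    if qa.std() == 0 or qb.std() == 0:
        return math.nan
    return float(np.corrcoef(qa, qb)[0, 1])


def e3(
    matrix: SpectralCountMatrix,
    a: str,
    b: str,
    denominator: str = "all",
    use_abundance: bool = False,
) -> float:
    """Rank-proximity-weighted co-abundance, averaged over experiments.

    ``denominator="all"`` divides the summed per-experiment terms by
    the total number of experiments (experiments lacking either protein
    contribute zero but still count); ``"cooccurring"`` divides by the
    number of experiments where both are detected.
    """
    if a == b:
        raise ValueError("self-pairs are not scored")
    if denominator not in ("all", "cooccurring"):
        raise ValueError("denominator must be 'all' or 'cooccurring'")
    values = (matrix.q if use_abundance else matrix.spc).to_numpy(dtype=float)
    counts = matrix.spc.to_numpy()
    ia = matrix.protein_ids.get_loc(a)
    ib = matrix.protein_ids.get_loc(b)
    total = 0.0
    n_co = 0
    for j in range(values.shape[1]):
        if counts[ia, j] <= 0 or counts[ib, j] <= 0:
            continue
        present = counts[:, j] > 0
        ranks = rankdata(-values[present, j], method="min")
        rank_of = dict(zip(np.flatnonzero(present), ranks))
        total += (values[ia, j] + values[ib, j]) / (
            abs(rank_of[ia] - rank_of[ib]) + 1
        )
        n_co += 1
    if denominator == "cooccurring":
        return total / n_co if n_co else 0.0
    n_exp = values.shape[1]
    return total / n_exp if n_exp else 0.0


def ab_correlation(
    matrix: SpectralCountMatrix, a: str, b: str, use_abundance: bool = False
) -> float:
    """Mean SPC product over experiments, normalised by the summed mean SPCs."""
    if a == b:
        raise ValueError("self-pairs are not scored")
    values = matrix.q if use_abundance else matrix.spc
    va = values.loc[a].to_numpy(dtype=float)
    vb = values.loc[b].to_numpy(dtype=float)
    denom = va.mean() + vb.mean()
    if denom == 0:
        return math.nan
    return float((va * vb).mean() / denom)


# ---------------------------------------------------------------------------
# all-pairs scoring (vectorised)
# ---------------------------------------------------------------------------


def score_all_pairs(
    matrix: SpectralCountMatrix,
    methods: Sequence[str] = METHODS,
    min_cooccurrence: int = 1,
    e3_denominator: str = "all",
    use_abundance: bool = False,
) -> pd.DataFrame:
    """Score every unordered prey pair with the requested methods.

    Returns a DataFrame with columns ``protein_a``, ``protein_b``
    (lexicographically ordered within each row), ``cooccurrence``, one
    column per method, and a ``rank_<method>`` column per method
    (rank 1 = best; undefined scores get no rank). Only pairs detected
    together in at least ``min_cooccurrence`` experiments are kept.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if min_cooccurrence < 1:
        raise ValueError("min_cooccurrence must be >= 1")
    n, m = matrix.spc.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 proteins and 2 experiments to score pairs")

    counts = matrix.spc.to_numpy(dtype=float)
    present = counts > 0
    cooc = present.astype(np.int64) @ present.astype(np.int64).T

    score_mats: dict[str, np.ndarray] = {}
    if "sor" in methods:
        occ = present.sum(axis=1).astype(float)
        denom = occ[:, None] + occ[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            sor = 2.0 * cooc / denom
        sor[(occ == 0)[:, None] | (occ == 0)[None, :]] = np.nan
        score_mats["sor"] = sor
    if "pr" in methods:
        q = matrix.q.to_numpy(dtype=float)
        std = q.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.corrcoef(q) if n > 1 else np.ones((1, 1))
        pr[(std == 0)[:, None] | (std == 0)[None, :]] = np.nan
        score_mats["pr"] = pr
    if "ab" in methods:
        values = matrix.q.to_numpy(dtype=float) if use_abundance else counts
        means = values.mean(axis=1)
        prod = (values @ values.T) / m
        denom = means[:, None] + means[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ab = prod / denom
        ab[denom == 0] = np.nan
        score_mats["ab"] = ab
    if "e3" in methods:
        values = matrix.q.to_numpy(dtype=float) if use_abundance else counts
        acc = np.zeros((n, n))
        for j in range(m):
            idx = np.flatnonzero(present[:, j])
            if idx.size < 2:
                continue
            v = values[idx, j]
            r = rankdata(-v, method="min").astype(float)
            terms = (v[:, None] + v[None, :]) / (
                np.abs(r[:, None] - r[None, :]) + 1.0
            )
            acc[np.ix_(idx, idx)] += terms
        if e3_denominator == "cooccurring":
            with np.errstate(divide="ignore", invalid="ignore"):
                e3_mat = np.where(cooc > 0, acc / np.maximum(cooc, 1), 0.0)
        elif e3_denominator == "all":
            e3_mat = acc / m
        else:
            raise ValueError("e3_denominator must be 'all' or 'cooccurring'")
        score_mats["e3"] = e3_mat

    iu, ju = np.triu_indices(n, k=1)
    keep = cooc[iu, ju] >= min_cooccurrence
    iu, ju = iu[keep], ju[keep]
    ids = matrix.protein_ids.to_numpy(dtype=object)
    a_ids, b_ids = ids[iu], ids[ju]
    swap = a_ids > b_ids
    a_ids, b_ids = np.where(swap, b_ids, a_ids), np.where(swap, a_ids, b_ids)
    table = pd.DataFrame(
        {
            "protein_a": a_ids,
            "protein_b": b_ids,
            "cooccurrence": cooc[iu, ju],
        }
    )
    for meth in methods:
        table[meth] = score_mats[meth][iu, ju]
        n_undef = int(table[meth].isna().sum())
        if n_undef:
            logger.info("%s: %d pairs with undefined score excluded from ranking",
                        meth, n_undef)
    add_ranks(table, list(methods))
    first = methods[0]
    table = table.sort_values(
        [f"rank_{first}", "protein_a", "protein_b"],
        na_position="last",
    ).reset_index(drop=True)
    return table


def add_ranks(table: pd.DataFrame, methods: Sequence[str]) -> None:
    """Attach ``rank_<m>`` columns in place: score descending, ties broken
    by lexicographic pair id; undefined scores are left unranked (NaN)."""
    order_key = list(zip(table["protein_a"], table["protein_b"]))
    for meth in methods:
        s = table[meth]
        idx = np.lexsort(
            (
                [k[1] for k in order_key],
                [k[0] for k in order_key],
                -s.fillna(-np.inf).to_numpy(),
            )
        )
        ranks = np.full(len(table), np.nan)
        pos = 1
        for i in idx:
            if not math.isnan(s.iat[i]):
                ranks[i] = pos
                pos += 1
        table[f"rank_{meth}"] = ranks


def combine_with_sorensen(table: pd.DataFrame, base_method: str) -> pd.DataFrame:
    """Multiply a base score by the Sørensen coefficient and re-rank.

    Pearson is first mapped to ``(pr + 1) / 2`` so the combined score
    is monotone in both factors. Adds columns ``<base>_x_sor`` and
    ``rank_<base>_x_sor``; returns the same table.
    """
    if base_method not in _COMBINABLE:
        raise ValueError(f"base_method must be one of {_COMBINABLE}")
    if "sor" not in table.columns or base_method not in table.columns:
        raise ValueError("table must carry both the base method and 'sor' scores")
    base = table[base_method]
    if base_method == "pr":
        base = (base + 1.0) / 2.0
    col = f"{base_method}_x_sor"
    table[col] = base * table["sor"]
    add_ranks(table, [col])
    return table


def top_fraction_intersection(
    tables: Mapping[str, tuple[pd.DataFrame, str]] | Sequence[tuple[pd.DataFrame, str]],
    fraction: float,
) -> set[frozenset]:
    """Pairs ranked in the top ``fraction`` of *every* scored table.

    ``tables`` maps a label (or just sequences) to ``(table,
    score_column)``. All tables must cover the same pair universe.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(tables, Mapping):
        items = list(tables.values())
    else:
        items = list(tables)
    if not items:
        raise ValueError("need at least one scored table")
    universes = [
        frozenset(
            frozenset(p) for p in zip(t["protein_a"], t["protein_b"])
        )
        for t, _ in items
    ]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("scored tables cover different pair universes")
    result: set[frozenset] | None = None
    for t, col in items:
        k = math.ceil(fraction * len(t))
        sub = t.sort_values(
            [col, "protein_a", "protein_b"],
            ascending=[False, True, True],
            na_position="last",
        ).head(k)
        top = {frozenset(p) for p in zip(sub["protein_a"], sub["protein_b"])}
        result = top if result is None else result & top
    return result or set()
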