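"""Domain-domain interaction (DDI) scoring from predicted prey-prey PPIs.

A predicted PPI between proteins A and B with score *s* is propagated
to the Pfam domain pairs it could be mediated by: every unordered pair
``(d_a, d_b)`` with ``d_a`` from A's domain multiset and ``d_b`` from
B's receives a share of *s*. With the default normalisation the share
is ``s * m_a * m_b / (|D_A| * |D_B|)``, where ``m_a``/``m_b`` are the
multiplicities of the domains and ``|D_A|``/``|D_B|`` count domains
with multiplicity; each PPI thus distributes exactly its own score
over the domain pairs it supports. Setting ``normalize=False``
assigns the raw ``s * m_a * m_b`` instead.

Alongside the propagated score, the λ index counts, per domain pair,
how many predicted PPIs present that pair on opposite sides, score
regardless. λ can be folded into a ranking multiplicatively
(``ddi_score * λ``), which favours domain pairs supported by many
independent protein pairs over pairs riding on a single high-scoring
PPI.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import DomainAnnotation

logger = logging.getLogger(__name__)

__all__ = ["score_ddis", "combine_ddi_rankings"]


def score_ddis(
    ppi_table: pd.DataFrame,
    annot: DomainAnnotation,
    score_col: str,
    top_fraction: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Propagate PPI scores onto domain pairs.

    ``ppi_table`` is a scored pair table (``protein_a``, ``protein_b``
    and a score column). Only the top ``top_fraction`` of PPIs by
    ``score_col`` contribute (default: all with a defined score).
    Proteins without annotation contribute nothing.

    Returns a DataFrame with ``domain_a``, ``domain_b`` (sorted within
    the row), ``ddi_score``, ``lam`` (the λ support count) and
    ``n_support``, ranked by ``ddi_score`` descending.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if score_col not in ppi_table.columns:
        raise ValueError(f"no column {score_col!r} in PPI table")
    scored = ppi_table.dropna(subset=[score_col])
    if top_fraction < 1.0:
        k = math.ceil(top_fraction * len(scored))
        scored = scored.sort_values(
            [score_col, "protein_a", "protein_b"],
            ascending=[False, True, True],
        ).head(k)

    ddi_score: dict[tuple[str, str], float] = {}
    lam: dict[tuple[str, str], int] = {}
    support: dict[tuple[str, str], set] = {}
    n_unannotated = 0
    for a, b, s in zip(scored["protein_a"], scored["protein_b"], scored[score_col]):
        da = annot.domains(a)
        db = annot.domains(b)
        if not da or not db:
            n_unannotated += 1
            continue
        na = sum(da.values())
        nb = sum(db.values())
        seen_pairs = set()
        for dom_a, mult_a in da.items():
            for dom_b, mult_b in db.items():
                key = (dom_a, dom_b) if dom_a <= dom_b else (dom_b, dom_a)
                w = float(s) * mult_a * mult_b
                if normalize:
                    w /= na * nb
                ddi_score[key] = ddi_score.get(key, 0.0) + w
                seen_pairs.add(key)
        for key in seen_pairs:
            lam[key] = lam.get(key, 0) + 1
            support.setdefault(key, set()).add((a, b))
    if n_unannotated:
        logger.info("%d PPIs skipped: missing domain annotation", n_unannotated)

    keys = sorted(ddi_score)
    table = pd.DataFrame(
        {
            "domain_a": [k[0] for k in keys],
            "domain_b": [k[1] for k in keys],
            "ddi_score": [ddi_score[k] for k in keys],
            "lam": [lam[k] for k in keys],
            "n_support": [len(support[k]) for k in keys],
        }
    )
    table = _rank_ddi(table, "ddi_score")
    return table


def _rank_ddi(table: pd.DataFrame, col: str, out_col: str = "rank") -> pd.DataFrame:
    table = table.sort_values(
        [col, "domain_a", "domain_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table[out_col] = np.arange(1, len(table) + 1)
    return table


def combine_ddi_rankings(
    tables: Mapping[str, pd.DataFrame],
    use_lambda: bool = False,
) -> pd.DataFrame:
    """Aggregate per-method DDI tables into one ranking.

    Each method's effective score is ``ddi_score`` (times λ when
    ``use_lambda``); per-method ranks are averaged and the combined
    table is ordered by mean rank (ties broken lexicographically by
    domain pair). All tables must cover the same domain-pair universe.
    """
    if not tables:
        raise ValueError("need at least one DDI table")
    methods = sorted(tables)
    keyed: dict[str, pd.DataFrame] = {}
    universe = None
    for meth in methods:
        t = tables[meth].copy()
        t["_key"] = list(zip(t["domain_a"], t["domain_b"]))
        uni = frozenset(t["_key"])
        if universe is None:
            universe = uni
        elif uni != universe:
            raise ValueError("DDI tables cover different domain-pair universes")
        eff = t["ddi_score"] * t["lam"] if use_lambda else t["ddi_score"]
        t["_eff"] = eff
        t = t.sort_values(
            ["_eff", "domain_a", "domain_b"], ascending=[False, True, True]
        ).reset_index(drop=True)
        t[f"rank_{meth}"] = np.arange(1, len(t) + 1)
        keyed[meth] = t.set_index("_key")

    base = keyed[methods[0]][["domain_a", "domain_b", "lam"]].copy()
    for meth in methods:
        base[f"ddi_score_{meth}"] = keyed[meth]["ddi_score"]
        base[f"rank_{meth}"] = keyed[meth][f"rank_{meth}"]
    base["mean_rank"] = base[[f"rank_{m}" for m in methods]].mean(axis=1)
    base = base.sort_values(
        ["mean_rank", "domain_a", "domain_b"]
    ).reset_index(drop=True)
    base["combined_rank"] = np.arange(1, len(base) + 1)
    return base
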