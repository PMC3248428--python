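"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (set enumeration,
textbook formulas, nested loops) without reusing the package's code
paths, so agreement is a real cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations


def sorensen_bf(spc: dict[str, list[int]], a: str, b: str) -> float:
    """2|M_AB| / (|M_A| + |M_B|) by direct set enumeration."""
    m = len(next(iter(spc.values())))
    ma = {j for j in range(m) if spc[a][j] > 0}
    mb = {j for j in range(m) if spc[b][j] > 0}
    if not ma or not mb:
        return math.nan
    return 2 * len(ma & mb) / (len(ma) + len(mb))


def pearson_closed_form(x: list[float], y: list[float]) -> float:
    """cov(x, y) / (sigma_x * sigma_y) from the textbook definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    sx = math.sqrt(sum((xi - mx) ** 2 for xi in x) / n)
    sy = math.sqrt(sum((yi - my) ** 2 for yi in y) / n)
    if sx == 0 or sy == 0:
        return math.nan
    return cov / (sx * sy)


def pearson_bf(spc: dict[str, list[int]], mw: dict[str, float], a: str, b: str) -> float:
    qa = [c / mw[a] for c in spc[a]]
    qb = [c / mw[b] for c in spc[b]]
    return pearson_closed_form(qa, qb)


def _ranks_desc_min(values: list[int]) -> list[int]:
    """Competition ('min') ranks for descending order: rank 1 = largest."""
    return [1 + sum(1 for w in values if w > v) for v in values]


def e3_bf(spc: dict[str, list[int]], a: str, b: str,
          denominator: str = "all") -> float:
    m = len(spc[a])
    total = 0.0
    n_co = 0
    for j in range(m):
        if spc[a][j] <= 0 or spc[b][j] <= 0:
            continue
        present = [p for p in spc if spc[p][j] > 0]
        vals = [spc[p][j] for p in present]
        ranks = dict(zip(present, _ranks_desc_min(vals)))
        total += (spc[a][j] + spc[b][j]) / (abs(ranks[a] - ranks[b]) + 1)
        n_co += 1
    if denominator == "cooccurring":
        return total / n_co if n_co else 0.0
    return total / m


def ab_bf(spc: dict[str, list[int]], a: str, b: str) -> float:
    m = len(spc[a])
    mean_prod = sum(x * y for x, y in zip(spc[a], spc[b])) / m
    denom = sum(spc[a]) / m + sum(spc[b]) / m
    if denom == 0:
        return math.nan
    return mean_prod / denom


def triangle_edges_bf(nodes: list, edges: set[frozenset]) -> set[frozenset]:
    """Edges in >=1 triangle, by exhaustive O(n^3) triple enumeration."""
    kept = set()
    for a, b, c in combinations(nodes, 3):
        ab, bc, ca = frozenset((a, b)), frozenset((b, c)), frozenset((c, a))
        if ab in edges and bc in edges and ca in edges:
            kept |= {ab, bc, ca}
    return kept


def lambda_bf(ppis: list[tuple[str, str]],
              annot: dict[str, list[str]]) -> dict[frozenset, int]:
    """Count, per unordered domain pair, the PPIs presenting it on
    opposite sides; direct incidence enumeration."""
    out: dict[frozenset, int] = {}
    for a, b in ppis:
        da = annot.get(a, [])
        db = annot.get(b, [])
        seen = set()
        for x in da:
            for y in db:
                seen.add(frozenset((x, y)))
        for key in seen:
            out[key] = out.get(key, 0) + 1
    return out


def auc_mannwhitney(scores: list[float], labels: list[bool]) -> float:
    """AUC as the Mann-Whitney U statistic normalisation with averaged
    ranks for ties (computed from scratch)."""
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    ranks = [0.0] * len(scores)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    rank_sum_pos = sum(r for r, is_pos in zip(ranks, labels) if is_pos)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)
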