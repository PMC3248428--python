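"""Synthetic IP-MS pull-down generator with planted ground truth.

The generator emulates the structure of a large antibody pull-down
compendium: a proteome is partitioned into disjoint protein complexes
(the planted ground truth), antibodies target a bait within one
complex — and sometimes cross-react with one or two fixed off-target
complexes — and each experiment reports a protein list of roughly
30–200 identifications with a heavy upper tail. In each IP the
antibody's antigens (intended target and any cross-reaction partners)
compete: each is pulled independently, so an off-target complex can be
captured instead of, rather than always alongside, the intended one.
Members of each pulled complex are captured with a configurable
probability and given spectral counts
from a gamma–Poisson (negative-binomial) model scaled by a per-protein
lognormal abundance factor; sticky contaminants appear in most
experiments at moderate counts; the remaining list slots are filled by
random low-count background proteins.

Domains are assigned so that each planted complex carries one
compatible domain pair split across its members, giving a ground-truth
DDI per complex; every protein additionally receives decoy domains.

What this emulates: co-occurrence structure, count noise, antibody
cross-reactivity and contaminant background. What it does not:
peptide-level identification, protein inference ambiguity, shared
subunits between complexes, or condition-dependent remodelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (
    DomainAnnotation,
    ExperimentTable,
    ReferenceInteractions,
    SpectralCountMatrix,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "degrade"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the pull-down simulator.

    The defaults describe the reference condition used throughout the
    test suite: 1,000 proteins, 40 disjoint complexes of 3–25 members,
    200 experiments reporting 30–200 proteins each (2% of experiments
    draw a 3x longer list to emulate the heavy tail), capture
    probability 0.8, 30 sticky contaminants present in 80% of
    experiments, and 30% of antibodies cross-reacting with one or two
    off-target complexes.
    """

    seed: int
    n_proteins: int = 1000
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (3, 25)
    n_experiments: int = 200
    list_size_range: tuple[int, int] = (30, 200)
    heavy_tail_fraction: float = 0.02
    heavy_tail_multiplier: float = 3.0
    capture_probability: float = 0.8
    background_rate: float = 1.0
    n_sticky: int = 30
    sticky_rate: float = 0.8
    n_antibodies: int = 100
    antibody_crossreact_probability: float = 0.3
    target_pull_probability: float = 0.9
    offtarget_pull_probability: float = 0.4
    spc_dispersion: float = 0.5
    depth_sigma: float = 0.5
    mean_member_spc: float = 30.0
    mw_range: tuple[float, float] = (20.0, 250.0)
    n_decoy_domains: int = 200

    def __post_init__(self) -> None:
        probs = {
            "heavy_tail_fraction": self.heavy_tail_fraction,
            "capture_probability": self.capture_probability,
            "sticky_rate": self.sticky_rate,
            "antibody_crossreact_probability": self.antibody_crossreact_probability,
            "target_pull_probability": self.target_pull_probability,
            "offtarget_pull_probability": self.offtarget_pull_probability,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, rng_ in (
            ("complex_size_range", self.complex_size_range),
            ("list_size_range", self.list_size_range),
            ("mw_range", self.mw_range),
        ):
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, got {rng_}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ValueError("n_proteins and n_experiments must be positive")
        if self.spc_dispersion <= 0:
            raise ValueError("spc_dispersion must be > 0")
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic compendium."""

    complexes: list[frozenset]
    true_ppis: set = field(default_factory=set)  # frozenset pairs
    true_ddis: set = field(default_factory=set)  # frozenset domain pairs
    sticky: frozenset = frozenset()
    bait_by_experiment: dict = field(default_factory=dict)
    pulled_complexes_by_experiment: dict = field(default_factory=dict)

    def true_ppi_reference(self) -> ReferenceInteractions:
        return ReferenceInteractions(tuple(p) for p in self.true_ppis)

    def true_ddi_reference(self) -> ReferenceInteractions:
        return ReferenceInteractions(tuple(p) for p in self.true_ddis)


def _within_complex_pairs(members: Iterable[str]) -> set:
    mem = sorted(members)
    return {
        frozenset((mem[i], mem[j]))
        for i in range(len(mem))
        for j in range(i + 1, len(mem))
    }


def generate(
    config: GeneratorConfig,
) -> tuple[SpectralCountMatrix, ExperimentTable, DomainAnnotation, GroundTruth]:
    """Simulate a pull-down compendium under ``config``.

    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = np.array([f"P{i:04d}" for i in range(n)], dtype=object)

    # planted complexes: disjoint blocks of the proteome
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    if sizes.sum() + config.n_sticky > n:
        raise ValueError(
            "n_proteins too small for the requested complexes and sticky list"
        )
    complexes: list[frozenset] = []
    cursor = 0
    for s in sizes:
        complexes.append(frozenset(proteins[cursor : cursor + s]))
        cursor += int(s)
    sticky = frozenset(proteins[cursor : cursor + config.n_sticky])
    member_of = {}
    for ci, members in enumerate(complexes):
        for p in members:
            member_of[p] = ci

    # per-protein nuisance parameters
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    mw = rng.uniform(*config.mw_range, size=n)

    # antibodies: a fixed intended bait plus, for cross-reacting
    # antibodies, one or two fixed secondary antigens (arbitrary
    # proteins; pulling one captures its complex if it has one)
    # designed panel: antibodies cover the complexes round-robin, so
    # every planted complex is the intended target of a similar number
    # of antibodies (as in a deliberately assembled antigen panel)
    antibody_target = np.arange(config.n_antibodies) % config.n_complexes
    antibody_bait = {}
    antibody_off = {}
    for ab in range(config.n_antibodies):
        target_members = sorted(complexes[antibody_target[ab]])
        antibody_bait[ab] = target_members[rng.integers(0, len(target_members))]
        off: list[int] = []
        if rng.random() < config.antibody_crossreact_probability:
            n_off = int(rng.integers(1, 3))
            off = list(rng.integers(0, n, size=n_off))
        antibody_off[ab] = off

    cell_lines = ("HeLa", "MCF7", "HEK293", "U2OS")
    conditions = ("untreated", "stimulated")

    spc = np.zeros((n, config.n_experiments), dtype=np.int64)
    meta_rows = []
    truth = GroundTruth(complexes=complexes, sticky=sticky)
    for members in complexes:
        truth.true_ppis |= _within_complex_pairs(members)

    prot_index = {p: i for i, p in enumerate(proteins)}
    lo_l, hi_l = config.list_size_range
    for j in range(config.n_experiments):
        # experiments cycle over the antibody panel (scheduled coverage,
        # not random draws)
        ab = j % config.n_antibodies
        # antigens are pulled independently per IP: the intended target
        # with high probability (optimised affinity), cross-reaction
        # partners less reliably; an off-target antigen brings down its
        # complex only if it belongs to one
        antigen_probs = [(antibody_bait[ab], config.target_pull_probability)] + [
            (str(proteins[i]), config.offtarget_pull_probability)
            for i in antibody_off[ab]
        ]
        pulled_antigens = [p for p, prob in antigen_probs
                           if rng.random() < prob]
        pulled: list[int] = []
        lone_antigens: list[str] = []
        for p in pulled_antigens:
            ci = member_of.get(p)
            if ci is not None:
                if ci not in pulled:
                    pulled.append(ci)
            else:
                lone_antigens.append(p)
        target_size = int(rng.integers(lo_l, hi_l + 1))
        if rng.random() < config.heavy_tail_fraction:
            target_size = int(target_size * config.heavy_tail_multiplier)
        # per-run spectral depth: total MS/MS yield varies between IPs
        # and counts are not rescaled per experiment downstream
        depth = rng.lognormal(mean=0.0, sigma=config.depth_sigma)

        present_idx: list[int] = []
        for ci in pulled:
            for p in sorted(complexes[ci]):
                if rng.random() < config.capture_probability:
                    present_idx.append(prot_index[p])
        for p in lone_antigens:
            if prot_index[p] not in present_idx:
                present_idx.append(prot_index[p])
        for i in present_idx:
            mean = config.mean_member_spc * abundance[i] * depth
            lam = rng.gamma(shape=1.0 / config.spc_dispersion,
                            scale=mean * config.spc_dispersion)
            spc[i, j] = 1 + rng.poisson(lam)

        for p in sorted(sticky):
            if rng.random() < config.sticky_rate:
                i = prot_index[p]
                spc[i, j] = 1 + rng.poisson(5.0 * abundance[i] * depth)
                present_idx.append(i)

        n_fill = int(round(config.background_rate
                           * max(0, target_size - len(present_idx))))
        if n_fill > 0:
            free = np.setdiff1d(
                np.arange(n), np.array(present_idx, dtype=int), assume_unique=False
            )
            if free.size:
                weights = abundance[free]
                weights = weights / weights.sum()
                chosen = rng.choice(free, size=min(n_fill, free.size),
                                    replace=False, p=weights)
                for i in chosen:
                    spc[i, j] = 1 + rng.poisson(1.0 * depth)

        exp_id = f"E{j:04d}"
        meta_rows.append(
            {
                "experiment_id": exp_id,
                "bait": antibody_bait[ab],
                "antibody": f"AB{ab:03d}",
                "cell_line": cell_lines[j % len(cell_lines)],
                "condition": conditions[j % len(conditions)],
            }
        )
        truth.bait_by_experiment[exp_id] = antibody_bait[ab]
        truth.pulled_complexes_by_experiment[exp_id] = tuple(pulled)

    meta = pd.DataFrame(meta_rows).set_index("experiment_id")
    matrix = SpectralCountMatrix(
        spc=pd.DataFrame(spc, index=pd.Index(proteins, name="protein_id"),
                         columns=meta.index.copy()),
        mw=pd.Series(mw, index=pd.Index(proteins, name="protein_id")),
    )
    experiments = ExperimentTable.from_matrix(matrix, meta)

    # domains: one compatible pair per complex, split across members,
    # plus shared decoys everywhere
    annot = DomainAnnotation()
    for ci, members in enumerate(complexes):
        da, db = f"PFC{2 * ci:04d}", f"PFC{2 * ci + 1:04d}"
        truth.true_ddis.add(frozenset((da, db)))
        for k, p in enumerate(sorted(members)):
            annot.add(p, da if k % 2 == 0 else db)
    for p in proteins:
        for _ in range(int(rng.integers(1, 3))):
            annot.add(p, f"PFD{int(rng.integers(0, config.n_decoy_domains)):04d}")

    return matrix, experiments, annot, truth


def degrade(
    truth: GroundTruth, fraction: float, seed: int
) -> ReferenceInteractions:
    """Random subsample of the true PPI set, emulating incomplete
    literature knowledge. Each pair is kept independently with
    probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = sorted(tuple(sorted(p)) for p in truth.true_ppis)
    kept = [p for p in pairs if rng.random() < fraction]
    return ReferenceInteractions(kept)
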