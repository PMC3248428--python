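# Methods

## Problem setting

An immunoprecipitation–mass-spectrometry (IP-MS) pull-down reports a
list of identified proteins with semi-quantitative spectral counts
(SPC): the intended bait, co-complex members, cross-reaction products
and abundant contaminants, typically a few dozen to a few hundred
proteins per experiment. A single pull-down cannot distinguish direct
binding from co-membership or contamination, but across many
experiments with different baits, proteins that belong to the same
complex reappear together — and near the top of the same lists —
far more often than chance. `preylink` scores every unordered pair of
*prey* proteins across a compendium of such experiments, deliberately
ignoring which bait was intended: antibody cross-reactivity makes
bait–prey assignment unreliable, while prey–prey co-occurrence is
robust to it.

## Data model

The substrate is a proteins × experiments matrix of raw integer
spectral counts, plus per-protein molecular weights (largest isoform,
one consistent unit, kDa by convention). The derived abundance
`Q = SPC / MW` normalises a protein's count for the number of peptides
it can yield — an NSAF-like quantity that is deliberately *not*
rescaled per experiment. Counts are accepted as integers only;
fractional counts from shared-peptide apportioning are rejected at
load time so silent unit mix-ups surface early.

Before scoring, proteins on a "non-specific" (sticky) list — heat-shock
proteins, ribosomal proteins, hnRNPs and similar contaminants that
co-purify with most baits — are removed. The curated list is an input;
a frequency-based helper (`derive_sticky_list`, flag proteins present
in more than a fraction *f* of experiments, default 0.5) is provided as
a convenience and is not an established convention.

Experiments are related to each other by the Jaccard distance between
their identified-protein sets; pairs with JD < 0.7 (default) are
linked and experiments with no link are dropped from the similarity
graph. The keep-edge rule (strictly below the threshold) is the
operational one.

## Pair scores

For proteins A, B with per-experiment counts `SPC_Aj`, let `M_A` be
the set of experiments where A is detected (`SPC > 0`).

* **Sørensen** `Sor = 2|M_A ∩ M_B| / (|M_A| + |M_B|)` ∈ [0, 1].
  Pure presence/absence overlap.
* **Pearson** `Pr = corr(Q_A, Q_B)` over *all* experiments, zeros
  included, on the abundance scale.
* **E3**: in each experiment *j* where both are detected,
  `e3_j = (SPC_Aj + SPC_Bj) / (|rank_Aj − rank_Bj| + 1)`, where ranks
  are assigned by descending SPC among the proteins detected in that
  experiment (competition/"min" ranking for ties, rank 1 = highest);
  the final score averages `e3_j` over all experiments, experiments
  lacking either protein contributing zero. The `+1` in the
  denominator keeps the term finite when the two proteins tie in
  rank; it is a reconstruction choice, as is the rank convention.
  An alternative averaging denominator (co-occurring experiments
  only) is exposed as `e3_denominator="cooccurring"`.
* **AB** `= mean_j(SPC_Aj·SPC_Bj) / (mean_j SPC_Aj + mean_j SPC_Bj)`,
  a co-abundance product normalised by overall abundance; zero iff
  the pair never co-occurs.

E3 and AB are stated on raw counts and Pearson on abundance; a
`use_abundance` switch lets E3/AB run on `Q` instead for exploration.
Pairs are scored only if they co-occur in at least
`min_cooccurrence` experiments (default 1). Undefined scores (a
protein detected nowhere, a zero-variance abundance profile, two
all-zero count rows) are excluded from that method's ranking rather
than imputed. All rankings break ties by score descending, then
lexicographic pair id, so they are reproducible.

Each base score can be combined with Sørensen multiplicatively,
`base × Sor`, with Pearson first mapped affinely to [0, 1] via
`(Pr + 1)/2` so the product is monotone in both factors. Multiplication
is the simplest combiner with the intended annihilation property (a
pair that never co-occurs is killed regardless of its base score).
Note that a multiplicative combination blends two rankings: it helps
when the factors fail in complementary ways (the motivating case —
quantitative scores corrupted by count artifacts that leave
presence/absence intact) and it can cost a little accuracy in regimes
where the base score alone is already near-perfect and Sørensen
carries no extra information. The synthetic reference condition below
is such a regime: there, combined scores trail their base scores by
0.001–0.04 AUC rather than improving on them.

## Domain-pair (DDI) scoring

A predicted PPI (A, B) with score *s* is propagated to Pfam domain
pairs: with `D_A`, `D_B` the domain multisets of A and B (a domain may
occur more than once per protein; `|D_A|` counts multiplicity), every
unordered pair `(d_a, d_b)` receives `s·m_a·m_b / (|D_A|·|D_B|)`.
This conserves mass — each PPI distributes exactly *s* — making
contributions comparable across proteins with different domain
counts; `normalize=False` assigns raw `s·m_a·m_b` instead. Domain
pairs shared by both sides produce homodomain entries `(d, d)`, which
are retained. The λ index counts, per domain pair, how many predicted
PPIs present it on opposite sides, score regardless. Rankings from
several methods are aggregated by mean rank; `use_lambda`
multiplies each method's score by λ first. On the synthetic reference
data λ-weighting *lowers* DDI AUC (≈0.97 → 0.88), because widely
shared decoy domains accumulate incidence counts; with real Pfam
annotations, where promiscuous domains also mediate real
interactions, the balance can differ.

## Evaluation

Reference interactions are first restricted to pairs whose both
members occur in the prediction universe; that restricted count is
the only defensible recall denominator.

* **Running sum**: walking down the ranked list, the statistic rises
  by `√((u−t)/t)` on a known interaction and falls by `√(t/(u−t))`
  otherwise (`u` = list length, `t` = known interactions in the
  list). The step sizes balance exactly, so every walk ends at zero;
  the peak deviation and its rank summarise how early hits
  concentrate. Shuffled-rank nulls (label permutations, seeded)
  provide the mean curve and min/max envelope.
* **ROC / AUC** via the standard curve construction; tied scores are
  handled by score grouping, equivalent to the Mann–Whitney
  averaged-rank convention (verified in tests against an independent
  rank-sum computation).
* **Sliding recall**: trailing moving average of the hit indicator
  (window 2000 by default, truncated at the list start). Trailing
  rather than centred, preserving the "performance up to rank r"
  reading.
* **Edge classes**: a predicted pair is *recalled* if it is a known
  direct interaction, *indirect* if the two proteins share a
  neighbour in the known graph (path of length two), else *novel*.

## Networks and complexes

The top fraction (default 10%) of pairs ranked by *every* combined
method forms the global prediction network, nodes annotated
bait/prey and edges by recall class. For complex extraction the cut
is tightened to the top 1% by all methods and edges not participating
in any three-node clique (triangle) are discarded; candidate
complexes are the connected components of the triangle-filtered
graph, reported with size and density and every edge guaranteed to
sit in a triangle. Components are the minimal faithful reading of
"cliques grouped into complexes"; a 3-clique-percolation mode is
available where finer granularity is wanted (it splits components
whose triangles share no edge). Percent overlap against reference
complex sets is reported in both orientations (predicted-set and
reference-set denominators).

## Synthetic compendium

The generator plants disjoint complexes (40 complexes of 3–25
members by default) in a 1,000-protein proteome and simulates 200
experiments with list sizes 30–200 (2% of lists are drawn 3× longer,
emulating the heavy upper tail of real pull-downs). Its design
choices, with defaults and rationale:

* **Antibody panel**: 100 antibodies cover the complexes round-robin
  (a designed antigen panel, not random draws — every planted complex
  is deliberately targeted), each with a fixed bait subunit;
  experiments cycle over the panel. 30% of antibodies additionally
  cross-react with one or two fixed secondary antigens drawn from the
  whole proteome; a secondary antigen brings down its complex only if
  it belongs to one.
* **Capture**: in each IP the intended antigen is pulled with
  probability 0.9 and each cross-reaction antigen with probability
  0.4 (optimised vs incidental affinity), independently — so an
  off-target complex can be captured instead of, not only alongside,
  the intended one. Members of a pulled complex are each captured
  with probability 0.8.
* **Counts**: gamma–Poisson (negative binomial, dispersion 0.5) with
  mean 30 × a per-protein lognormal abundance factor (σ = 0.5) × a
  per-experiment lognormal depth factor (σ = 0.5). The depth factor
  models run-to-run variation in total spectral yield, which is not
  rescaled away downstream.
* **Contaminants**: 30 sticky proteins appear in 80% of experiments
  at moderate counts; remaining list slots are filled with random
  low-count background proteins weighted by abundance.
* **Domains**: each complex carries one compatible domain pair split
  alternately across its members (the ground-truth DDI); every
  protein also receives 1–2 decoy domains from a shared pool of 200.
* **Molecular weights**: uniform 20–250 kDa.

Ground truth (complex memberships, implied within-complex PPIs,
planted DDIs, sticky list, per-experiment pulls) is returned
alongside the data; `degrade` subsamples the true PPI set to emulate
incomplete literature knowledge.

What passing tests on this generator do show: the scoring equations,
combination, evaluation machinery and clique pipeline recover planted
co-complex structure through realistic capture noise, count
dispersion, depth variation, cross-reactivity and contamination. What
they do not show: performance on real compendia with shared subunits
between complexes, condition-dependent remodelling, correlated
contamination, repeated near-identical experiments, or protein
inference ambiguity — none of which are simulated. In particular, in
this synthetic regime presence/absence is the dominant signal, so the
quantitative scores are individually stronger, relative to Sørensen,
than they are on real data.

## Numerical choices and degenerate inputs

* Ranks everywhere are deterministic (score desc, lexicographic pair
  id tiebreak); rank columns are contiguous over defined scores.
* Oracle agreement for the four scores is asserted to 1e-12 against
  nested-loop reference implementations; DDI mass conservation to
  1e-12 relative; running-sum termination to 1e-9 absolute on lists
  up to 2,000 (pure cumulative float error; ~1e-7 at 4×10⁵ ranks).
* Degenerate evaluations raise rather than guess: a walk needs both
  hits and misses, ROC needs both classes, Jaccard distance needs a
  non-empty union, all-pair scoring needs ≥2 proteins and ≥2
  experiments. An oversized sliding window degrades to the single
  full-list point with a warning.
* Pipeline reruns with the same inputs, parameters and seed are
  byte-identical; the run manifest records parameters, input hashes
  and package version (timings go to the log so the manifest itself
  is reproducible).

## Problem sizes used in the test suite

The reference condition (1,000 proteins, 200 experiments, ~4×10⁵
scored pairs) is used for end-to-end recovery checks; unit and
property tests use matrices up to 20 × 15 where brute-force oracles
are exact, random graphs up to 50 nodes for triangle enumeration, and
a 150-protein / 40-experiment compendium for pipeline integration.
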