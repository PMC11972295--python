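# Methods

This note documents the statistical models and procedures implemented in
`organotrope`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## CI encoding and exclusion rules

A chromosomal imbalance (CI) is identified by a canonical string:
sign (+/−), chromosome, arm, optional band interval (absent ⇔ whole-arm
aneuploidy), optional ` amp` suffix for a high-level amplification. The
internal matrix stores per-signed-event presence codes {0, 1, 2}; the TSV
dialect writes a present loss as −1 and a present gain as +1/+2, and the
reader additionally accepts unsigned arm columns with signed codes
(split into the two signed events) and `1` as a loss presence. A gain
column containing −1 is rejected: a sample cannot simultaneously gain and
lose the same region in a net clonal profile.

The default exclusion mask removes regions that band-level CGH cannot
score reliably: 1p32→pter, the short arms of the acrocentric chromosomes
13/14/15/21/22, bands containing `ter` (telomeric), and the constitutive
heterochromatic blocks on 1q12, 9q12, 16q11 and Yq12. Band-range rules
apply to focal events only — a whole-arm 1p loss is a reportable event
even though its distal bands are individually unreliable — while
whole-arm rules (the acrocentric short arms) drop any matching event.
Mask application is idempotent.

Per-sample counts split CIs into whole-arm aneuploidies and focal events;
a code-2 amplification counts once, as a gain. Acrocentric short-arm
events never count as aneuploidies; should a custom mask admit them they
are bucketed under `n_focal` so that `n_total = n_arm + n_focal` holds
unconditionally.

The arm-level caller for segmented copy-number input uses fixed,
documented thresholds in the style of standard arm-calling tools:
log2-ratio threshold 0.2, minimum arm coverage 0.5, minimum altered
fraction 0.7 of the covered length, and +2 when the length-weighted mean
log2 ratio of gained segments reaches 1.0. SEG coordinates are 1-based
inclusive on disk and half-open internally; arms come from merging
cytoband rows sharing an arm letter.

When a patient contributes several metastases, one is retained:
brain > lung > liver (rarer sites first), then the lesion with the fewest
CIs (closest to the minimal alteration state needed for spread), then the
lexicographically smallest sample id for determinism.

## Exact statistics

The 2×k Fisher exact test (k = 2, 3) enumerates every table with the
observed margins; the two-sided p-value sums the multivariate
hypergeometric probabilities of tables no more probable than the observed
one, within a relative tolerance of 1e−7 to absorb floating-point ties.
This "probability ≤ observed" rule is the dominant two-sided convention;
the alternative (doubling the smaller tail) is not offered. Any zero
margin gives p = 1. Benjamini–Hochberg adjustment is the usual step-up
with downward monotonization and a cap at 1. Kruskal–Wallis omnibus
p-values come from the tie-corrected chi-square approximation; Dunn
post-hoc z statistics use the pooled mean ranks with the tie-corrected
variance and two-sided normal p-values, BH-adjusted across pairs — no
exact small-sample Dunn is attempted. The log2 frequency ratio
log2(f1/f2) requires both frequencies positive; callers must apply the
minimum-occurrence filter first.

## Organotropic map

Frequencies are computed over metastases only, one lesion per patient, so
the per-site denominators are explicit. Events seen fewer than
`min_count = 3` times are dropped; sex-chromosome events are excluded
from the map by default (they remain in the data model). Each retained
event gets an omnibus 2×3 Fisher test (present/absent × site), BH across
events. For omnibus-significant events the top-frequency site s\* is
compared 2×2 against each other site, BH pooled across *all* pairwise
tests, and the enriched-site set is {s\*} plus every site not
significantly below it. This set rule is our formalization of patterns
such as "liver-and-brain enriched"; it is monotone in the evidence and
reduces to {s\*} when both other sites fall clearly below. Ternary
coordinates c_s = f_s/Σf place each event in the site simplex; the
overall frequency sets the bubble size for plotting.

## Co-occurrence model

Conditioning on both marginal counts makes the joint count hypergeometric
without any nuisance frequency parameter. Both tails include the observed
count — hence p_lt + p_gt ≥ 1 — matching the convention of probabilistic
co-occurrence models in ecology and cancer genomics; one consequence,
verified by simulation, is that the *union* rule
min(p_lt, p_gt) ≤ α rejects at up to 2α under the null, while each tail
separately is conservative. The screen therefore applies BH jointly over
both tails of all retained pairs and labels a pair by its adjusted tails.
Pairs are retained when both events occur ≥ 3 times and the expected
joint count n_a·n_b/N is ≥ 1; gain/loss pairs of the same region are
structurally exclusive under the encoding and are skipped rather than
reported as spurious avoidance. The pmf is computed in log space
(gammaln), and an algebraic identity with the three-binomial product form
is property-tested.

## Oncogenetic trees

Observed profiles are cross-sectional, so event order must be inferred
from nesting of frequencies. Marginal and joint frequencies use a 0.5
pseudocount. The initial topology is the maximum-weight spanning
arborescence (Edmonds, via networkx) of the digraph with root edges
log f_v and event→event edges log f_uv − log f_u − log f_v, restricted to
the direction from the more frequent to the less frequent event.
The generative model is then: the root is present; event v is present
with probability θ_v given its parent, absent otherwise; every observed
cell is flipped independently with ε (default 0.01). θ_v is the
conditional frequency f_{uv}/f_u clipped to 1. A deterministic
first-improvement hill-climb over single-parent reattachments (fixed scan
order, strict improvement, θ re-estimated per move) refines the topology;
the likelihood is computed by a tree-structured sum over latent presence
patterns, so each evaluation is linear in events × samples. The climb
never decreases the likelihood and stops at a local optimum.

Event timing is the root distance d_v = Σ −log θ along the root path, so
improbable transitions land "later"; the interval [0, d_max] is cut into
nine equal-width right-closed bins, class 1 earliest. With this metric a
child's class never precedes its parent's. Topological depth is offered
as an alternative (`metric="depth"`) since equal-width binning of either
quantity is defensible; the weighted form is the default. `top_k`
(default 25) restricts the model to the most frequent events of the site
subset, echoing the scale of published cohort trees.

## Patient phylogenies

Characters are binary event presences over a patient's samples plus an
all-zero normal outgroup; a high-level amplification is a separate
character on top of the base event, so `+12p` and `+12p amp` can change
on different edges. Characters may change in both directions at equal
cost — CGH profiles do show reversals. The Fitch score is minimized
exhaustively over all rooted topologies up to 8 taxa ((2t−3)!!
enumeration) and by stepwise-insertion branch and bound beyond; ties are
broken by the lexicographically smallest canonical sorted-newick string.
Event placement uses a Sankoff pass with a deterministic backtrace that
fixes the root to the normal state on ties and prefers presence at tied
child choices, which pushes ambiguous gains to the edge closest to the
root (the "earliest suggested occurrence" display convention).

Edges are segmented by the number of tumor-lineage branching nodes
strictly between the root and the edge: 0 → trunk, 1 → branches,
≥2 → sub-branches. This is our formalization of trunk/branches/
sub-branches; for a two-sample patient it yields one trunk edge and two
branch edges, with sub-branches appearing from three samples up. The CI
score of a segment is the mean timing class (from the patient's
metastasis-site tree, the default; pooled classes would also be
coherent but site-specific classes match the per-site modeling) of the
events gained on its edges; unclassified events are logged and excluded.

The trunk→sub-branch trend is tested by permutation rather than a linear
mixed model: the statistic for a segment pair is the difference of
segment means pooled across patients, and the null permutes segment
labels within each patient, preserving each patient's score set exactly.
The omnibus p uses the maximum absolute pairwise statistic; pairwise
p-values are BH-adjusted. This is assumption-light and respects the
patient as the exchangeability unit; note the null is discrete — with k
patients carrying two segments each, the smallest attainable p is about
2^−k — so the test needs a handful of multi-segment patients (a warning
fires below 5).

## Synthetic cohorts

The generator emulates the structure the analyses assume. Defaults (the
study conditions of the test suite): 200 patients; site mix
0.45/0.35/0.20 liver/lung/brain; an 18-event CRC-like true tree whose
truncal events are the classic CRC aneuploidies (−18q, +13q, +20q, −8p,
+8q, …) and whose deep events include −3q, +5q, −6q and +12p; one
metastasis sample per patient, a primary sample with probability 0.5 and
a second metastasis with probability 0.1; flip noise ε = 0.01; eight
focal noise events at rate 0.05 each. Organotropism enters as
multipliers on the post-dissemination acquisition probabilities: the nine
common events +7p, −8p, +8q, +13q, +16p, +16q, −18p, +20p, +20q are
enriched in liver (×1.5) and brain (×2.0) — brain more strongly, matching
the observed frequency ordering on shared events — and the four deep
events are brain-enriched at ×3. Products θ·m above 1 are clipped with a
warning. Per patient the primary lineage accumulates events top-down, a
dissemination index uniform over the acquisition order fixes the truncal
events, and the metastasis lineage continues acquiring with multiplied θ.
All draws flow from one seeded generator; identical seeds give
byte-identical outputs.

What the simulations do *not* emulate: breakpoint-level CGH noise,
tumor-purity effects, polyclonal seeding, site-dependent dissemination
timing, and mutation data. Passing tests therefore demonstrate that the
estimators recover the planted structure under the stated model, not that
real cohorts satisfy that model.

## Numerical and scale choices

Exact-test enumeration is vectorized over first-row compositions;
log-factorials via gammaln. Likelihood evaluations guard against
underflow at 1e−300. Hill-climb acceptance requires improvement beyond
1e−12 to avoid cycling on plateaus. Permutation p-values use the
add-one estimator (b+1)/(n+1). The acceptance script and test suite run
the default 200-patient cohort and scale calibration runs to a few
thousand null hypotheses (e.g. ~1,700 null pairs for the co-occurrence
screen, 200 trend replicates at 400–2,000 permutations each with the
documented seeds); the library default for the trend test remains
n_perm = 100,000.

## Known limitations

- The Freeman–Halton enumeration is exact but quadratic in the margins
  for 2×3 tables; cohorts of a few hundred samples per site are fine,
  biobank scales would need the network algorithm.
- The oncogenetic hill-climb finds a local optimum; the exhaustive-search
  oracle covers only small instances, and distinct topologies can be
  likelihood-equivalent when θ ≈ 1.
- Branch-and-bound parsimony is practical to roughly a dozen samples per
  patient; beyond that heuristic searches would be required.
- The enriched-site set rule depends on the pairwise BH pool, so adding
  events can in principle flip a borderline site in or out.
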