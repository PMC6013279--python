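# Methods

## Overview

`engramtrack` analyses longitudinal immediate-early-gene (IEG) imaging
experiments in which the same field of cortical neurons is imaged across
many behavioural sessions, and a short-lived fluorescent reporter marks the
cells each session recruited.  The pipeline has four stages:

1. **fluorescence** — reduce the 8 raw per-session timepoints to 4
   meta-timepoints and compute the per-cell activity readout ΔF = T3 − T1;
   utilities for synthetic image stacks (z-reduction, circular-ROI mean
   grey values) mirror the imaging workflow at desk scale.
2. **activity** — call active cells per session against a per-animal pooled
   threshold and summarise activity (percent active, active cell pool,
   condition-block collapsing).
3. **overlap** — Jaccard similarity between session ensembles, its exact
   combinatorial null and tail p-value, Fisher combination across animals,
   Bonferroni adjustment, and the normalised retention/reactivation scores.
4. **cohort** — condition clustering, maze-error scoring, error-difference
   construction and the engram-stability-versus-forgetting correlations;
   plus the synthetic-cohort generator that supplies test beds for all of
   the above.

## Activity detection

ΔF is the difference between meta-timepoints 3 and 1 (pairwise means of
raw timepoints; T3 covers 150–180 min after behaviour onset, where
IEG-driven fluorescence peaks).  All ΔF values of one animal, across cells
and sessions, are pooled; a cell is active on a session when

    ΔF > mean(pool) + 1.5 · SD(pool)   and   ΔF > 0.

Numerical conventions, fixed and tested:

* the inequality at the boundary is strict (ties are measure-zero on
  continuous data, but the convention is pinned);
* SD is the sample standard deviation (n − 1); at realistic pool sizes
  (10⁴–10⁵ values) the difference from the population SD is negligible,
  but the choice matters for bit-reproducibility;
* the positivity clause is applied explicitly even though a positive
  threshold implies it;
* all finite ΔF values are pooled, including cells that are incompletely
  tracked in some sessions (their missing sessions are simply absent);
* an all-identical pool degenerates to SD = 0 and warns.

For pure double-exponential (Laplace) noise the pooled SD is √2·s, so the
expected exceedance is 0.5·exp(−1.5√2) ≈ 5.99% — the "approximately one-
tailed 5% z-test" operating point of the 1.5-SD rule.  For Gaussian noise
the same rule admits Φ̄(1.5) ≈ 6.7%.

## The exact overlap null

With *a* and *b* active cells on two sessions and an active-cell pool of
size *t*, the number of co-active cells under random re-assignment of the
second session's active set is hypergeometric:

    P(c) = C(a, c) · C(t − a, b − c) / C(t, b),
    max(0, a + b − t) ≤ c ≤ min(a, b).

J = c/(a + b − c) is strictly increasing in c at fixed (a, b), so the
upper tail in c equals the upper tail in J; the reported p-value is the
inclusive tail P(C ≥ c_obs), which guarantees p ∈ (0, 1] and p = 1 at the
support minimum.  Binomial coefficients are evaluated through `gammaln`
and tails through `logsumexp`; naive factorials overflow near t ≈ 1000,
log-gamma is exact to ~1e−12 at any realistic pool size (verified against
exhaustive subset enumeration for all t ≤ 12, against
`scipy.stats.hypergeom` at t up to 2000, and against random-subset
Monte-Carlo simulation).

Degenerate cases: a session with zero active cells gets J = 0 and p = 1
against every partner, with a warning; such animals are excluded from that
pair's Fisher combination (they carry no overlap information and their
p = 1 would only dilute the combined statistic).  Fisher's method uses
X = −2 Σ ln pᵢ ~ χ²(2k); exact zeros are rejected (the caller must floor
them — the exact null never produces them).  A single p-value is returned
unchanged.  The family-wise threshold is α divided by the number of session
pairs, C(13, 2) = 78 for the default schedule.

## Normalised retention indices

The raw retention indices J(R2, 19) and J(R2, R1) contain a non-specific
component (chronically active cells, chance overlap) and differ in overall
scale between animals (imaging-window quality).  Both are removed by a
two-stage normalisation: divide each animal's two indices by that animal's
control index J(R2, C1); then divide all values by the single cohort
constant s = mean(stage-1 values) / mean(raw values), which returns the
normalised indices to the raw scale.  Stage 2 is a common positive factor,
so between-animal rank order is set entirely by stage 1.  Animals with
J(R2, C1) = 0 cannot be normalised and are excluded with a warning; if all
animals are excluded the pipeline reports the correlations as undefined
(NaN) rather than failing.

Reactivation scores (percentage of session-19 or R1 active cells that are
also active on R2) are chance-normalised.  The printed form of the chance
level — (a_ref/t)·(a_R2/t) — is a product of two fractions while the score
is a percentage of the reference set, which is dimensionally inconsistent.
The default convention therefore treats the score as a fraction of the
reference set and divides by the per-reference-cell chance a_R2/t, so data
at the hypergeometric expectation normalise to exactly 1.  The literal
product-of-fractions reading is also implemented
(`convention="literal"`), default-off.

## Clustering and behaviour

Conditions are clustered by between-group (average/UPGMA) linkage.  The
distance is D = 1 − J taken directly from the mean similarity matrix — the
analysis' own statistic — rather than Euclidean distance between matrix
rows; the row-Euclidean variant is available behind `metric="rows"`.
Average linkage on a fixed dissimilarity yields monotone merge heights, so
the dendrogram is ultrametric.  Newick serialisation goes through
scikit-bio's tree builder.

Maze scoring: a reference-memory (RM) error is any visit to a never-baited
arm, defined as the complement of the configured baited set (default
{2, 3, 4, 8}); a working-memory (WM) error is any re-entry into an arm
already visited within the same trial.  Error-score differences against
the reference session (training day 19, the best-performance day) are
taken in chronological order — later session minus earlier session — so
training values are negative while performance improves and retention
values are positive when the memory has degraded.  Pearson correlations
report the two-sided p from the t-distribution with n − 2 df; two-sidedness
is the conservative default since the sign of the stability–forgetting
relationship is the hypothesis under test.

## The synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes —
not the optics.  Defaults describe a cohort of 8 animals × 800 cells
imaged on 13 sessions (habituation H on day 0; training days 1, 4, 7, 10,
13, 16, 19; dark controls C1/C2 on days 22/40; retention tests R1/R2 on
days 25/43; novelty N on day 28), on an 8-bit intensity scale.

Each animal's cells split into disjoint random groups:

| group | default size | active on | probability |
|---|---|---|---|
| task ensemble | 2.5% (20 cells) | training j = 1..7 | min(1, 0.15·j) |
| | | retention | delay-scaled fidelity (below) |
| exploration ensemble | 2.5% (20) | H and early training | max(0, 0.8 − 0.18·j) |
| cage ensemble | 2% (16) | controls C1, C2 | 0.65 |
| nonspecific cells | 1.5% (12) | every session | 0.7 |
| novelty set | 1.3 × ensemble (26) | novelty N | 0.85 |
| all cells | — | every session | baseline 0.0025 |

Rationale for the three auxiliary groups:

* **cage ensemble** — the negative controls are repeated exposures to the
  same dark home-cage context, so they share a context ensemble with each
  other and with nothing else.  Without it the controls could never form
  their own similarity block: chance Jaccard overlap *grows* with the
  partner's active-set size, so two small control ensembles are closer, by
  chance alone, to training sessions than to each other.
* **exploration ensemble** — habituation and the first training days share
  the experience of exploring a novel maze before the task representation
  has formed; its decaying activation is what groups {H, 1, 4}.
* **nonspecific cells** — a chronically IEG-active subpopulation supplying
  the uniform non-specific similarity floor across all session pairs.  This
  is exactly the component the control-based normalisation of the retention
  indices is designed to divide out, and it keeps the normaliser J(R2, C1)
  away from zero.

**Reinstatement fidelity** f ∈ [0, 1] is each animal's probability that a
task-ensemble cell reactivates at the *final* retention test; earlier
retention tests interpolate linearly in elapsed time since training (R1 at
6 of 24 days: 1 − 0.25·(1 − f)), so forgetting accrues with delay and the
R2 − R1 contrast carries fidelity signal.  The default cohort spreads
fidelities evenly over [0.3, 1.0].  The emergence rate 0.15 saturates the
task-ensemble activation at 1 by training day 19, so with f = 1 and no
noise the retention active sets equal the day-19 set exactly.

**Fluorescence.**  A truly activated (cell, session) adds
`active_amplitude` (50 intensity units) to its ΔF; every (cell, session)
receives symmetric Laplace ΔF noise with scale 5, reproducing the
double-exponential pooled histogram the threshold rule assumes.  No
per-cell amplitude statistics are available for real active cells, so the
amplitude is a free parameter; 10:1 amplitude-to-scale keeps detection of
true activations near-certain (≈ 99%) while noise-only exceedance lands
near 1%, which together with the ensemble schedule puts per-session
percent-active at 3.3–5.6% (novelty highest, dark controls lowest) and the
active-cell pool near 27–30% of cells.  Raw 8-timepoint traces are
reconstructed around the meta values (the two frames of each pair sit
symmetrically about their mean, ±2-unit jitter), with T2 and T4 at 0.6 and
0.7 of the T1→T3 excursion so the mean time-course peaks at T3.  Values
are clipped to [2, 253] before jitter, so traces stay within the 8-bit
range without disturbing the pairwise means.

**Behaviour.**  Five trials per maze session; a trial ends after the four
baited arms are cleared or eight visits.  Each visit is erroneous with
probability 0.02 + 0.9·(1 − s), where the stability s is the session's
task-ensemble activation probability (training) or the animal's
delay-scaled fidelity (retention); erroneous visits head for never-baited
arms (perseverative exploration).  This couples reference errors to engram
stability: errors fall over training as the ensemble consolidates and rise
at retention in proportion to 1 − fidelity.

**Determinism.**  A single root seed; per-animal streams are derived as
`SeedSequence(seed, spawn_key=(animal,))`, so cohorts are reproducible
bit-for-bit, including under parallel per-animal generation.

**Image stacks** (optional): cells render as separable 3-D Gaussian blobs
(σ = 3 µm in x/y, 1.5 planes in z) whose peak tracks the cell's trace,
over a flat noisy background; masks are 7-µm circles at each cell's
brightest plane.  Desk-scale defaults are 256×256 px × 60 planes at the
native 400/1024 µm/px pixel size.  A warning is raised when > 5% of
cell-footprint voxels are claimed by several cells.

### What the generator does *not* emulate

No registration drift, photobleaching, head-motion artefacts, slow
baseline trends, spatially correlated noise, or anatomical structure
(cell positions are uniform, activity groups are position-independent).
Passing tests on synthetic cohorts therefore demonstrate the correctness
and statistical behaviour of the analysis under its own model assumptions
— clean tracking and exchangeable cells — not robustness to the imaging
artefacts a real registration chain must remove first.

## Problem sizes and tolerances in the test suite

Exhaustive enumeration validates the null for every (a, b, c, t) with
t ≤ 12 to 1e−12; normalisation is checked to 1e−10 over 1000 random
configurations with pools up to 2000; Monte-Carlo agreement uses 10⁵
random-subset draws per parameter set (within 3 binomial SE).  Cohort-level
structure recovery uses 50–100 independent default cohorts per test, with
recovery demanded in ≥ 90% of seeds; these sizes keep the full suite under
a minute while leaving the binomial uncertainty of the recovery rates
(≈ 2–4 percentage points) well clear of the thresholds.

## Known limitations

* Simulated animals approach a near-perfect training asymptote, so the
  first-to-last training-session error reduction (~99%) is larger than
  real mice show; only the *ordering* and fidelity-coupling of errors is
  calibrated, not their absolute floor.
* The cohort-mean similarity of late training (J ≈ 0.31–0.37) sits above
  typical in vivo values, a consequence of clean tracking and the absence
  of registration loss; the exact statistics are unaffected.
* The chance-normalised reactivation score's two conventions (see above)
  differ by the factor t/a_ref; cross-study comparisons must fix one.
* With very small cohorts (tens of cells) the control index J(R2, C1) is
  frequently zero and the normalised correlation becomes undefined; the
  pipeline warns and reports NaN.
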