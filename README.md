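# engramtrack

Tools for tracking neuronal engrams across weeks of longitudinal
immediate-early-gene (IEG) imaging.  In *Fos*-eGFP mice, a short-lived
fluorescent reporter marks recently active neurons, so repeated two-photon
imaging of the same field of view reveals which cells a behavioural episode
recruited on each day of an experiment.  `engramtrack` implements the
analysis chain for such data — from per-cell fluorescence traces to
cohort-level statements about engram stability and forgetting — together
with a synthetic-cohort generator so every stage is testable without any
imaging data.

The package is aimed at systems-neuroscience labs running longitudinal
ensemble-tracking experiments (IEG reporters, or any design that yields a
binary cells × sessions activity table) who need the overlap statistics and
meta-analysis around them.

## The analysis

**Active-cell calling.**  Eight raw images per session (15-min intervals,
90–195 min after behaviour) are averaged into four meta-timepoints T1–T4;
the activity readout is ΔF = T3 − T1, where IEG-driven fluorescence peaks.
All ΔF values of one animal are pooled — the pooled distribution is
near-symmetric double-exponential with a long positive tail — and a cell is
*active* on a session when its ΔF is positive and exceeds the pooled mean by
1.5 pooled SD (admitting ≈ 5–6% of values).  Cells active on ≥ 1 session
form the animal's *active cell pool* of size *t*.

**Similarity and its exact null.**  Two sessions with *a* and *b* active
cells and *c* co-active cells have similarity index (Jaccard)

    J = c / (a + b − c)

Holding (*a*, *b*, *t*) fixed, a random re-draw of the second session's
active set makes *c* hypergeometric:

    P(c) = C(a, c) · C(t − a, b − c) / C(t, b)

and the p-value is the inclusive upper tail P(C ≥ c_obs), computed in
log-gamma space so pools of thousands of cells are exact.  Per-animal
p-values are combined across the cohort with Fisher's method
(−2 Σ ln pᵢ ~ χ² with 2k df) and assessed at a Bonferroni-adjusted
α / C(13, 2) = α / 78.

**Cohort synthesis.**  The mean similarity matrix is clustered by
between-group (average/UPGMA) linkage on D = 1 − J; maze behaviour is scored
as reference-memory errors (visits to never-baited arms) and working-memory
errors (within-trial re-entries); and engram stability is related to
forgetting by correlating each animal's *normalised* retention similarity
— J(R2, 19) and J(R2, R1) divided by the control index J(R2, C1), then
rescaled by a single cohort constant — against the chronological error-score
difference between the final retention test and the reference session.

## Worked example

```python
from engramtrack import overlap_test, fisher_combine

test = overlap_test(set(range(40)), set(range(25, 60)), pool_size=250)
print(test.a, test.b, test.c, test.t, round(test.jaccard, 3), f"{test.p_value:.3g}")
# 40 35 15 250 0.25 3.19e-05

print(fisher_combine([0.04, 0.2, 0.008]))
# CombinedResult(p_values=(0.04, 0.2, 0.008), statistic=19.31..., df=6, p_value=0.0037...)
```

Fifteen of the 40 cells recur among the 35 active on the next session; in a
pool of 250 tracked cells that overlap (J = 0.25) would arise by chance with
probability 3 × 10⁻⁵, and three animals showing p = 0.04, 0.2 and 0.008
combine to p ≈ 0.004.

End-to-end on a synthetic cohort (8 animals × 800 cells × 13 sessions —
maze habituation H, training days 1–19, dark controls C1/C2, retention
tests R1/R2 and a novelty session N):

```python
from engramtrack import CohortConfig, generate_cohort
from engramtrack.cohort import analyze_cohort

report = analyze_cohort(generate_cohort(CohortConfig(seed=1)))
print(report.mean_similarity.loc["13", "16"])   # 0.374
print(report.mean_similarity.loc["C1", "16"])   # 0.106
print(report.dendrogram.cut(4))
# {'H': 3, '1': 3, '4': 3, '7': 2, '10': 2, '13': 2, '16': 2, '19': 2,
#  'C1': 1, 'R1': 2, 'N': 4, 'C2': 1, 'R2': 2}
print(report.correlations["r2_19"])             # (-0.67, 0.068, 8)
```

Late-training sessions are far more similar to each other (J ≈ 0.37) than
to the dark controls (J ≈ 0.11); cutting the dendrogram at four clusters
separates habituation + early training, late training + retention tests,
the two controls, and novelty; and animals whose error score rose most
between training day 19 and the final retention test show the lowest
normalised J(R2, 19) — the engram-stability/forgetting relationship
(r = −0.67 across the 8 simulated animals at this seed).

The same pipeline runs from a shell:

```bash
engramtrack all -o run/ --seed 1        # simulate → ... → report bundle
```

writing trace/behaviour/activity CSVs, per-animal and mean similarity
matrices, the Fisher/Bonferroni table, a Newick dendrogram, a similarity
heatmap and `report.json`.

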