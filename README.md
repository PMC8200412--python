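# crossomics

Paired analysis of two-period crossover multi-omics trials: whole-profile
Spearman distances, a dual paired-Wilcoxon differential screen, and
responder-score baseline-dependence diagnostics — with a ground-truth
synthetic trial generator so every stage is testable without access to any
study's raw data.

## Who this is for

Biostatisticians and microbiome/metabolome researchers analysing
randomised crossover supplementation trials: each subject takes a control
supplement in one period (samples `C1`, `C2`, `C3` at weeks 0, 2, 4) and
the test supplement in the other (`T1`–`T3`), with period order randomised
per subject and a washout in between. Measurements are taxa relative
abundances (summing to 1 per sample), metabolite relative peak areas with
detection-limit missingness, and clinical outcomes such as weekly
defecation frequency or blood folate.

## The statistics at the core

**Profile distances.** The distance between two samples is
`d = 1 − ρ_s`, one minus the Spearman rank correlation of their whole
feature profiles (0 = identical ranking, 2 = reversed). Distances between
different subjects' first samples ("inter") are compared with each
subject's own across-timepoint distances ("intra") by a Wilcoxon rank-sum
test, quantifying whether between-subject variation dominates the
intervention.

**Dual Wilcoxon screen.** After filtering (taxa with mean relative
abundance < 0.001; metabolites undetected in ≥ 75% of samples; remaining
non-detections set to 0), each feature is tested twice with the Wilcoxon
signed-rank test: T1 vs T3 paired within subjects, and the per-subject
period changes (T3 − T1) vs (C3 − C1). A feature is a *candidate* if both
raw p < α = 0.05, and *confirmed* if additionally a Benjamini–Hochberg
q-value (per layer, per test family) is < q\* = 0.10. The between-period
test guards against placebo drift; both rank tests use exact null
distributions at trial sizes (signed-rank up to m = 25 tie-free
differences by generating-function recursion, rank-sum up to n = 12 by
enumeration).

**Responder scores.** Per subject and measure,

```
R = ((T3 − T1) − (C3 − C1)) / Average(C1, T1)
```

so positive R means the test period raised the measure beyond the control
period relative to the subject's starting level. Correlating R against a
baseline factor (Spearman ρ with the t-approximation p-value,
`t = ρ√((n−2)/(1−ρ²))`) asks whether the response depends on the
subject's initial gut environment. Because a change score correlated with
its own noisy baseline is biased by regression to the mean, the package
ships a permutation diagnostic (`rtm_null`): period labels are swapped
C↔T independently per subject — valid under "no treatment effect", while
preserving the artifact's machinery — and the observed ρ is located in
the resulting null distribution.

## Worked example

The built-in six-subject fixture has hand-computable numbers. Subject S1
has defecation quadruple (C1=2, C3=3, T1=2, T3=5):

```python
>>> import crossomics as cx
>>> ds = cx.worked_fixture()
>>> rt = cx.responder_table(ds, "outcome", "defecation_frequency")
>>> dict(zip(rt.subject_ids, rt.scores.round(4)))
{'S1': 1.0, 'S2': 0.5, 'S3': 0.25, 'S4': 0.5, 'S5': -0.1667, 'S6': 0.5833}
>>> pairs = cx.extract_deltas(ds, "outcome", "defecation_frequency")
>>> cx.wilcoxon_signed_rank(pairs)
TestResult(statistic=1.0, p_value=0.0625, n_effective=6, method='exact')
```

S1's score is ((5−2) − (3−2)) / 2 = 1.0: the test period raised weekly
defecation frequency by twice the control-period change, relative to
baseline. The exact signed-rank p = 0.0625 is the smallest two-sided
p-value attainable at n = 6 — the period difference is as one-sided as six
subjects can make it.

A synthetic trial with a planted baseline-dependent effect on an abundant
metabolite (the "responders have low baselines" phenomenon):

```python
>>> import numpy as np
>>> cfg = cx.GeneratorConfig(seed=7, planted_effects=[cx.plant_baseline_dependent_scfa()])
>>> trial, truth = cx.generate_trial(cfg)
>>> rt = cx.responder_table(trial, "metabolites", "met_001")
>>> corr = cx.baseline_correlation(rt)
>>> (round(corr.rho, 3), round(corr.p, 6), corr.n)
(-0.704, 0.000535, 20)
>>> null = cx.rtm_null(rt, n_permutations=1000, seed=7)
>>> (round(null.p_two_sided, 4), round(float(np.quantile(null.null, 0.025)), 3))
(0.002, -0.478)
```

The observed ρ = −0.704 lies far below the permutation null's 2.5%
quantile (−0.478): the negative baseline correlation is stronger than
regression to the mean alone can manufacture, so the diagnostic flags a
genuinely baseline-dependent response.

The same pipeline is scriptable from the shell:

```
crossomics simulate --seed 7 --out trial/
crossomics distance --data trial/ --out results/
crossomics screen   --data trial/ --out results/
crossomics respond  --data trial/ --target outcome:blood_folate \
    --factor outcome:defecation_frequency --out results/
```

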