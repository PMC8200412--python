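# Methods

This note documents the statistical model behind `crossomics`, the
numerical choices made where the design was genuinely open, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Trial model

A two-arm, two-period crossover: every subject receives both the control
and the test supplement for four weeks each, in randomised order (arms
`CT` and `TC`), separated by a washout. Samples are labelled by supplement
period and timepoint (`C1/C2/C3`, `T1/T2/T3` at weeks 0, 2, 4 of the
respective period), independent of calendar order; all alignment runs
through sample metadata, so the arm can never change the value of an
extraction — this invariance is property-tested. Week-2 samples (`C2`,
`T2`) are carried in the data model but used only by the profile-distance
stage, which is the only analysis that consumes them.

Signs follow one convention everywhere: *later minus earlier* within a
period. The "between" contrast is (T3 − T1) vs (C3 − C1), compared as
paired differences per subject.

Missing metabolite values mean "not detected" (below the instrument
detection limit) and are kept distinct from zero at the I/O layer; they
become zeros only where an analysis needs a complete table — inside the
differential screen after the detection filter, and in the rank-distance
computation (a non-detection sits below the detection limit, hence at the
lowest rank). Taxa tables must close to 1 ± 1e-6 per sample on input;
violations raise rather than being silently renormalised. Filtered taxa
tables are sub-compositions and are deliberately *not* re-closed: the
tests are rank-based per feature, so renormalisation would only inject
spurious coupling between features.

## Statistical primitives

All primitives are implemented in the package and verified in the test
suite against independent oracles (full enumeration, definitional
formulas, and the scipy/statsmodels implementations).

* **Wilcoxon signed-rank** — zero differences are discarded before ranking
  (the classic treatment, matching the mainstream scientific stacks).
  With m ≤ 25 retained tie-free differences the exact two-sided p-value is
  computed from the distribution of W⁺ over all 2^m sign patterns
  (generating-function recursion; counts are exact in float64 since
  2²⁵ < 2⁵³). Otherwise a normal approximation with tie correction
  (−Σ(t³−t)/48 on the variance) and a 0.5 continuity correction is used.
  The crossover point is chosen so a tie-free 20-subject trial takes the
  exact path; it is configurable.
* **Wilcoxon rank-sum** — exact by enumeration of all C(n₁+n₂, n₁) group
  labelings for n₁+n₂ ≤ 12 without ties; otherwise normal approximation
  with tie and continuity corrections.
* **Spearman correlation** — Pearson on midranks; perfectly monotone
  inputs return exactly ±1; constant vectors raise rather than returning a
  silent 0. The p-value uses the Student-t approximation
  t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom at every n (it reproduces
  the printed (r, p) pairs of the emulated study to within 1%); an exact
  permutation option exists for n ≤ 10.
* **Benjamini–Hochberg** — the definitional step-up
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1, order-preserving.
* **Paired t and paired Cohen's d** — d = mean(diff)/sd(diff) with the
  n−1 sd; the confidence interval is the normal approximation
  d ± z·√(1/n + d²/2n). The CI method used for the effect sizes printed in
  the emulated study's outcome table is not stated and is not reproduced
  by this approximation; no agreement is promised there.

Two-sided tests only; no one-sided mode is exposed.

## Dual differential screen

Per layer: filter, then two signed-rank tests per feature (within: T1 vs
T3; between: the period deltas), BH-FDR within layer and within test
family (the two families are adjusted separately, matching the separate
significance statements the design is built for), candidate = both raw
p < α, confirmed = candidate and min(q) < q\*. Features with fewer than 3
usable nonzero differences are skipped with a recorded reason, never
silently dropped.

The metabolite detection filter reads "not detected in 75% of samples" as
*excluded when the undetected fraction is ≥ 0.75* — a metabolite must be
detected in more than a quarter of samples. The stricter reading (require
detection in ≥ 75%) is available via `rule="require_detected"`. The
default discards less data and exposes the threshold. The taxa abundance
filter keeps features with mean relative abundance ≥ 0.001 (boundary
inclusive), mean taken over all retained samples with missing as 0.

`direction` is the sign of the median within-period change (T3 − T1).
Note it is a within-period quantity: relabelling periods (C↔T) leaves
p_between invariant — the between statistic is symmetric — but replaces
the within-period test's target, so no direction flip is implied.

## Responder analysis and the regression-to-the-mean diagnostic

R = ((T3 − T1) − (C3 − C1)) / Average(C1, T1). Subjects with
mean(C1, T1) = 0 are excluded with a recorded reason; at least 5 valid
subjects are required. Default baseline covariate is Average(C1, T1),
consistent with the score's own denominator; `T1_only` and `C1_only` are
selectable, since "at baseline" admits all three readings. Correlations
are reported with q-values always computed alongside, but headline output
is ordered by raw p (multiple-comparison caveats are the caller's to
weigh, and the q-values are right there).

**Regression to the mean.** The choice of baseline matters more than it
looks. Writing the score numerator N = T3 − T1 − C3 + C1:

* against the `T1_only` baseline, cov(N, T1) = −var(T1) under pure noise —
  the classic negative RTM bias (a noisy-low T1 inflates the score);
* against the `mean_C1_T1` baseline the bias cancels analytically: C1
  enters N with the opposite sign, and swapping the period labels negates
  the score while fixing this baseline, so under period exchangeability
  the (score, baseline) law is symmetric and the expected correlation is
  exactly zero.

Both facts are property-tested. Because real analyses often use the
pre-test-period level ("before intake") as the baseline, the RTM
diagnostic matters: `rtm_null` swaps C↔T independently per subject — a
valid permutation under "no treatment effect", which negates the score
numerator, keeps the mean baseline fixed, and maps a T1 baseline to C1
for swapped subjects — recomputes the Spearman correlation each time, and
reports the observed ρ's attained quantile in the null. The permutation
test is exact under exchangeability up to the discreteness of the 2^n
flip group; ANCOVA-style adjustment would be the standard modelling
remedy and is deliberately out of scope.

## Synthetic generator

The generator emulates the structure the analysis assumes, with defaults
matching the emulated study's scale: 20 subjects with omics data, ~150
taxa, ~200 metabolites, 6 sampling timepoints.

* **Latent structure** — feature level for subject s, feature j:
  log x = u_sj + ε, with u_sj ~ N(0, signature_sd²) the subject signature
  (default sd 1.0) and ε ~ N(0, noise_sd²) per sample (default 0.3). All
  between-subject structure lives in the signatures; with signature sd 0
  the samples are i.i.d. and whole-profile distances are exchangeable
  between the inter and intra sets, which is what makes the null
  calibration of the distance comparison testable. An optional shared
  feature-level base profile (`taxa_base_sd`, `metabolite_base_sd`,
  default 0) adds a common rank-abundance curve; see Limitations for why
  it is off by default.
* **Taxa** — exponentiated and closed to sum 1 (closure to 1e-9 before
  I/O rounding is property-tested).
* **Metabolites** — one global detection limit at the configured quantile
  (default 0.15) of all generated values, mimicking an instrument limit
  rather than per-feature limits; values below it are recorded missing.
* **Planted effects** — multiplicative, at half strength (log scale) at
  T2 and full strength at T3. A baseline-dependent effect scales the log
  multiplier by 1/(1 + b_s/median(b)), where b_s is the subject's latent
  baseline level: full effect for low-baseline subjects, vanishing for
  high. Planted features can carry an abundance offset so an
  abundant-analyte scenario (e.g. a major SCFA) is never censored. The
  packaged `plant_baseline_dependent_scfa` scenario uses multiplier 4.0,
  set so the induced score-vs-baseline correlation magnitude matches what
  the emulated study reports for faecal propionate (ρ ≈ −0.59 at n = 20).
* **Outcomes** — weekly defecation frequency: per-subject latent mean
  (4.0 ± 1.2 stools/week) plus a placebo drift of 1.0 stools/week applied
  at timepoint 3 of *both* periods, reproducing the regime where each
  period shows a significant before/after change but the between-period
  contrast does not. Blood folate (9 ± 3 ng/ml between subjects, 0.8
  within) gains a T3 response proportional to the subject's baseline
  defecation frequency (default 2.0 ng/ml per stool/week; half at T2).
* **Randomisation** — stratified permuted blocks (default size 4) over
  age band × baseline defecation class; remainder blocks are balanced at
  their own size, so even-sized strata split exactly.
* **Determinism** — one master seed feeds independent named substreams
  (arms, subjects, taxa, metabolites, outcomes), so enlarging one layer
  never perturbs another's draws; same seed ⇒ bit-identical dataset.

What the generator does *not* emulate: realistic rank-abundance curves by
default (see below), taxon–taxon correlation structure, per-feature
detection limits, compliance/dropout, carryover effects, or week-scale
autocorrelation. Passing tests therefore demonstrate the pipeline's
statistical behaviour under the assumed structure, not performance on any
particular real dataset.

## Analysis problem sizes

Monte Carlo checks in the test suite and acceptance script use 50–200
generator seeds per property, 200–400 permutations per RTM null, and the
default trial dimensions above — sizes at which the measured quantities
(sensitivity medians, coverage fractions) are stable to a few percent.

## Limitations

* **Inter/intra distance testing on real tables.** The rank-sum test
  treats the distance lists as independent observations. When profiles
  share a common rank-abundance backbone (as real microbiome tables do,
  and as the optional base-profile knobs reproduce), each sample's own
  deviation magnitude enters every distance it participates in. The group
  means then fluctuate with roughly the number of *samples*, not the
  number of *pairs*, of freedom, and the test becomes anticonservative
  under the null. This is the standard motivation for sample-level
  permutation procedures (PERMANOVA), which are out of scope here. For
  strongly separated data the conclusion is unaffected; for borderline
  p-values on real data the inter/intra p should be read qualitatively.
* The folate–defecation coupling saturates near ρ ≈ 0.5 in the generator
  because the responder score divides by the subject's own noisy folate
  baseline; stronger printed correlations are not reproducible without
  shrinking the between-subject folate spread below the emulated study's.
* The Cohen's d confidence interval is a large-sample normal
  approximation; noncentral-t intervals are not implemented.
* No compositional transforms (CLR), zero-imputation models, linear or
  mixed-effects period adjustment, or Bayesian variants.
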