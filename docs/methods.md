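# Methods

This note documents the statistical models in `amyscreen`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Synthetic cohort model

The generator emulates a dementia-free population sample of ~70-year-olds
with concurrent amyloid PET and plasma biomarker data. Per participant it
draws, in order:

1. **PET status** ~ Bernoulli(prevalence), default 0.186.
2. **Age** ~ Normal(70.7, 0.7²) truncated to [69, 72] years (a narrow birth
   cohort); **sex** ~ Bernoulli(0.506 female).
3. **APOE ε4 carriage** ~ Bernoulli(0.573 | PET-positive; 0.220 |
   PET-negative).
4. **SUVR** from the status-specific Gaussian: negative N(0.54, 0.030²),
   positive N(0.70, 0.080²). These locations are generator conventions —
   chosen so the 99th-percentile rule lands near the conventional 0.61
   threshold — not measured values.
5. **Seven biomarkers** (Simoa Aβ40, Aβ42, p-tau181; LC-MS Aβ1-38, Aβ1-40,
   Aβ1-42, Aβ−3-40, all pg/ml) jointly log-normal within status.

Skewed assay concentrations are published as `median [q1, q3]`, so
per-status log-normal parameters are inverted exactly:
`loc = ln(median)`, `scale = (ln q3 − ln q1)/(2·z₀.₇₅)` with
z₀.₇₅ = 0.674490. This preserves the median and the quartile ratio q3/q1
exactly; for a log-asymmetric summary the individual quartiles sit at
`exp(loc ∓ z₀.₇₅·scale)`, within ~1.5% of the inputs in the worst case
(p-tau181). Ratios such as Aβ42/40 are never drawn directly — they are
always computed from the generated peptides, so ratio consistency is
structural.

**Within-status correlation.** `CohortSpec.log_correlation` is a Gaussian
copula on the latent normal scores (identity = independence, the simplest
model). The *default* cohort, however, uses an exchangeable correlation of
0.6 among the four LC-MS peptides and 0.5 between the two Simoa amyloid
peptides, for two reasons: (i) real LC-MS peptide panels are moderately
inter-correlated (published pairwise r ≈ 0.55–0.70); and (ii) independence
is inconsistent with the published *ratio* marginal — with independent
peptides the derived Aβ42/40 ratio would have log-scale
√(s₄₂² + s₄₀²) ≈ 0.28, far wider than the published ratio IQR implies
(≈ 0.16), which would also depress the ratio's discriminative performance
well below what population cohorts report. With ρ = 0.6 the generated
PET-negative ratio spread and the ratio AUC (~0.80–0.82) both match the
published neighbourhood. p-tau181 is left independent of the amyloid
peptides; its discrimination comes entirely from its status-specific
marginals.

**What the generator does not model:** longitudinal change, assay batch/CV
structure beyond the log-normal scale, cross-platform correlations (r ≈
0.19–0.41 in real data; omitted as weak), MCI/dementia adjudication, and
missing-data mechanisms. Passing tests therefore demonstrate correctness of
the *methods* under a faithful but simplified data-generating process; they
are not evidence about any particular real cohort's AUCs or cut-offs, which
are data-dependent.

## PET positivity cut-point

A two-component Gaussian mixture is fitted to SUVR by EM. Numerical
choices:

* **Initialisation**: split at the sample median, component moments from
  the two halves — deterministic given the data. A seed matters only for
  optional random restarts (default 0).
* **Convergence**: absolute log-likelihood change < 1e-8, max 1000
  iterations; non-convergence returns a flagged fit with a warning rather
  than raising. The per-iteration log-likelihood trace is retained and is
  non-decreasing (an EM guarantee, asserted in tests).
* **Variance floor**: σ ≥ 1e-6 × data range, preventing component collapse.
* **Labels**: components are reported sorted by mean; "lower" is
  positional, never label-dependent.

The cut-point is closed-form: `t = μ_lo + z(percentile)·σ_lo` (default
percentile 0.99, z = 2.326348); with the default mixture this gives
t ≈ 0.6098. Classification is `SUVR ≥ t` — the boundary is positive. At
n = 441 the EM recovers the lower component tightly: the derived cut-point
has median absolute error < 0.01 SUVR over seeded replicates (the upper,
broader component is estimated less precisely, which the cut-point does not
depend on).

## Concordance models

* **Composite score**: the LC-MS composite is the mean of the sample
  z-scores (ddof = 1) of Aβ−3-40/Aβ1-42 and Aβ1-40/Aβ1-42, standardised on
  the analysis sample, so it has sample mean 0 and rises with cerebral
  amyloid.
* **Logistic models** are maximum likelihood (Newton) via statsmodels.
  Separation is detected (statsmodels' perfect-separation signal, or
  runaway coefficients > 1e3) and reported as an unconverged, flagged model.
* **ROC/AUC**: AUC is the midrank Mann–Whitney estimate (ties count ½),
  exactly equal to pair-counting and invariant under strictly monotone
  transforms. Candidate thresholds are midpoints between adjacent distinct
  scores plus ±∞; classification puts the boundary on the positive side
  (≥ for higher-is-positive scores, ≤ for lower-is-positive ones, mirroring
  the SUVR rule). Direction handling: model-based scores go through the
  fitted probability (direction is learned); raw biomarkers take an
  explicit orientation flag (ratios are lower-is-positive).
* **DeLong test**: placement-value (structural component) covariance of the
  paired AUCs, O(n log n) via midranks; z = ΔAUC/√var, two-sided normal p.
  Identical rankings give zero variance; that degenerate case reports p = 1
  with a flag. The same variance yields the AUC 95% CI
  (AUC ± 1.96·√var, clamped to [0, 1]); the CI method for published tables
  of this kind is typically unstated, and the DeLong-variance normal
  interval was adopted here (it tracks a stratified bootstrap within ~20%
  in tests).
* **Youden cut-point**: maximises J = sens + spec − 1; ties break toward
  higher sensitivity, then the smaller threshold (deterministic output).
  Accuracy is sens·p + spec·(1−p) at the sample prevalence, which equals
  the raw agreement fraction.
* **Correlations**: Pearson on natural-log values (the composite exempt,
  being a z-score average), Bonferroni-adjusted by the number of pairs
  tested; Bonferroni is the only multiplicity adjustment offered.

## Screening economics

All quantities are solved continuously from the closed forms in the README;
integers appear only at reporting time, rounded half away from zero.
Published tables of this kind round sensitivity/specificity to one decimal
before back-calculating, so reconstructed NNS/NPS can differ from printed
values by ±2 counts (e.g. 939 vs 940, 621 vs 623); the package documents
that ±2-count (±0.2 accuracy point) reconciliation tolerance rather than
imitating any particular rounding. Two published baselines for "scans
without screening" at 18.6% prevalence (543 and 538) are themselves
inconsistent; the design equations give n/p = 537.8 → 538, which is what
this package reports. `n_target` defaults to 100 PET-positive recruits but
is a parameter. Setup costs are absorbed into the per-unit PET (x) and
blood (y) costs; the relative cost is linear and increasing in y/x, and at
y = 0 equals 1 − (fraction of scans saved).

## Pipeline

The pipeline applies a complete-case filter first (analysis tables must be
complete), derives ratio/composite columns, classifies PET status (mixture
fit, or a fixed SUVR threshold that skips the fit), then runs the
nine-model roster: a demographic base model (age + sex + APOE ε4), four
single-biomarker models, and the four biomarker models adjusted for the
base covariates. Reports carry a config hash (analysis-relevant fields
only, so the output directory does not perturb it) and are byte-identical
across reruns of the same config and seed; timestamps are deliberately kept
out of report files. The SUVR cut-off sensitivity sweep (default 0.57–0.65
by 0.01) reclassifies PET status at each threshold, recomputes the plasma
Youden cut-off, and splits discordance into plasma+/PET− and plasma−/PET+
fractions; a threshold yielding a single PET class is flagged and skipped.

## Problem sizes and determinism

Default analyses use n = 441 participants (the published analysis-sample
size); distribution-level tests use 20 seeded replicates, a 10,000-rep
bootstrap for the DeLong-variance check, 10⁶ draws for the log-normal
inversion check, and n = 10⁵ for marginal-recovery checks. All randomness
flows through `numpy.random.default_rng` seeded from explicit `seed`
parameters; identical spec + seed gives bit-identical cohorts and reports.

## Known limitations

Biomarker effect sizes are tied to the published group marginals; cohorts
with different assay platforms or age ranges will differ. The conditional
independence of p-tau181 from amyloid peptides slightly understates real
joint structure. The economics model is expectation-only (no sampling
variation in the 2×2 projection) and absorbs setup costs into per-unit
prices. The EM fit can in principle find a local optimum on pathological
inputs; random restarts are available but off by default in favour of
determinism.
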