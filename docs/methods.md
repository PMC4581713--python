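# Methods

## The estimand and the modelling pipeline

The package answers a model-comparison question: how much does adding
mammographic dense area, and then a polygenic risk score (GRS), improve a
questionnaire-based breast-cancer risk model for a mammography-screening
population of women aged 50–64? Performance is measured on each woman's
predicted 10-year absolute risk — the clinically actionable scale — via
cross-validated ROC/AUC, the Gönen–Heller concordance probability and
predictive values at fixed risk thresholds.

Because the individual-level data of the emulated screening programme are
not public, the package's synthetic-cohort generator *is* the study
population. Its defaults are fixed study conditions, not tuning knobs:
24,161 women; pooled covariate marginals of the reference population; the
fully adjusted hazard ratios of the reference analysis as generating
effects; recruitment spread uniformly over October 1994–February 1997 with
administrative censoring on 31 December 2011; a baseline rate calibrated so
the expected number of incident cases is 680.

## Synthetic cohort

**Covariates.** Eight categorical variables (age band, ethnicity, age at
menarche, age at first live birth, first-degree relatives with breast
cancer, past biopsy, BMI, mean dense area) are sampled independently from
their population marginals. Real risk factors are correlated (BMI and
density negatively, notably); no joint distribution is available to
emulate, so independence is a deliberate simplification. Consequences:
fitted coefficients still recover the generating values (the generator is
itself a proportional-hazards law in these covariates), but discrimination
can drift slightly relative to a correlated population. Variables recorded
in the reference population but absent from its risk models (education,
HRT use, parity, age at menopause) are not generated.

**Outcomes.** Event times are exponential: constant baseline hazard λ₀
(events per person-year) times exp(β′x). The reference analysis never
states a baseline shape; a constant rate makes calibration closed-form and
is defensible over a 15–17-year horizon for postmenopausal incidence.
Follow-up is censored only administratively — no competing mortality, no
loss to follow-up. Times are day-resolution (minimum 1 day), ten years is
3,652 days, and the 10-year case label is `event & time ≤ 3652`.

**Calibration.** λ₀ solves E[events] = target analytically: the covariate
mixture is enumerated exactly (13,824 profiles with product probabilities
and hazard multipliers), entry dates are averaged over a 64-point grid
spanning the recruitment window, and Brent root-finding inverts the
expected-event curve. The Monte-Carlo event count at the default scale then
scatters around 680 with binomial noise (±26 or so).

**Age bands.** The oldest band is treated as 60–64 (the screening ages),
with no within-band age modelling.

## Genotype simulation and the GRS

Controls follow Hardy–Weinberg proportions from the risk-allele frequency;
cases follow the exponential tilt Q_g ∝ OR^g·P_g — the canonical
log-additive per-allele model, and the natural realization of "draw each
woman's genotype from her status-specific genotype frequencies". SNPs are
mutually independent (no linkage disequilibrium) and independent of all
other covariates; genotypes are simulated *after* outcomes, conditional on
final case status, exactly as in the reference design.

Two consequences are used as end-to-end checks rather than inputs:

1. P(case | g)/P(non-case | g) ∝ exp(GRS), so logistic — and, for a rare
   outcome, Cox — regression of case status on GRS has slope 1 per GRS
   unit; the fitted hazard ratio per 0.1 units converges to e^0.1 ≈ 1.105.
2. Genotype frequencies among non-cases stay in Hardy–Weinberg
   proportions.

**Default panel.** The published per-SNP frequencies and odds ratios behind
the reference score are unavailable, so the shipped 75-SNP panel
(`data/snp_panel_synthetic75.tsv`) is synthetic: frequencies uniform on
(0.1, 0.9), log odds ratios lognormal shapes passed through a power/scale
transform solved (deterministically, fixed seed) so the control GRS mean is
4.53 and SD 0.37 — the location/scale implied by the reference quintile
boundaries (4.22/4.43/4.62/4.84) under normal-quantile spacing. Resulting
per-allele odds ratios span ≈1.02–1.25, typical of GWAS-era susceptibility
loci. The panel matches the reference score's location, scale and count by
construction, not provenance; any user panel in the same TSV schema
replaces it.

**Quintiles.** GRS quintile labels use minimum-rank tie-breaking at the
empirical 20/40/60/80th percentiles; a constant score vector collapses to
quintile 1 by convention.

**Reproducibility.** Replicate r of a run with master seed s draws from
`SeedSequence((s, r))`, so any one of the (by default 1,000; 20 in most
tests) virtual genotype datasets can be regenerated in isolation.

## Proportional-hazards risk models

Three nested specifications: Gail variables + ethnicity + BMI ("gail_bmi",
15 dummy columns), + six dense-area categories (+5), + continuous GRS (+1).
Dummy coding uses the reference levels of the reference analysis (age
50–54, Chinese, menarche ≥14, first birth <20, no affected relatives, no
biopsy, BMI <20, dense area ≤10 cm²). The GRS enters per unit; hazard
ratios per 0.1 unit are reported as exp(0.1·β).

Fitting maximizes the Efron-tie partial likelihood (lifelines backend).
Day-resolution exponential times generate few ties, so Efron vs Breslow is
immaterial here, but Efron is the safer default. An unpenalized fit is
attempted first; if Newton iteration fails — in practice only through
quasi-separation when a sparse level (e.g. Malay ethnicity, ~5% prevalence)
carries no events in a small cross-validation training fold — the fit
retries once with a small L2 penalty (1e-3) that bounds the divergent
coefficient and leaves identified ones essentially unchanged. Full-scale
fits never need it. Divergent "successes" (|log HR| > 15) are treated as
failures of the unpenalized attempt.

**Baseline hazard and absolute risk.** The Breslow/Nelson–Aalen cumulative
hazard H₀(t) = Σ_{tᵢ≤t} dᵢ / Σ_{j at risk} e^{lpⱼ} is evaluated at the
largest event time at or before 3,652 days (step-function convention). The
10-year baseline value is extracted at a reference profile x̄ — reference
categories for categoricals, the cohort-mean GRS for the continuous score —
as H₀(10y) = −log S^NA(10y | x̄)/e^{β′x̄}, which is algebraically exact for
the survival model S(t|x) = exp(−e^{β′x}H₀(t)). (A superficially different
arrangement of this formula, dividing the survival estimate rather than its
logarithm by e^{β′x̄}, is not consistent with that model and is not used.)
Individual risk is r = 1 − exp(−e^{β′x}H₀(10y)). With no events before ten
years H₀ = 0 and all risks are 0, with a warning. Mean predicted risk
tracks the realized 10-year cumulative incidence (calibration-in-the-large
within a few percent at the default scale).

**Diagnostics.** `check_proportional_hazards` correlates scaled Schoenfeld
residuals with rank-transformed event time (lifelines implementation);
simulations in the test suite confirm near-nominal type-I error under
proportional hazards and >80% power against a sign-flipping effect.

## Evaluation

**Cross-validated AUC.** Folds are stratified by the 10-year case label so
every training part contains events (refolding with a shifted seed if not,
logged). Each fold's subjects are scored by a model fitted — including its
own baseline-hazard extraction — on the other folds; out-of-fold risks are
pooled into one Mann–Whitney AUC (ties get half credit). For the GRS model
this repeats per genotype replicate; the mean and 2.5/97.5 percentile
across replicates are reported, and ROC curves are averaged pointwise on a
fixed false-positive grid. ROC labels are 10-year case status, matching the
10-year risk score.

**Concordance.** The Gönen–Heller estimator is computed from linear
predictors only (censoring-robust):
K̂ = [2/(n(n−1))] Σ_{i<j} 1/(1+e^{−|Δᵢⱼ|}), with tied pairs contributing
1/2 (the continuous limit). The implementation is a chunked O(n²) pair sum,
verified against a brute-force double loop to 1e−12; an optional
nonparametric bootstrap over subjects (200 resamples by default in the
pipeline) gives a percentile interval.

**Predictive values.** PPV(τ) = P(case | risk ≥ τ) and
NPV(τ) = P(non-case | risk < τ) at the a-priori thresholds 1.0–10.0%;
empty denominators give NaN. Group sizes are reported because the 5% and
10% tails hold few women and their values are unstable — at reference scale
only a handful of subjects clear those cuts.

## Problem sizes

Defaults mirror the reference analysis (n = 24,161, 680 expected cases,
1,000 genotype replicates, 10-fold CV, 200 bootstrap resamples). The test
suite and the acceptance script run the same cohort scale with 20 genotype
replicates — enough for replicate means to stabilize well inside the
tolerances checked — and use a 1/6-scale cohort (n = 4,000, 113 expected
cases, 5 folds) for the 20-master-seed AUC-gap stability comparison, and
1/12 scale (n ≈ 1,500–2,000) for pipeline smoke and reproducibility
checks. These sizes are the package's own trade-off between Monte-Carlo
precision and turnaround.

## Known limitations

- Covariate independence: real screening populations correlate BMI,
  density, parity and age; absolute discrimination of the covariate-only
  models can shift slightly in correlated data.
- The GRS is independent of density and the Gail variables by design; in
  real data shared heritability would erode part of its incremental AUC.
- The synthetic SNP panel matches the reference GRS in distribution, not
  identity; per-SNP conclusions are out of scope.
- Constant baseline hazard and purely administrative censoring; the
  case/non-case asymmetry in median follow-up emerges from the model but
  is not separately enforced, and competing mortality is ignored.
- Percent-density as an alternative density encoding is supported only by
  supplying a schema/hazard specification with those categories; the
  shipped defaults use dense area.
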