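# Methods

This note documents the models implemented in `equusage`, the parameter
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Age transform and the elastic-net clock

Chronological age is square-root transformed before fitting
(`transform="sqrt"`, offset 0 years by default). The transform compresses
the adult range and expands early life, matching the empirically faster
methylation change in young animals; the offset is exposed for datasets
containing age-0 samples, but is not needed when the youngest sample is
strictly positive. Predictions are squared back to years; a negative
prediction on the sqrt scale (possible under cross-species extrapolation)
is clamped to 0 years and flagged rather than raised, since transfer to a
diverged species is an expected use.

The clock solves the glmnet-form objective

    (1/2n)·Σ(y − β₀ − x·w)² + λ·(α‖w‖₁ + (1−α)/2·‖w‖₂²)

by cyclic coordinate descent with soft-thresholding. Predictors are
standardized internally (population SD) and weights back-transformed;
constant columns are excluded with a warning. Convergence is declared
when the largest coefficient change in a sweep drops below `tol` (1e-7
for final fits, 1e-4 inside cross-validation, where only the ordering of
the CV curve matters); stationarity (KKT) residuals at the solution are
reported and sit below 1e-6 on final fits. The path solver warm-starts
along a descending log-spaced grid of 100 λ values from λ_max (the
smallest λ with an all-zero solution) down to 1e-3·λ_max, and screens
coordinates per λ with the sequential strong rule, followed by a full
KKT pass that admits any violator — the screen changes the work done,
never the solution.

Defaults: α = 0.5 (the penalized-clock literature's convention; exposed
in config), LOO folds for λ selection, and the one-standard-error
selection rule. The 1-SE rule is a deliberate design choice: the CV
curve's minimum is estimated with sampling error, so every λ whose CV MSE
lies within one standard error of the minimum is treated as tied with it,
and ties break toward the larger λ (the sparser model). The exact
minimizer is available as `rule="min"`. Under a pure-noise response the
1-SE rule keeps the selected model essentially empty, which is the
behavior a null-calibrated screen should have; the exact minimizer
occasionally chases CV noise into a dense model.

Leave-one-out evaluation re-runs the entire pipeline — λ selection
included — without the held-out sample, so no information leaks through
the penalty choice. On the synthetic blood-scale recovery problem
(n = 76, 2000 sites, 50 informative at slope ±0.02 per √year, noise SD
0.01 beta units) this nested LOO achieves r ≈ 0.997 and median absolute
error ≈ 0.15 years.

## Epigenetic pacemaker

The pacemaker models each selected site j and sample i as
m_ij = m0_j + r_j·s_i + ε_ij with a latent per-sample epigenetic state
s_i. Sites enter the model when |Pearson r(β_j, age)| ≥ a threshold
(0.75 for single-tissue fits; 0.6 for combined fits, where cross-tissue
heterogeneity lowers correlations). Fitting alternates

  (a) per-site simple regression of β_j on the current states, then
  (b) the per-sample update s_i = Σ_j r_j(β_ij − m0_j) / Σ_j r_j²,

with states initialized at chronological age. Each half-step minimizes
the total squared error given the other block, so the recorded error
trace is non-increasing — asserted in tests over 50 seeds. Iteration
stops when the relative error improvement falls below 1e-6 or at 100
iterations (both in config). States are identified only up to an affine
gauge (scaling all rates by k and states by 1/k leaves the fitted surface
unchanged); the age initialization anchors the gauge, and all downstream
use is either correlation-based or goes through the trend curve, both
gauge-invariant in the relevant sense. Leave-one-out states apply update
(b) to the held-out sample under a model trained without it; the internal
fit there accepts n−1 = 2 training samples so the documented n = 3
minimum works.

States are translated to years through the shifted-log trend
s = a·ln(age + c) + d, fit by bounded nonlinear least squares (c > 0)
with five multi-starts over c ∈ {0.1, 0.5, 1, 2, 5}; translated age is
exp((s − d)/a) − c clamped at 0. The shifted-log family is the standard
pacemaker convention and reproduces the fast-early/slow-late pattern; it
is a documented assumption, not an estimated model class. EPM age
acceleration is exposed in two forms: the state residual from the trend
curve at the sample's age (state units) and translated minus
chronological age (years).

## Synthetic data

The generator produces the statistical structure the analyses assume —
and nothing more:

- **Ages**: log-uniform on [0.15, 25] years by default, giving the
  right-skewed age structure typical of managed wildlife cohorts. The
  generator exposes min/max but makes no claim of matching any real
  cohort's shape.
- **Methylation**: three site classes. Clock-like sites are linear in
  √age with slope ±0.02 beta per √year by default, so clock recovery has
  a well-posed truth on the fitted scale. Pacemaker-like sites share one
  state trajectory s(age) = a·ln(age + c) (a = 5, c = 1) with per-site
  rates; null sites are age-constant. Per-site intercepts are drawn so
  mean betas stay inside [0, 1] (no clipping of the signal itself); noise
  is i.i.d. Gaussian (SD 0.01 by default) and the final betas are clipped
  to [0, 1]. Optional small tissue and sex offsets emulate nuisance
  structure. Not emulated: probe-level chemistry, spatial correlation
  between CpGs, normalization artifacts — so passing tests demonstrate
  the estimators' correctness, not robustness to array artifacts.
- **Related species**: a configurable fraction of sites keeps its
  (m0, r); the rest get Gaussian intercept shifts. This emulates
  conserved-probe transfer; it does not emulate rate evolution.
- **Genotypes**: Hardy-Weinberg background at per-site alt frequencies
  drawn U(0.1, 0.5), with planted homozygous runs per individual whose
  lengths are drawn in [1.5, 60] Mb and sum exactly to the target
  F_ROH × screened length (targets below one minimum run length are
  rejected). Runs are placed without overlap; inside a run the genotype
  is homozygous (alt with probability p), with an optional contamination
  rate of ordinary draws. No linkage disequilibrium, pedigree structure,
  or genotyping error is simulated.
- **Acceleration phenotypes**: accel = β₃·age·F + ε with configurable
  main effects (default 0) and noise whose SD grows 10% per decade of age
  by default — the heteroskedasticity that motivates the sandwich errors.

All generators are deterministic under their seed and return truth
records sufficient to score recovery.

## Inbreeding

Hard filters follow the GATK germline short-variant heuristics: a site is
removed iff QD < 2, FS > 60, SOR > 3, MQ < 40, MQRankSum < −12.5, or
ReadPosRankSum < −8; a site lacking an INFO field passes that criterion
(counted in the report). The MAF floor is strict (< 0.01 removed, exactly
0.01 retained); an optional minor-allele-count filter (MAC ≥ 3) removes
singletons and private doubletons for the ROH input, since frequency
pruning beyond that can bias ROH detection in inbred populations.

F̂ = (O_hom − E_hom)/(L − E_hom) with E_hom = Σ(1 − 2p_l q_l) over the
individual's non-missing polymorphic loci, frequencies estimated from the
panel itself; monomorphic loci are excluded and an individual with no
usable loci gets a missing estimate. Because frequencies come from the
same panel, F̂ carries a small-panel bias of about −1/(2N−1); the optional
L/(L−1) correction is off by default. Tests therefore calibrate F̂ on a
30-individual panel, where the bias is well inside the tolerance.

ROH detection interprets the scan in SNP units: windows of 150
consecutive SNPs (the referenced tool's unit is SNPs; "150" is read as a
stringency increase of its 100-SNP run default), a window called
homozygous iff it has 0 heterozygotes and ≤ 2 missing calls, per-SNP hit
fraction ≥ 0.05 (the tool's default), candidate runs of consecutive
qualifying SNPs, and final segments requiring ≥ 150 SNPs and ≥ 1.5 Mb
first-to-last span. Output is BED (0-based half-open); VCF positions are
1-based. The implementation is vectorized but is held, test-by-test,
to exact agreement with a brute-force window-enumeration oracle. The
screened genome length is a required input for F_ROH (it is a property of
the callable genome, not of the call set); whether it should be reduced
per-individual is unresolved, and a global constant is used.

Mendelian errors use the biallelic transmission table on fully observed
trio-locus pairs; imputation quality is hard-call concordance plus
squared Pearson correlation of dosages, per individual.

## Acceleration models

Age acceleration defaults to the residual of predicted age regressed on
chronological age, which is exactly uncorrelated with age by
construction. The plain difference and the literal reversed regression
(chronological on predicted, sign-flipped so positive still means
epigenetically old) are implemented as alternatives because both
definitions circulate and they disagree in small samples; the residual
form is the field's convention for age-adjusted analyses. EC acceleration
should be computed from LOO predictions — in-sample predictions are
shrunk toward the truth and understate acceleration variance.

The association models are OLS of acceleration on intercept, sex (0/1),
age, inbreeding (F or F_ROH), and age×inbreeding, solved by QR; rank
deficiency raises with the offending columns named. Robust covariances
are the sandwich (XᵀX)⁻¹Xᵀdiag(ω)X(XᵀX)⁻¹ with ω = e² (HC0),
e²·n/(n−k) (HC1), or e²/(1−h)² (HC3). HC3 is the default at the n ≈ 70
scale these cohorts run at; p-values are two-sided Student-t on n−k df.
A unit-leverage point makes HC3 undefined and raises. Known limitation:
at n = 70 with log-uniform ages, the age×F term is collinear enough with
its margins that ±2·SE coverage of a planted β₃ sits near its nominal
level (93–97/100) but power at small effect sizes is modest.

## EWAS

Per-site screening: Pearson r of beta with age, t = r√(n−2)/√(1−r²),
two-sided p on n−2 df, z = sign(r)·Φ⁻¹(1 − p/2). Perfectly correlated
sites underflow p; the reported p is floored at 1e-300 and |z| capped at
40 with a flag, keeping extreme sites finite and ordered. Zero-variance
sites get missing statistics. Stouffer meta-analysis uses weights √n_k by
default — with tissue sizes as unbalanced as 76 vs 20 the weighting is
material — and combines only sites scored in every tissue. Top-k
selection takes the k most positive and k most negative z (k = 500
default), with ties broken lexicographically by site id for determinism.
The island-vs-non-island comparison is a two-sided Wilcoxon rank-sum test
on the z-scores; the rank-sum choice (rather than, say, a t-test on
medians) is a documented convention, as is p-inversion (rather than a
Fisher transform) for the z-scores themselves.

## Problem sizes and determinism

Study-scale checks run at the cohort sizes the analyses are designed for:
clocks at n = 76 × 2000 sites with nested LOO, the pacemaker at n = 120 ×
300 selected sites, ROH on panels of 20–30k SNPs over a few hundred Mb,
association models at n = 70 × 100 replicates, and EWAS calibration on
1e5 null sites. Every stochastic path takes an explicit seed, and a fixed
seed reproduces all tables byte-identically.
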