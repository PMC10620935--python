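# Methods

`midpipe` analyses ¹³C stable-isotope-tracing LC-MS data: tables of
isotopologue peak areas (rows `metabolite × mass shift`, columns samples)
measured across cell populations (e.g. CD8⁺ T-cell subsets TN, TSCM,
TCM, TEM, TEFF, TEX) from several donors, together with blank
injections. This note records the models, the defaults and why, and what
the synthetic-data tests do and do not demonstrate.

## Quantification thresholds

For each batch, every isotopologue's blank statistics are estimated from
the blank injections of that batch: mean μ_b, sample SD σ_b (ddof = 1,
appropriate for the typical three blanks), and quantification threshold
T = μ_b + 2σ_b. At least two blanks per batch are required; an
isotopologue absent from the blanks gets the permissive μ_b = T = 0 with
a warning.

Intensities are then mapped piecewise:

* x < μ_b → 0 (indistinguishable from background),
* μ_b ≤ x < T → T·(x − μ_b)/(T − μ_b) (the blank-to-threshold band is
  stretched linearly onto [0, T], so the map is continuous at T and
  monotone),
* x ≥ T → unchanged.

The map is a calibration of the *raw* intensity scale; tables already at
the thresholded stage pass through unchanged (re-mapping mapped values
would corrupt them — any non-identity map of the band cannot be
pointwise idempotent). Degenerate T = μ_b zeroes everything below T.

Two missingness filters follow. An analyte is *testable* when at least
two biological replicates exceed T. *Group cleaning* removes an
analyte's values from any sample group in which strictly more than 1/3
of the values (missing counts as below) fall below T; the >1/3 rule uses
exact integer arithmetic so a group at exactly 1/3 survives.
Sub-threshold membership is always judged on the thresholded-stage
values, where the thresholds are defined; the resulting mask is applied
to the normalized table, i.e. cleaning happens after correction and
normalization. Cleaning before correction would interact destructively
with the correction's missing-value propagation: every metabolite with
an always-sub-LOD high isotopologue (any 6-carbon TCA intermediate)
would lose its complete vector in every group.

## Natural-abundance correction

High-resolution instruments resolve the isotopic contributions of
non-carbon elements away from the carbon envelope, so only carbon is
corrected. For a metabolite with n carbons of which j are
tracer-labeled, each remaining carbon is independently ¹³C with natural
probability p (default 0.0107, the standard terrestrial abundance), so

    M[i, j] = C(n−j, i−j) · p^(i−j) · (1−p)^(n−i),  i ≥ j.

M is lower-triangular and column-stochastic; the forward model is
verified in tests against brute-force enumeration of all 2ⁿ per-atom
configurations. Measured vectors are de-convolved by solving M·y = x
with non-negative least squares (default; prevents the small negative
isotopologues that direct inversion produces on noisy data). Direct
triangular inversion with clipping is available for oracle tests.
Corrected vectors are *not* renormalized to the observed total; absolute
corrected intensities continue into normalization. An optional
tracer-purity term (default off, purity 1.0 — no impurity value is
assumed) pre-composes M with a binomial label-dilution matrix; with
purity < 1 the kernel is no longer triangular. Vectors containing a
missing entry yield an all-missing corrected vector: the solve needs the
complete envelope.

## Normalization

Two stages:

1. **Between isotopologues.** Every value of metabolite m is divided by
   the metabolite's mean abundance A_m — the across-sample mean of its
   per-sample isotopologue sums — giving every metabolite mean abundance
   1 regardless of ionization efficiency. A_m = 0 leaves the metabolite
   untouched and flagged. ("Mean over samples" is our reading of an
   ambiguous phrase; the alternative, mean over isotopologues, would not
   equalize metabolites.)
2. **Between samples.** Size factors are weighted means of analyte
   signals: the relative variance of analyte k is rv_k = var_k/mean_k²
   across samples (squared CV, linear scale), its weight w_k = 1/rv_k
   clamped at the 99th percentile of finite weights so a flat analyte
   cannot dominate. s̃_j = Σ_k w_k x_kj / Σ_k w_k, anchored to geometric
   mean 1. Analytes with missing values are excluded from the weighting
   set. When no analyte has a finite weight (identical samples) equal
   weights are used — this makes the all-identical case yield unit
   factors rather than an error.

MIDs are per-sample fractions and therefore invariant to size factors.
Like all abundance-composition normalizations, the size factors assume
most analytes are unchanged between groups; when many analytes change in
one direction the factors absorb part of the shift (compositional bias),
which is why the recovery test uses an effect-free design.

## Summaries

Abundance(m, s) = Σ_k x_(m,k),s over non-missing isotopologues (cleaned
isotopologues are near the detection limit by construction, so skipping
them changes the sum negligibly); missing only when the whole vector is
missing. MID: π_k = x_k / Σ x, undefined at zero or missing sums.
Fractional labeling F = Σ_k k·π_k / n (undefined for n = 0) is the
quantity drawn on pathway maps. Diagnostic ratios: per-sample
isotopologue ratios (e.g. m+3/m+2 in TCA intermediates, contrasting
anaplerotic pyruvate-carboxylase entry against oxidative PDH entry of
glucose carbon) with arithmetic group means, and per-sample metabolite
abundance ratios (fumarate/succinate and the like), zero denominators
giving missing.

## Differential testing

**Abundances** are modeled on the natural-log scale:
log y = β_group + b_donor + ε, b ~ N(0, σ²_d), fit by REML
(statsmodels MixedLM). Zeros are handled by adding half the analyte's
smallest positive value before logging. The design matrix is one-hot in
group, so coefficients are group means and contrast vectors apply
directly. Boundary fits (σ_d → 0) occasionally fail with gradient-based
optimizers; a retry ladder (default → Powell → Nelder-Mead) removes the
failures. With σ²_d = 0 the fixed effects equal the OLS group means
(verified to 1e-6).

**Isotopologue fractions** use beta regression with a donor random
intercept: y ~ Beta(μφ, (1−μ)φ), logit(μ) = β_group + b_donor. No
installed Python package provides this model, so it is implemented here:
the marginal likelihood integrates b out per donor with *adaptive*
Gauss-Hermite quadrature (nodes centered at the per-donor posterior mode
found by a vectorized Newton iteration, scaled by the curvature; 15
nodes by default, ≥9 supported — refinement from 9 to 25 nodes moves the
log-likelihood of a three-donor example by < 1e-9). β, log φ and
log σ_d are maximized jointly with L-BFGS-B; σ_d has a floor of 1e-8,
below which the likelihood analytically reduces to fixed-effects beta
regression (verified against statsmodels' BetaModel). Standard errors
come from the central-difference observed information. Boundary
fractions are made admissible by the shrinkage y' = (y(N−1) + 0.5)/N
applied to the boundary observations only; interior values are not
perturbed. Analytes with every observation at one boundary are flagged
degenerate and reported with missing p.

**Contrasts and FDR.** For contrast vector c: estimate cᵀβ, SE from the
coefficient covariance, Wald statistic, two-sided p. The default
reference is a t distribution on residual degrees of freedom
(n − k_fixed − (n_donors − 1)): with paired designs of ~20 residual df
the normal reference is measurably anti-conservative (long-run null
rejection ≈ 0.063 at α = 0.05 in our simulations versus ≈ 0.048 for the
t reference), so `df_method: z` is kept as a config switch rather than
the default. p-values are Benjamini-Hochberg adjusted across analytes
within each contrast family; metabolite-level and isotopologue-level
analyses form separate families (`fdr_family: pooled` merges contrasts).
Default contrast sets follow the designs: consecutive differences
TSCM−TN, TCM−TSCM, TEM−TCM for differentiation panels and TEX−TEFF for
exhaustion panels. An analyte whose fit lacks a contrast level (group
removed by cleaning) is reported with missing values for that contrast.

## Synthetic data

The generator runs the measurement process forwards: per-group true MIDs
and mean log-abundances; a donor random intercept (SD σ_d, drawn per
donor × metabolite) in a paired design where every donor appears in
every group; forward natural-abundance convolution using the *same*
kernel object as the corrector, so forward and inverse models cannot
drift apart; multiplicative log-normal noise with configured CV
(standard for LC-MS peak areas); additive Gaussian blank baseline
(clipped at 0); optional per-sample scale factors; left-censoring below
a floor (peak integration fails for tiny peaks); blank samples carrying
baseline only. One seed fixes the entire dataset.

Presets (the study conditions used throughout the tests):

* **differentiation** — 4 groups × 3 donors × 2 replicates, 24-metabolite
  panel: glycolysis/TCA intermediates plus 12 stable unlabeled free
  amino acids. TN has label only up to 3-phosphoglycerate (an
  enolase-block pattern); activated groups share m+3-dominant lactate
  (π₃ = 0.6) and m+2-dominant TCA labeling with anaplerotic
  m+3/m+2 = 0.15. Abundance effects (±0.3–0.5 natural-log per
  differentiation step, balanced in direction) sit in 4 of 24
  metabolites, keeping changed analytes a minority as size-factor
  normalization assumes. Blank baseline 50 ± 10 against abundances
  ~2·10⁵.
* **exhaustion** — TEFF vs TEX, 3 donors × 2 replicates; TEX has reduced
  labeling and lower abundances of succinate/fumarate/malate.
* **null** — 2 groups × 3 donors × 4 replicates (24 samples), 1000
  3-carbon metabolites, no effects anywhere; used for type-I-error
  calibration. The sample size gives the group contrast ~19 residual
  degrees of freedom, enough for the Wald reference to be meaningful.
* **lod_stress** — 30 metabolites with abundances straddling a large
  blank baseline (1000 ± 250), exercising zeroing, the linear band and
  group cleaning.

What passing tests show — and don't. The generator reproduces the
statistical structure the analysis assumes (donor intraclass
correlation, multiplicative noise, blank baseline, LOD censoring), so
the tests demonstrate internal correctness: the corrector inverts the
forward model, estimators recover generating parameters, type-I error is
controlled under the assumed model. Real chromatography adds
retention-time drift, saturation, co-elution and non-Gaussian blanks
that are not modeled; conclusions about real data rest on the model
assumptions, not on these tests.

## Numerical choices

* Blank SD uses ddof = 1; thresholds computed per batch.
* The >1/3 cleaning rule compares 3·n_below > n_group in integers.
* NNLS via scipy; direct solves via triangular back-substitution with
  negatives clipped.
* Beta likelihood: μ clipped to [1e-12, 1−1e-12]; Newton steps damped to
  |Δb| ≤ 5; curvature capped below −1e-10; log-sum-exp for the
  quadrature sum.
* L-BFGS-B bounds: φ ∈ [1e-2, 1e8], σ_d ∈ [1e-8, 50] (log scale);
  starting values from a logit-scale least-squares fit and a
  method-of-moments φ.
* Constant-response analytes short-circuit to estimate 0, p = 1 (both
  model paths).
* Manifest hashes cover the analysis configuration but not the output
  directory, so identical analyses give byte-identical manifests.

## Known limitations

* Carbon-only correction: not valid for low-resolution data where other
  elements' isotopes overlap, and tracer elements other than carbon are
  out of scope.
* The LMM assumes log-normal abundances; strongly censored analytes
  (many zeros) violate this, and the offset rule only mitigates it.
* Residual-df t reference is a pragmatic approximation, not Satterthwaite
  or Kenward-Roger.
* Size factors inherit compositional bias when many analytes change in a
  correlated direction.
* No drift/QC-pool correction and no imputation; missing means missing.
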