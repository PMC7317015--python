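# Methods

This note documents the models implemented in `cgmtap`, the choices made
where the design was open, and what the synthetic data can and cannot show.

## Genomic data and kinship

Genotypes are coded 1 / 0.5 / 0 (homozygote, heterozygote, alternate
homozygote); on this half-dosage scale the reference-allele frequency `p_l`
is the column mean and the kinship is

    K_ij = Σ_l (M_il − p_l)(M_jl − p_l) / b,   b = Σ_l p_l (1 − p_l).

Defaults for marker QC: MAF ≥ 5%, heterozygosity ≤ 5%, missing rate ≤ 5%
(rates computed on non-missing calls), then windowed LD pruning (window 100
SNPs, step 5, r² ≤ 0.8, later marker of a violating pair removed — any
consistent tie-break satisfies the testable contract that no retained
within-window pair exceeds the threshold), then frequency imputation of
missing calls. `allele_freq` may be supplied externally when the reference
frequencies come from a larger diversity panel.

## Environmental characterization

Covariate columns are standardized by a rank-based inverse-normal transform,
`x → Φ⁻¹((rank − 0.5)/E)` with average ranks for ties (a z-score alternative
is available). Note the finite-sample SD of normal scores is slightly below
1 (≈0.967 at E = 3), approaching 1 as E grows; no post-rescaling is applied.
The environment covariance is `W = 1 − D_Ω/max(D_Ω)` from Euclidean row
distances of Ω: unit diagonal, entries in [0, 1], zero attained by the most
dissimilar pair. `W` is not guaranteed positive semidefinite; before any REML
use it is bent by adding `δ = max(0, −λ_min) + 1e−8` to the diagonal and
renormalizing the diagonal to 1.

Environments are classified by their HD–GY relationship: quadratic when the
quadratic OLS fit improves adjusted R² by more than `quad_margin`
(default 0.05), otherwise low/medium/high by absolute Pearson correlation
(<0.3 / 0.3–0.6 / >0.6). The margin matters: under a purely linear
relationship a chance quadratic term improves adjusted R² with probability
≈ P(F(1, n−3) > 1) ≈ 0.32 at any noise level, so a zero-margin rule would
label a third of linear environments quadratic. A 0.05 margin brings that
false rate below 0.1% at n = 220 while preserving genuinely quadratic
environments, whose typical adjusted-R² gain is ≈ 0.14.

## Phenology model

A minimal deterministic wheat model with exactly two genetic parameters:

* thermal time `TT(t) = Σ max(0, tmean_d − t_base)` (t_base 0 °C);
* emergence at `TT ≥ 120 °C·d`;
* Haun stage `HS(t) = (TT − 120)/P` with phyllochron `P ∈ [60, 160]` °C·d;
* at the first day with `HS ≥ 4` the perceived daylength `DL*` fixes the
  final leaf number `L_f = clip(8 + SLDL·max(0, 15 − DL*), 8, 24)`,
  `SLDL ∈ [0, 2]` leaves per hour of daylength shortfall;
* heading at the first day with `HS ≥ L_f + 2.5`.

Daylength comes from latitude via solar declination (no twilight
correction). Heading is reported as the first whole day crossing the
threshold; a linearly interpolated fractional day is available and is the
default inside MCMC likelihoods (smoother mixing). Vernalization is
deliberately omitted: the intended material is autumn-sown winter wheat
assumed fully vernalized before photoperiod becomes limiting. The model is
monotone in both parameters and costs two binary searches per prediction
once cumulative thermal time is cached, which is what makes MCMC calibration
cheap.

## Bayesian calibration and identifiability

Per variety, an independent Metropolis-within-Gibbs chain updates P and SLDL
coordinate-wise (Gaussian proposals, SD 3 °C·d and 0.05; uniform priors over
the valid ranges; proposals outside the support rejected) under
`HD_obs ~ N(HD_model, σ_HD²)` with σ_HD fixed at 1.5 days by default, or
sampled under an inverse-gamma(2, 2) prior. Defaults: 10 000 iterations,
2 000 burn-in, thinning 10. Chains are vectorized across varieties; all
random draws are pre-generated from one numpy Generator, so the optional
numba-compiled kernel and the pure-numpy kernel are bit-identical.

An identifiability caveat discovered while validating against exact
grid-posteriors: in an all-autumn-sown network at 43–50°N the leaf-number-
fixing stage falls in mid-winter everywhere, `DL*` is nearly constant across
environments, and the likelihood only constrains the ridge combination
`(L_f(SLDL) + 2.5)·P`. Heading *prediction* in similar environments is
unaffected (the ridge is exactly what predicts), but the individual
parameters are not separable — the exact posterior mean can miss the truth
by 5–10 °C·d. Separate recovery requires photoperiod contrast, i.e. a
calibration-optimized design; `simulate.calibration_design_weathers`
provides one (sowings staggered October–March, spread latitudes), under
which posterior means recover both parameters to ±3 °C·d / ±0.1 for >90% of
varieties at σ_HD = 1 day.

For brand-new varieties (no heading phenotype), parameters are predicted by
a GBLUP mixed model per parameter (intercept + optional major phenology
markers as fixed effects, polygenic effect with covariance K, variance
components by REML via the eigendecomposition of K); predictions are clipped
to the valid parameter ranges they feed.

## GEI mixed models

All nine specifications share one covariance family on the
variety × environment grid:

    V = K ⊗ (σ_g² J + σ_ge² Σ_E) + σ_e² I,   Σ_E ∈ {—, I, bent W}

which factorizes exactly as `(U ⊗ Q) diag(λ_k d_j + σ_e²)(U ⊗ Q)'` with
`K = UΛU'` and `σ_g² J + σ_ge² Σ_E = QDQ'`. Observed training cells are a
subset of the grid; the unobserved cells are handled exactly through a
Schur-complement correction of the full-grid inverse, so a REML likelihood
evaluation costs O(nE·m) (m = unobserved grid cells) instead of O(N³). The
residual variance is profiled out and the two variance ratios are maximized
directly by Nelder–Mead, with the GE ratio parametrized on the square-root
scale so the zero-variance boundary is an interior point of the search;
convergence requires the REML log-likelihood stable to 1e−6 across the final
simplex, and components are floored at 1e−8 of the phenotypic variance.
The implementation is verified, for all nine specifications, against a dense
explicit-V GLS / conditional-Gaussian oracle to 1e−6.

Fixed effects are a full environment factor (no global intercept) plus, per
specification, environment-specific slopes on standardized HD and on its
standardized square. Standardization constants come from training records
only and are reused on test records. Predictions of unobserved cells are
BLUE(fixed) + BLUP(random) with BLUPs from the covariance of the target cell
with the training cells. Two policies for never-observed environments: the
fixed environment mean is the average of training-environment BLUEs (a
constant per environment, so within-environment predictive ability is
unaffected), and the K ⊗ I structure is refused outright since it carries no
information across environments.

## New-environment covariate slopes

For leave-one-environment-out prediction, `alpha_j` (and `beta_j`) are first
estimated by per-environment OLS in the training environments, then
regressed on environmental covariates. Candidates are screened to the
min(10, E_train/2) covariates with the largest absolute marginal correlation
with the response — with up to 139 covariates and ~15 environments an
unscreened search is ill-posed. The selection criterion is the generalized
AIC `n·log(RSS/n) + k·p` (p counts coefficients including the intercept;
k = 3.7 for α, k = 8 for β). Because the screen caps the candidate set at
ten, the criterion is minimized exactly by subset enumeration rather than by
a forward–backward walk: the heuristic walk can stall in local optima on
correlated candidates (observed gaps of several criterion units), whereas
enumeration of ≤ 2¹⁰ tiny regressions is instantaneous and makes the
procedure's optimality testable against an independent oracle.

## Cross-validation orchestration

One master seed drives everything; per-(repeat, fold) seeds are derived
through `SeedSequence([master, repeat, fold])`, making every run
bit-reproducible. CVrandom and CVnewG use 6 folds (default 10 repeats);
CVnewE is leave-one-environment-out. In every fold the secondary trait of
the test cells is model-predicted — never observed: per-variety MCMC on
training cells (CVrandom), on training varieties followed by genomic
parameter prediction (CVnewG), or on the remaining environments (CVnewE,
where no heading is observed in the held-out environment for anyone).
Predictive ability is computed per environment within each fold; folds
contribute one correlation per environment with ≥3 test cells (smaller
groups are skipped with a logged notice), and summaries average these
correlations unweighted.

## Synthetic MET generator

Defaults emulate a 220-variety × 16-environment winter-wheat network:
biallelic inbred genotypes (MAF U(0.05, 0.5), 2% residual heterozygosity,
1% missing), one major phyllochron locus and two major photoperiod loci plus
200-marker polygenic backgrounds, per-environment weather (seasonal sinusoid
between site-specific winter 3–12 °C and summer 16–22 °C means, AR(1) noise
ρ = 0.7 / SD 2 °C, sowing window Oct 10 – Nov 5, latitudes 43–50°N), heading
dates from the phenology model plus N(0, 1 day) observation noise, 20
deterministic weather-summary covariates plus 5 pure-noise distractors, and

    GY_ij = mu_j + alpha_j h~_ij + beta_j h~²_ij + G_i + GE_ij + e_ij

with G drawn through marker effects (variance 0.5), GE from K ⊗ W_true
(variance 0.3, W_true from the true covariates) and residual variance 0.5.
Environment classes are designed 4/4/4/4 with per-class slope ranges
(|α| ≤ 0.2 low; 0.35–0.6 medium; 0.7–1.1 high, signs random; quadratic
β ∈ [−2.2, −1.0] with small α).

The covariate `h~` used in generation is heading centered per environment
and scaled by one pooled within-environment SD. This is what makes the class
design meaningful: with that scale, the within-environment correlation is
`r ≈ α/√(α² + 1.3)`, so the class ranges map onto the intended correlation
bands (had the covariate been globally standardized, between-environment
heading differences would shrink its within-environment variance and no
admissible slope could reach |r| > 0.6). The per-environment centering is
absorbed by the environment fixed effects at fitting time, and the scale
differs from the model-side global standardization by one common factor, so
fitted slopes reproduce the generating slopes up to that factor. The
boundary arithmetic also implies honest class overlap: α = 0.7 gives
r ≈ 0.52, so environments near a range edge can realize one severity class
off; confusions beyond an adjacent class essentially never occur.

What the generator does *not* emulate: real site weather and management
(nitrogen/drought treatments), crop-model-derived stress-index covariates,
LD decay along chromosomes (markers are exchangeable), vernalization
differences, and — importantly for CVnewE — slopes `alpha_j` are drawn
randomly within class rather than driven by the covariates, so the
environmental-covariate regression of α has no true signal in the synthetic
world and its accuracy there is a floor, not an estimate, of what real data
allow. Passing tests therefore demonstrate correctness of the machinery and
the qualitative trait-assisted pattern (largest gains in the "high" class),
not field-level predictive ability.

## Problem sizes and determinism

The test-suite and the acceptance script run the scenario studies at a
reduced design of 120 varieties × 16 environments × 1000 markers with 3
(tests) or 2 (acceptance script) repeats of 6-fold CVrandom, which preserves
the qualitative structure of the full design at a fraction of the cost;
parameter-recovery studies use 30 varieties × 8 environments at the default
10 000 MCMC iterations. Every stochastic component (generator, folds, MCMC)
descends from one seed, and repeated runs are bit-identical.
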