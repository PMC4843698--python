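# Methods

`divpart` implements the quantitative machinery used to ask whether resource
alterations (nutrient enrichment, drought) change diversity–productivity
relationships in grassland experiments: the additive partition of
biodiversity effects, hierarchical REML mixed models with temporal residual
correlation, and a multi-study synthetic-experiment generator that provides
ground truth for every stage.

## 1. Additive partition of biodiversity effects

For a mixture plot sown with N species in year t, with observed species
biomass Y_O,i (g m⁻²) and mean monoculture biomass M_i of the same species
in the same study, treatment and year:

    RY_O,i = Y_O,i / M_i                 observed relative yield
    RY_E,i = sown proportion of i        expected relative yield (1/N for
                                         substitutive designs)
    ΔRY_i  = RY_O,i − RY_E,i

    net (ΔY) = Σ Y_O,i − Σ RY_E,i · M_i
    CE       = N · mean(ΔRY) · mean(M)   complementarity effect
    SE       = N · cov(ΔRY, M)           selection effect

The covariance divides by N (population covariance), which makes the
identity **ΔY = CE + SE** algebraically exact; this identity is enforced as
a test invariant at 1e-9 relative tolerance.

**Exclusion filter.** Relative yields diverge as M_i → 0, so species whose
mean monoculture biomass in a given year falls below a threshold (default
2.5 g m⁻², configurable) are excluded. Excluded species — and species with
no monoculture data in their treatment-year — are dropped from the plot's
partition, expected proportions are renormalized over the survivors, and
the drops are listed per plot. Plots left with fewer than two usable
species get status `degenerate` (or `no_monoculture_data` when missing
monocultures caused it) and no effect values.

**Standardization.** Because the treatments themselves move absolute
biomass, effects are divided by the mean monoculture biomass of the
corresponding treatment, making them dimensionless and comparable across
treatments. The averaging scope is configurable: `study_treatment_year`
(default — denominators never mix studies with different productivity
scales), `study_treatment` (pools years, ~3x more monoculture plots per
denominator), or `treatment`. Scale invariance (multiplying every biomass
by c > 0 leaves standardized effects unchanged) is a tested property.

## 2. Mixed models

Productivity and diversity-effect responses are modelled as

    y = Xβ + Σ_k Z_k u_k + ε,   u_k ~ N(0, σ²_k I),  ε ~ N(0, σ²_e C(ρ))

with fixed effects intercept, ln(sown richness), treatment (0/1, or two
indicators for the NPK / NH₄NO₃ recoding), and their interaction; random
effects for study, study×ln richness, study×treatment,
study×ln richness×treatment, study×time (year), and plot within study
(independent components, diagonal G — no cross-correlations, matching the
reported variance-component structure); and within-plot residual
correlation across years C(ρ) that is AR(1) (ρ^|Δyear|, so missing years
are handled by the power of the integer lag), compound symmetry, or the
identity. Productivity is square-root transformed; standardized net/CE/SE
responses are modelled untransformed (they can be negative). Drought
diversity-effect models drop the temporal correlation structure (the
simplification used when AR(1) fails to add information on those
responses); nutrient models keep AR(1).

**Estimation.** All listed random terms nest in study, so the marginal
covariance V is block-diagonal by study; the restricted likelihood is
evaluated per block (Cholesky) with the residual variance profiled out.
Variance ratios λ_k = σ²_k/σ²_e are optimized on the log scale (bounds
e⁻¹⁴…e⁷) and ρ through a tanh map into its valid range (for compound
symmetry the lower bound is −1/(m−1) for the largest plot series m), by
L-BFGS-B seeded from the best of three starts (variance ratios 0.3, 0.02,
1.0), with full restarts from the remaining seeds if the first run fails.
Convergence tolerances: relative 1e-11 on the objective, 1e-7 on the
gradient, 500 iterations. Estimates with λ_k below 1e-5 are reported as
boundary (SE and z-ratio suppressed). AIC = −2·REML-loglik + 2·(number of
covariance parameters); fits being compared share the fixed structure, so
only covariance parameters are counted, and the AR(1)/compound-symmetry
comparison selects the lower AIC (exact ties keep AR(1) and are flagged).

**Inference.** Fixed effects are tested sequentially (each term adjusted
only for the terms before it) via incremental Wald F statistics computed
from the V^(−1/2)-whitened design QR. Denominator degrees of freedom use a
Satterthwaite approximation: the covariance of the variance parameters is
taken from the numerical curvature of the restricted likelihood (boundary
components excluded), and d Cov(β̂)/dφ from central differences; multi-df
terms combine per-contrast df by the standard harmonic formula. When the
curvature is unusable the fallback is a containment-style n−p, and the
method used is printed beside every p-value — this is deliberately *not*
the Kenward–Roger correction, and p-values near the threshold should be
read accordingly. Confidence intervals use t quantiles with per-coefficient
Satterthwaite df. With a single study, study-level random terms are dropped
and the corresponding fixed-effect tests are flagged untestable. Predicted
richness–response lines are fixed-effects-only (pooled) or add study-level
BLUPs (per study), on the model scale and back-transformed (squared) for
productivity.

## 3. Synthetic experiment generator

The generator emulates a set of 6–16 grassland experiments crossing a sown
richness gradient {1, 2, 4, 8, 16} with a binary resource alteration over
several years.

**Totals.** On the square-root scale, each plot-year's total biomass is
fixed part + study-level random draws + a plot effect + stationary AR(1)
year errors (+ optional extra iid noise), then squared (negative values are
clamped to zero and the clamp rate reported). Because noise is added on the
analysis scale, the productivity model is correctly specified under the
default configuration; a log-normal multiplicative noise toggle provides a
misspecified variant. For mixtures the fixed part is the linear predictor
β₀ + β₁ lnN + β₂T + β₃ lnN·T; monoculture plots instead use √M_i, the
species' own monoculture mean.

**Species pools.** Monoculture means are log-normal across species with
E[√M_i] = β₀ + β₂T, so the treatment acts multiplicatively on M (factor
> 1 for nutrient addition, < 1 for drought) and the monoculture scatter
parameter is interpretable as a log-scale CV. One monoculture plot per
species per treatment is sown by default (configurable) — diversity
experiments maintain monocultures of every pool species, and partition
denominators need them.

**Mixture composition.** Species' shares of the (noisy) plot total are
proportional to w_i = max(0, RY_E,i + ΔRY_i)·M_i, with injected deviations

    ΔRY_i = (mean_dry_slope + treatment_dry_shift·T
             + (selection_strength + treatment_selection_shift·T)·z_i
             + species_sd·u_i) · lnN / N

where z_i is the species' standardized log-M deviation and u_i independent
species-level scatter. Truncation of RY_E + ΔRY at 0 (a species cannot
produce negative biomass) is counted and reported; the default
configurations keep it below 1%. Because shares are renormalized to the
total, the *realized* per-plot deviations — recorded per mixture plot in
`TrueParameters`, evaluated by direct arithmetic independent of the
partition module — are the ground truth, and partitioning the noise-free
table reproduces them exactly (a tested identity). Two consequences are
worth stating plainly:

- a *uniform* shift of ΔRY (mean_dry_slope, treatment_dry_shift) cancels
  out of the realized partition at fixed totals; it mainly moves the
  truncation margin;
- the richness×treatment signal on *standardized* net/CE effects arises
  from (i) the treatment-specific monoculture denominator — fertilized
  monocultures are more productive, so standardized slopes are flatter
  under enrichment even with no productivity-scale interaction — and
  (ii) `treatment_selection_shift`, which tilts mixture dominance toward
  high-M (nutrient-responsive) species under treatment, shifting biomass
  gain from the complementarity to the selection component without
  touching totals.

**Default magnitudes** (square-root-biomass scale): nutrient studies —
intercept 14.12, richness slope 3.01, treatment +3.39, interaction −0.34;
variances study 14.69, study×richness 2.11, study×treatment 1.97,
study×richness×treatment ≈ 0, study×time 4.20, plot 13.86; ρ = 0.10;
drought studies — intercept 9.52, slope 2.03, treatment −1.18, interaction
−0.29; study 9.66, study×richness 0.94, study×treatment 0.08, study×time
2.92, plot 11.50; ρ = 0.05. Residual (AR(1) marginal) sd defaults to 3.0;
monoculture log-scatter to 0.4 — typical within-site species heterogeneity.
The headline configurations use 6 nutrient vs 3 drought studies (the sizes
of the species-level subsets such data typically offer), ~120–160 plots per
study (realistic for the large diversity experiments), 4 monoculture
replicates per species, zero productivity-scale interaction, and a
dominance tilt (+0.3) under nutrient addition only.

**Seeding.** One master seed; independent named substreams (CRC-keyed
`SeedSequence` spawn) per study for pools, design, random effects and
errors, so tables are bit-reproducible and robust to unrelated config
edits.

## 4. What the tests do and do not show

The generator produces Gaussian-on-√scale noise, substitutive designs with
equal sown proportions, balanced rosters, and species effects that are
constant across years. Real experiment databases are unbalanced, have
missing species-level biomass, drifting species identities, and
non-Gaussian errors; passing recovery/calibration tests here shows the
*machinery* is correct under its stated assumptions, not that those
assumptions hold for any particular field dataset. Two small-sample
caveats surfaced by the Monte-Carlo work: with very few plots (~48/study)
the plug-in sequential Wald test of the interaction is anti-conservative
(rejection ≈ 0.10–0.12 at nominal 0.05) — calibration is recovered at the
default design (~0.04); and with 3 studies (drought) p-values near 0.05
are unreliable in either direction. Monoculture-mean noise propagates
heavy-tailed errors into relative yields; the 2.5 g m⁻² filter removes
only the extreme cases, which is why diversity-effect inferences need
replicated monocultures.

## 5. Problem sizes and tolerances used by the checks

Monte-Carlo checks run at reduced designs chosen as the smallest sizes
that are calibrated: recovery and type-I use 6 studies × {1,2,4,8,16} ×
2 plots × 3 years (360 obs, totals only; 200 and 500 replicates), the
AR(1)-vs-CS comparison 4 studies × 6 years (100 replicates), the headline
contrast 5 nutrient + 7 drought replicate pipelines at the headline
configurations. Exactness tolerances: partition identity and scale
invariance 1e-9 relative; noise-free round trip 1e-9; balanced-design REML
vs closed form 1e-6; restricted log-likelihood vs dense evaluation 1e-8;
GLS = OLS 1e-6. The local-optimality of returned REML optima is probed
against 100 random covariance-parameter perturbations.

## 6. Known limitations

- Kenward–Roger denominator df are not implemented; Satterthwaite (with
  containment fallback) is a coarser approximation and every output labels
  the method used.
- The generator cannot produce a complementarity×treatment interaction at
  fixed totals through a uniform ΔRY shift (see §3); mechanisms must go
  through the denominator or the dominance tilt.
- Random effects are independent within and across terms; correlated
  random slopes/intercepts are out of scope.
- Degenerate mixtures (all weights truncated to zero) split the plot total
  equally among sown species and are flagged; they do not occur under the
  default configurations.
- `n_added` and drought duration are study-level constants; within-study
  dose gradients are not modelled.
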