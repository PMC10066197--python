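# Methods

This note documents the statistical model behind `divstab`, the estimation
choices, the synthetic-data generator, and the limits of what the test
suite demonstrates.

## Design and block-level statistics

The data model is a three-level hierarchy: sites contain blocks ("larger
scales", canonically 250 m²), blocks contain plots ("patches", canonically
ten 25 m² plots).  Species cover is censused per plot to the nearest 1%
independently per species, so summed cover may exceed 100% in multilayer
canopies; total live biomass (g m⁻²) is measured per plot.  Blocks with
fewer than two plots cannot support any among-plot statistic and are
excluded; blocks with 2–9 or >10 plots are retained with a flag.

**Diversity.** Alpha-diversity is the mean per-plot richness, gamma the
pooled block richness, both on presence/absence (cover > 0 counts as
present; a recorded cover of exactly 0 is an absence).  Beta-diversity is
the mean distance of the block's plots to their centroid in the
principal-coordinate (PCoA) embedding of the binary Jaccard dissimilarity
matrix.  The embedding keeps axes with negative eigenvalues: squared
distances are accumulated as (real-part sum) − (imaginary-part sum) and
clamped at zero before the square root, matching the standard treatment of
non-Euclidean dissimilarities.  Because the Gower-centered matrix places
the centroid at the origin, each plot's squared distance equals the
corresponding diagonal entry of that matrix — the test suite exploits this
closed form as an independent oracle.  Abundance-based alternatives
(Shannon H = −Σ pᵢ ln pᵢ; inverse Simpson = ENS_PIE = 1/Σ pᵢ²; Ružička
dissimilarity; Whittaker's multiplicative and additive beta) are provided
behind flags.  Two conventions of multiplicative beta are exposed —
alpha/gamma and the textbook gamma/alpha — because sources differ; the
default is alpha/gamma and both can be emitted.  Abundance-based gamma
pools by the mean of per-plot relative covers (a summed-cover pooling is
flag-switchable); the choice is documented here because no convention is
universal.

**Spatial variability.** Per block, µ is the mean and σ the sample
standard deviation (n−1 denominator throughout the package) of plot
biomass; CV = σ/µ is modeled on the natural-log scale.  Blocks with CV = 0
have no defined log and are dropped from log-scale fits; these exclusions
are counted in the run log.

**Species covariation.** With per-species biomass Bᵢ(p) in plot p,

    covariation = Var_p(Σᵢ Bᵢ) / (Σᵢ SD_p(Bᵢ))²,

the spatial analog of temporal species synchrony: Cauchy–Schwarz bounds it
in [0, 1]; it is 1 when all species are perfectly proportional across
plots and 0 under exact compensation.  A variant dividing by the unsquared
Σᵢ SD(Bᵢ) is exposed as `as_printed` for comparison with sources that
print the formula without the exponent; it carries biomass units, is not
bounded by 1, and is never the default.  Since per-species biomass is not
measured, it is proxied by relative cover: Bᵢ(p) = coverᵢ(p)/Σⱼ coverⱼ(p) ×
biomass(p).  Cover is normalized before multiplying because summed cover
can exceed 100%; the proxy then conserves plot biomass exactly.

**Environmental heterogeneity.** Soil C%, N%, P ppm, K ppm, pH and
ambient light are z-standardized over *all* plots in the dataset (not per
block, so the index is comparable across blocks; per-block standardization
would erase exactly the contrast of interest), then each block's
heterogeneity is the mean pairwise Euclidean distance among its plots.
Variables that are constant dataset-wide are dropped with a warning.

## Inference layer

**Mixed models.** Each bivariate relationship (diversity → ln CV,
diversity → covariation, covariation → ln CV, and the µ and σ component
fits) is a linear mixed model with site as the grouping factor.  The
random structure — intercept only vs intercept + slope — is selected by
BIC on REML fits; singular or non-convergent random-slope fits fall back
to intercept-only with a note.  The fixed effect is tested by a 1-df
likelihood-ratio χ² between ML fits with and without the predictor; a Wald
χ² is flag-switchable.  95% CIs use the normal approximation on the fixed
effect's standard error.  MixedLM optimizers occasionally stall short of
the optimum on near-singular problems; fits retry alternative optimizers
and keep the best finite likelihood, and any likelihood-ratio that comes
out negative triggers a thorough refit of both models before the statistic
is clamped at zero.  A response that is an exact linear function of the
predictor leaves no residual variance to estimate; that case is reported
directly as a deterministic fit (infinite χ²).

**Type II regression.** The ranged major axis: both variables are scaled
by their ranges, the slope is the leading eigenvector of the 2×2
covariance matrix of the ranged variables (oriented by the sign of their
covariance), and the slope is back-transformed by the range ratio with the
intercept through the means.  Confidence limits use the closed-form
major-axis angle interval θ ± ½ arcsin(2√H), H = F₀.₉₅(1, n−2)·λ₁λ₂ /
((n−2)(λ₁−λ₂)²), computed on the ranged variables and back-transformed;
when the arcsine argument leaves its domain the interval is unbounded.
Because a type II fit has no random effects, these fits (and the climate
residualization feeding them) use site-mean values to avoid
pseudoreplication.

**Climate residualization** is an OLS multiple regression of site-mean
log CV on MAT, MAP, temperature range, temperature SD, precipitation CV,
and mean temperature of the wettest four months; the residuals are then
regressed on diversity by RMA.  Constant covariates are dropped with a
warning; exact collinearity raises an error naming the aliased columns.

**AIC all-subsets.** Every admissible combination of candidate terms
(interactions only alongside both main effects) is fit by OLS and ranked
by AIC with ΔAIC and Akaike weights; AICc is flag-switchable.  The
exhaustive enumeration refuses more than 12 candidate terms.

## Piecewise SEM

The path diagram is declared in a plain-text config (`a -> b` edges,
`a ~~ b` correlated errors, `group:` factor); the packaged observational
diagram routes alpha, beta, and gamma diversity to ln CV directly, through
mean biomass µ (the overyielding route), and through species covariation
(the insurance route), with alpha~~gamma and alpha~~beta as correlated
errors.  When soil data are present a heterogeneity node is added acting
on beta-diversity.

Each endogenous node is fit by a mixed model on its parents with a site
random intercept (intercept-only throughout, matching the random structure
the bivariate layer selects).  Standardized coefficients are raw × SD(x) /
SD(y) on the complete-case data.  Correlated errors are Pearson
correlations — of the raw variables when both are exogenous, of component-
model residuals otherwise — and are reported, not interpreted causally.

**d-separation.** The basis set contains one claim per non-adjacent pair
(no directed edge either way, not a correlated-error pair): the later
variable in (lexicographic) topological order is regressed on the union of
both variables' parents plus the claimed-independent variable, whose
two-sided p-value (normal approximation on the mixed-model coefficient)
tests the claim.  Claim p-values are floored at 1e−300 against log
underflow; exact zeros are rejected by `fishers_c` itself.  Fisher's
C = −2 Σ ln pᵢ is referred to χ² with 2k df; an empty basis set is a
vacuous perfect fit.  How p-values for mixed-model coefficients should be
computed is genuinely open (t-as-z vs degree-of-freedom corrections); the
normal approximation is used and noted here — with hundreds of blocks the
difference is negligible, and the calibration test below checks the
consequence that matters.

**R².** Marginal R² = var(fixed) / (var(fixed) + var(random) +
var(residual)); conditional R² adds the random-intercept variance to the
numerator (the variance-partition formulas for mixed models).

**Simplification** (off by default, flag-switchable): iteratively remove
the least-significant non-significant path, refit, and keep the change
only if the summed component-model BIC decreases; stop when every path is
significant or no candidate drop improves BIC.  A node that loses its last
parent keeps an intercept-only component model so the BIC sum stays
comparable.  The audit trail records every drop, and dropped + retained
always equals the initial edge count.

**Multigroup comparison.** For two phases (ambient vs enhanced
heterogeneity), every component model is refit on the stacked data with a
model-wide phase interaction.  Paths whose interaction term has p ≤ 0.05
are "free" (phase-specific estimates); all others are "constrained" to the
global estimate, whose standardized value still differs between phases
because each phase standardizes by its own SDs.  Per-phase Fisher's C is
reported alongside.

## Synthetic metacommunity

The generator exists to provide ground truth the field data cannot: known
niche structure, known treatment effects, and a dial for the insurance
mechanism.

Each site draws a species pool uniformly from `pool_size_range`
(default 5–50, creating the among-site diversity gradient).  Each plot has
a scalar latent environment e = block mean + N(0, h), block means
N(0, 0.5) within a site; h (`env_sd_within_block`, default 1) is the
patch-scale heterogeneity.  A fraction `insurance_strength` of the pool
has niche optima dispersed uniformly on [−2.2, 2.2]; the rest sit at the
center.  Expected cover is a Gaussian niche response with breadth w
(default 0.6) and peak 30%, multiplied by lognormal noise (σ = 0.5) and
recorded to the nearest 1% as in field protocols — rounding is what makes
rare species genuinely absent and gives presence/absence indices realistic
behavior.  Plot biomass is 3 g m⁻² per summed cover percent with 20%
Gaussian noise, truncated at zero — roughly 100–2000 g m⁻², the observed
range in global grasslands.  Soil variables and light are noisy linear
readouts of the latent axis; site climate covariates are drawn
independently of everything (they exist to exercise the residualization
code, not to model climate).

`apply_treatments` assigns the ten factorial treatments (control, N, P,
Kmu, NP, NKmu, PKmu, NPKmu, fence, fence+NPKmu) randomly within each
block.  Each added nutrient shifts the plot's latent environment by its
own amount (N +1.2, P −0.9, Kmu +0.5) so that distinct nutrient
combinations create distinct patch niches and among-plot environmental
variance rises; shifted plots re-express the niche model at the new
environment with fresh noise, while unshifted plots keep their observed
community (so an all-identity configuration is a strict no-op).
Fertilization removes each species with a treatment-specific probability
(biomass reduced pro rata), biomass is scaled by the treatment multiplier
(1.0–1.6, largest for fenced +NPKmu), and the added nutrients are written
into the soil readouts of fertilized plots — without this the
z-standardized heterogeneity index barely responds to treatment.

With dispersed optima under heterogeneity, these mechanics *produce* (not
encode) the target phenomenology: richer sites cover the environmental
axis better, species compensate across patches, covariation falls, and the
spatial CV of biomass falls with alpha-diversity; treatments raise µ, σ,
CV, beta-diversity and heterogeneity while lowering alpha; and the
alpha→covariation link weakens after treatment.

What the generator does not emulate: multivariate environmental axes,
spatially explicit distance or dispersal, temporal dynamics, taxonomic
structure, and observer error beyond the 1% rounding.  Passing recovery
tests therefore show the inference chain is correct and adequately
powered under a faithful one-axis metacommunity — not that the field
data meet the model's assumptions.

One limit worth stating: when all species share one optimum and h = 0,
the only among-plot variation is the per-(plot, species) lognormal noise,
and the covariation statistic of the cover-proxy necessarily sits low
(≈ CV²_biomass / (CV²_biomass + CV²_relcover) ≈ 0.15–0.2) rather than near
1 — species cannot "respond in unison" to an environment that does not
vary.  The high-covariation regime requires shared responses to actual
heterogeneity (insurance 0, h > 0), and that is what the tests assert.

## Numerical and procedural choices

- Sample (n−1) denominators for every variance and SD.
- Eigenvalues below 1e−10 of the spectral radius are treated as zero in
  the PCoA embedding.
- A soil variable is "constant" when its SD is below 1e−12 of its mean's
  magnitude (guards float rounding on constant columns).
- Treatment labels are ASCII (`Kmu` etc.); readers normalize the
  micronutrient "μ" spelling on input.  Taxa are matched by exact
  case-normalized string; no synonym resolution.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; the analysis chain itself is deterministic,
  and two runs with the same config hash to identical output files.

## Test-suite problem sizes

Calibration and recovery tests run at the scale the corresponding claims
are made for: d-separation calibration uses a 4-node chain at n = 300
(30 groups × 10) over 500 replicates with the rejection band [0.02, 0.09];
slope and SEM-path recovery use 40 sites × 3 blocks over 100 seeds;
multigroup detection uses a 4-node, 4-path diagram over 100 seeds — with
many more paths the compounded 5% per-path false-positive rate would make
"every unchanged path stays constrained" an unreasonable joint criterion
at any implementation quality.
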