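# Methods

This note records the statistical model behind `epiland`, the conventions and
numerical choices where more than one defensible option existed, what the
synthetic-data generator does and does not emulate, and known limitations.

## Measurement model and fitness estimation

A competition assay inoculates a competitor genotype and a fixed fluorescent
reference strain at roughly equal densities and measures all four densities
(competitor/reference × initial/final) by flow cytometry after one ~20 h batch
growth cycle.  The competitive index

ŵ = ln[(D_comp^f / D_ref^f) / (D_comp^i / D_ref^i)]

is dimensionless, zero for a competitor growing exactly like the reference,
antisymmetric under swapping the two strains, and invariant to dilution (any
common rescaling of the four densities).  Densities are accepted as positive
reals (events per volume); zero or negative values are rejected rather than
pseudocounted, because the measurement model supplies no pseudocount scale.

Replicates are aggregated as unweighted means of per-replicate indices — not as
the index of pooled counts — with SE = sample SD/√n.  That matches how such
data are reported (mean ± SE over n = 3–4 replicates) and keeps each replicate
an exchangeable unit for the bootstrap.  Cells with n = 1 have an undefined SE;
when bootstrap inference needs a spread for such a cell it receives the median
SE of the other cells in the same environment and is flagged (`se_imputed`).
The two dye orientations (competitor-GFP vs competitor-mCherry) are pooled by
default *after* the dye-swap check passes; pooling is a switch because marker
neutrality is an empirical conclusion, not an assumption.

The dye-swap check pairs orientation-wise mean indices per genotype ×
environment cell, regresses the GFP index on the mCherry index, and adds
environment and genotype factors as incremental F-tests.  A neutral marker
gives slope ≈ 1, intercept ≈ 0, and no significant factor effects.

## Epistasis statistics

**Pairwise epistasis.**  ε = w_AB − w_A − w_B + w_WT per four-genotype slice.
Translation-invariant; scales linearly with fitness units.

**Gamma.**  For each focal mutation m and each background g carrying neither m
nor the other-locus mutation d, the ordered pair (s_m(g), s_m(g ⊕ d)) is
formed; pairs are pooled across all focal mutations of the requested class
(all / ABR / KO) and summarised by a single Pearson correlation.  In the
two-locus design the shared background is necessarily wild type at the
non-focal locus, so pairing has no remaining freedom.  The per-class variant
restricts the *focal* mutation only; the added mutation d always comes from the
other locus.  Degenerate case: zero variance in either pooled vector returns 1
when the vectors are element-wise equal (a perfectly additive landscape) and
NaN otherwise.  Alternative normalisations of background-averaged epistasis
correlations exist; the pooled-Pearson choice is isolated in one function so it
can be swapped.

**Sign classification.**  With s_A0 = w_A − w_WT, s_A1 = w_AB − w_B (and
symmetrically for B), locus A changes sign iff s_A0 and s_A1 are nonzero with
opposite signs.  Reciprocal = both loci change; simple = exactly one.
Comparisons use point estimates with exact zeros carrying no sign (a tolerance
is available but defaults to 0): statistical uncertainty enters *only* through
the bootstrap layer, where each resample is re-classified and a slice is
"detected" for a category occurring in > 5% of samples.  Fractions are
reported as the mean over bootstrap samples with a percentile CI.

**Roughness-to-slope.**  OLS of the four fitness values on (intercept, ABR
indicator, KO indicator); roughness = RMS residual with the divisor n = 4 (with
4 points and 3 parameters any df-corrected convention is a constant multiple of
this one — the n-divisor makes the closed form exact: roughness = |ε|/4);
slope = mean of the |coefficients| of the two indicators, absolute values
because signed slopes would cancel meaninglessly.  The ratio is 0 for additive
slices, scale-invariant, ∞ when a nonzero ε sits on an exactly flat fitted
plane, and 0/0 (a completely flat landscape) is defined as 0.  Fitted slopes
that are exactly zero emerge from `lstsq` as ~1e−16, so a relative tolerance of
1e−12 distinguishes the flat cases.

**Diminishing returns.**  Per environment and mutational class, effects are
regressed on the fitness of the background carrying them, pooled across the
class's mutations into one regression (one line per environment).  The slope is
averaged over bootstrap samples with a percentile CI; significant iff the CI
excludes 0.  `exclude_backgrounds` supports sensitivity analyses such as
dropping a hypersusceptible knock-out.

## Inference

**Parametric bootstrap.**  Each genotype × environment cell is redrawn
independently from Normal(ŵ, SE).  Normality of a mean of log-ratios is the
standard large-sample approximation and makes the generator's lognormal
measurement noise exactly well-specified.  B defaults to 1000; tests use
200–500 for runtime.  Streams are bit-reproducible under a fixed seed.
Percentile CIs use order-statistic quantiles (no interpolation), which makes
them exactly equivariant under monotone transformations of the metric.  BCa or
studentised intervals are deliberately out of scope.

**Trends.**  Per-environment metrics are regressed by OLS on antibiotic
concentration (continuous, µg/ml), temperature, or the environmental-quality
score; the slope's F-test and adjusted R² are reported.  Significance is
α = 0.01 throughout.  Environmental quality defaults to the mean over all
competitor strains and replicates of ln(final/initial competitor density);
reference-strain and combined-growth variants are selectable, since which
growth summary best orders environments is itself an empirical question.

**Cost of resistance.**  In antibiotic-free environments, the contrast
w(abr, ko) − w(WT, ko) per (background, ABR allele, temperature), with a
percentile bootstrap CI; a cost is flagged only when the CI lies entirely
below zero.

**Nested models.**  Per-replicate indices (not cell means) are the response, so
residual degrees of freedom reflect true replication (~996–1152 rows on the
full design).  Genotype factors are treatment-coded against the wild type;
temperature, an ordered three-level factor, gets orthogonal polynomial
contrasts (linear ∝ (−1,0,1), quadratic ∝ (1,−2,1), orthonormal); antibiotic
concentration is an unordered factor by default (level-wise interaction
coefficients) and continuous as a switch.  Model comparison uses
F = ((SSR_red − SSR_full)/Δdf)/(SSR_full/df_full) after verifying, by
projection, that the reduced design lies in the full design's span.  Fitted
values are invariant to the coding; only coefficients change.  Second-order
(G×G×E) terms are constructible through `ModelSpec`, but no automated model
selection is provided — a deliberate non-goal, as such searches overfit at this
design size.

## The synthetic-data generator

True fitness is w(g, e) = a_ABR(g, e) + a_KO(g, e) + i(ABR, KO, e) minus the
same sum for the reference genotype (*rpoB* H526Y by default), so the
reference's own index is exactly 0 and each slice's true ε equals its
interaction term.  Counts are emitted as inoculum × lognormal noise per
channel; the reference channel grows by a per-environment growth factor, the
competitor channel additionally by exp(w_true).  The resulting per-replicate
index is w_true + (final-channel noise difference), i.e. index SD =
noise_sd·√2 — noise on initial densities cancels exactly, mirroring how the
ratio estimator absorbs inoculum variation.  Consequently a cell SE is
noise_sd·√2/√n and a single-mutant *effect* SE is noise_sd·2/√n (≈ 0.058 at the
default noise_sd = 0.05 and n = 3).

Defaults mirror the study design: 4 *rpoB* alleles × 6 knock-out states,
{0, 4, 8, 10} µg/ml × {37, 40, 42} °C, 3–4 replicates per cell (fixed at 4 in
the `paper_like` scenario), noise_sd = 0.05 on each density channel.  One dye
orientation is emitted per replicate, alternating within a cell, so the cell
replicate count matches the 3–4 of the design while the dye-swap check still
finds pairs; `both_orientations=True` doubles the records, and a `dye_bias`
knob injects a marker effect for power-testing the neutrality check.

Scenario effect scales were chosen from the design algebra, once:

* scenarios meant to be *additive* use baseline effects of at least ~3 effect-SEs
  (min |effect| 0.18), so that a landscape intended as additive is not dominated
  by bootstrap sign flips of near-zero effects;
* `reciprocal_sign_at_zero_ab` injects i = −1.0 (≈ 17 effect-SEs) on the five
  I572S slices at 0 µg/ml only;
* `diminishing_returns` injects slope −0.4 with equal ABR baselines, making the
  pooled regression a single-intercept line so the injected slope is recovered
  without pooling bias;
* `paper_like` combines a strong ABR dose response (effects 1–4 at ≥ 4 µg/ml
  that overshadow knock-out effects in [−1, 0.2]), a knock-out hypersusceptible
  at 4 µg/ml whose extra cost is masked on ABR backgrounds, weak-allele
  reciprocal-sign interactions at 0 µg/ml, and interactions decaying
  exponentially with concentration — landscapes smooth out as antibiotic rises.

What the generator does **not** emulate: growth-curve dynamics (lag,
saturation — the cycle is one growth factor), density-dependent or frequency-
dependent competition, cytometry gating artefacts, non-lognormal outliers, or
batch/day effects shared across cells.  Passing tests therefore demonstrate
correctness of the estimators and calibration of the inference under the
stated measurement model, not robustness to structured experimental artefacts
in real data.

## Problem sizes in the test-suite and acceptance script

Monte-Carlo checks use 20 seeds for scenario discrimination and parameter
recovery (with B = 300–500 bootstrap samples), 200 simulated datasets for CI
coverage, 500 replicates for the nested-F null calibration, and 100 simulations
for dye-swap coverage — sizes at which the binomial tolerance on each check is
comfortably below the margins asserted, while a full run stays in the minutes
range on one CPU.

## Known limitations

* The Normal(ŵ, SE) bootstrap understates uncertainty for n = 3–4 if the true
  replicate distribution is heavy-tailed; coverage is verified under the
  generator's own noise model only.
* Gamma pools pairs that share background cells, so pairs are not independent;
  the bootstrap CI accounts for measurement error but the point statistic still
  dilutes class-specific signal as landscapes grow (a known property of
  background-correlation statistics).
* The exact-zero sign convention means a mutation with a true zero effect is
  classified "no sign change" at the point estimate; detection of its sign
  behaviour is meaningful only through the bootstrap rule.
* Environments are modelled as a complete grid; partially observed grids are
  rejected rather than imputed.
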