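# Methods

## Data model and processing rules

A raw record is one core × depth stratum with five sorted fraction masses
(mg) and a skeletal soil volume (cm³) measured by displacement. Processing
follows the field protocol exactly:

1. **Fragment allocation.** Short (< 1 cm) absorptive-category fragments
   are subsampled from a fraction `tray_fraction` of the sorting-tray area
   (default 0.10, i.e. the classic ×10 scaling); the scaled-up total is
   split between the absorptive and dead fractions in proportion to their
   sorted masses. When both sorted masses are zero the rule is 0/0; we
   assign all fragment mass to the absorptive fraction, since fragments are
   defined as absorptive-category material. Mass is conserved exactly:
   adjusted absorptive + dead = sorted absorptive + dead + tray mass /
   tray_fraction. Transportive and coarse fractions pass through untouched.
2. **Pooling.** Fraction masses and soil volumes are summed over the cores
   of a plot per stratum. A plot missing a stratum that other plots have is
   a hard error (a gap, not a zero).
3. **Density.** Each fraction's density is (fragment-adjusted) mass over
   pooled volume, mg cm⁻³. Soil volume always comes from the record; the
   cylinder formula π(d/2)²·thickness is only the synthetic generator's
   default, never imposed on measured data.

**Weighted mean rooting depth** is the mass-weighted mean of stratum
midpoints. From a density table, stratum mass is density × stratum
thickness (per unit ground area; the areal constant cancels). The bottom
stratum is 10 cm thick against 5 cm for the others, so this thickness
weighting is required — dropping it biases the mean shallow by pulling
weight away from the 20–30 cm stratum. An all-zero profile raises an
error rather than returning a fictitious 0 cm. The result is clipped to
[first midpoint, last midpoint] to absorb floating-point roundoff at the
degenerate point-mass profiles.

## Plasticity indices

All four indices use sample (n−1) standard deviations, including the
two-value CVm (SD of two values = |m₁−m₂|/√2), matching the default of
the statistics environments the field uses. Treatment means are unweighted
means over the replicate plots of an arm; missing plots reduce n with a
warning rather than being imputed. Indices are unit-agnostic but negative
trait values are rejected. Degenerate inputs raise explicit
`UndefinedIndexError`s: both means zero (PIv), zero mean (CV, CVm), zero
CV (PI:CV).

Useful identities, used as test oracles: for two treatment means,
CVm = √2·|m₁−m₂|/(m₁+m₂) = √2·PIv·max(m₁,m₂)/(m₁+m₂); with a noise-free
treatment multiplier τ ≥ 1, PIv = 1 − 1/τ.

## Bootstrap regression

"Resampling before and after calculating the index" is implemented as:
resample raw plot values with replacement (before), recompute treatment
means and the index per iteration (after). The alternative reading —
resampling the six species-level index values themselves — cannot produce
1000 distinct values per species and was rejected. Resampling is
stratified within treatment arm so no iteration has an empty arm (PIv
would be undefined). Each iteration is paired with the mean biomass of an
independently resampled set of the species' plots across both arms;
`paired_biomass="fixed"` substitutes the plain species mean. The pooled
species × iteration cloud (default 6 × 1000 points) is fit by unweighted
OLS with a 95% slope CI; one model per index × trait. Species centroids
(point-estimate index, mean biomass) are carried alongside as diagnostic
anchors and are guaranteed to equal the plasticity module's output on the
same inputs. No BCa or studentized intervals are attempted.

## Mixed models and Type-III tests

* **Absorptive density**: LMM on log(x+1)-transformed density (natural
  log; slopes read as proportional effects on density+1) with
  species × depth × treatment fixed effects (all interactions), a block
  random intercept and plot-level random intercepts as a variance
  component. If that structure fails to fit, the ladder drops the plot
  component, then falls back to OLS; the structure actually used is
  recorded in the fit metadata. The full random-slope structure
  (interactions within block and plot) is overparameterised at 48 plots
  and is not attempted.
* **Dead density**: values ×10 and rounded **half-up** to integers
  (`floor(10x + 0.5)`; the rounding convention is centralised in
  `transform_dead_counts`), then fit as a Poisson regression with the same
  fixed-effect structure plus block as a fixed covariate. This is a fixed-
  block Poisson GLM rather than a Poisson GLMM: no frequentist Poisson
  mixed model is available in the Python stack this package builds on, and
  block-as-fixed absorbs the dominant grouping. Plot-level extra-Poisson
  variation is therefore not modelled — X² values for within-plot terms
  should be read as anti-conservative. Wald X² per term.
* **Rooting depth**: Box-Cox transform (maximum-likelihood λ via profile
  optimisation; λ=0 ≡ log) then an LMM with species × treatment fixed
  effects and a block random intercept. No plot term: depth is one value
  per plot.

Type-III tables use sum-to-zero contrasts and joint Wald tests on the
fixed effects. Denominator degrees of freedom follow the split-plot
partition: terms varying only between plots (Species, H₂O, Species × H₂O)
are tested against plots − between-plot parameters (48 − 12 = 36 in the
default design); terms involving soil depth against observations − fixed
parameters. This is a deliberate approximation to Satterthwaite df that
keeps the between-plot tests honestly sized with only four blocks.

Post-hoc high-vs-low contrasts are computed per species (× stratum) from
the fitted cell means and adjusted with **Holm** within each stratum's
family of six species contrasts. The family-wise intent matches a
Tukey/multivariate-t adjustment; Holm was chosen because the contrast
family here is not the all-pairwise set that Tukey's method covers and no
multivariate-t machinery is available in the stack.

A pairwise Pearson correlation report (`correlation_report`) with an
|r| ≥ 0.5 flag replaces visual scatter-matrix screening for collinearity.

## Synthetic generator

The generator's mean structure is
`density(sp, s, arm) = d₀(sp) · exp(−k(sp)·mid_s) · [τ_s(sp) if high]`,
with log-normal multiplicative effects at block, plot and core level
(median parameterisation: zero noise reproduces the mean exactly).
Dead-root density reuses the same machinery scaled by a per-stratum dead
fraction; transportive and coarse fractions are fixed ratios of the live
mean with their own core noise. Fragment tray mass is generated as
`fragment_mass_fraction × (absorptive + dead) × tray_fraction`, so
fragment allocation downstream rescales all plots proportionally and
leaves the plasticity indices unchanged. Biomass is log-normal per plot
around a species median, independent of treatment.

Default parameters are illustrative, not fitted: conifer surface densities
(9–11 mg cm⁻³) exceed broadleaf ones (4.5–6), depth decline is strong
(double-to-triple order of magnitude over 30 cm at the default decay
rates), the slow-growing species (As, Pg; biomass medians 1.2 kg and
0.9 kg) carry large topsoil multipliers (1.65, 1.9), and the fast growers
(Bp, Ll; 6 kg and 5 kg) carry declining multiplier gradients that shift
their high-water profiles shallower. These choices encode the study
system's qualitative pattern — topsoil-density plasticity falls with
aboveground biomass while rooting-depth plasticity rises with it — and the
default noise SDs (block 0.15, plot 0.20, core 0.25 on the log scale) are
field-plausible guesses; within-plot variance is not constrained by any
published value and is fully overridable.

What the generator does **not** emulate: within-plot spatial core
placement, soil texture and plough-pan effects, root turnover and
decomposition dynamics, treatment effects on biomass, and any real
allometry behind the biomass values. Tests passing on synthetic data
therefore demonstrate the correctness of the computational chain and its
statistical calibration under the assumed generative model, not field
validity of the defaults.

## Numerical and testing choices

Simulation-based checks are sized to run on one CPU in seconds to a couple
of minutes: 20 seeded runs for the slope-direction pattern, 100
permutation replicates for the H₂O false-positive rate, 200 replicates for
slope-CI coverage, 10,000-draw property sweeps for conservation/bounds.
The "noise-free" ANOVA recovery check uses near-zero (0.02) noise SDs:
with exactly zero noise the saturated fixed-effect model has zero residual
variance and no F statistic exists. Bootstrap enumeration oracles use 2
plots per arm, where all 2²×2² with-replacement resamples can be listed
exhaustively.

## Known limitations

* The Poisson dead-root model omits plot-level random variation (see
  above).
* Wald-based Type-III tests with 4 blocks are asymptotic; the permutation
  check bounds the H₂O false-positive rate near nominal for the default
  design, but other designs should re-run that check.
* PIv on a trait whose treatment means are both near zero is numerically
  unstable; the indices refuse all-zero arms rather than guessing.
* The pipeline assumes every core reaches full depth; partially filled
  cores must be pre-corrected via their measured soil volumes.
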