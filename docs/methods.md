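# Methods

## The model

Leaf net CO₂ assimilation Aₙ (µmol CO₂ m⁻² s⁻¹) responds to CO₂
concentration (ppm) as a three-parameter asymptotic regression:

    Aₙ = c + (d − c) · (1 − e^(−CO₂/b))

* **c** — Aₙ at zero CO₂. Negative under respiration-dominated conditions
  (always negative in the tomato-leaf parameter range this package ships).
* **d** — the horizontal asymptote: maximum attainable Aₙ as CO₂ → ∞.
* **b** — a CO₂ scale in ppm; 1/b is proportional to the relative rate at
  which the curve approaches its asymptote. Large b (≈1265 at 90 µmol m⁻²
  s⁻¹ PPFD) means the response is nearly linear over the measured
  200–900 ppm range; b around 200–340 gives visible saturation.

The experiment behind the parameter tables crosses ten LED spectrum mixes
(three monochromatic B/G/R, six 80/20 binary mixes, one trichromatic
solar-like 37R36G27B) with seven light intensities (30–1000 µmol m⁻² s⁻¹
PPFD). Each of c, d, b is decomposed additively, **on the natural scale**,
into an intercept at the reference cell (37R36G27B × 350) plus one offset
per non-reference intensity and one per non-reference spectrum — 16 free
coefficients per curve parameter, 48 fixed effects in all. Intensity is a
categorical factor: the seven levels get free offsets, no functional form
in PPFD is assumed.

The stochastic part is hierarchical. Plants are nested in spectra (three
plants per spectrum); each plant j carries a Gaussian shift u_j ~ N(0, σᵤ²)
on its asymptote d, and each reading has residual noise e ~ N(0, σ²_I)
with one free SD per intensity level (gas-exchange noise grows with flux,
so homoscedasticity would be wrong). Because u enters the mean linearly
through the saturation weight g = 1 − e^(−CO₂/b), a plant's readings have
marginal covariance

    Σ_j = diag(σ²_I) + σᵤ² g gᵀ,

diagonal plus rank one. The marginal log-likelihood is evaluated with the
rank-one determinant and inverse identities; no dense per-plant covariance
matrix is formed in production code (a dense multivariate-normal oracle
exists in the test suite and agrees to ~1e-13).

## Estimation

Plain maximum likelihood (not REML), matching how this model family is
conventionally fit with nonlinear mixed-model software, and because ML
composes cleanly with Wald contrasts. The optimizer is L-BFGS-B over the
48 fixed effects plus log σᵤ and the seven log residual SDs, with the
search space rescaled by max(1, |θ₀|) per coordinate so the b offsets
(hundreds of ppm) condition the quasi-Newton updates equally with
unit-scale coefficients. Gradients are analytic (chain rule through the
rank-one form); a batched central-finite-difference gradient is retained
as `FitConfig(gradient="fd")` and the two agree to ~1e-7 relative in the
test suite. Convergence uses L-BFGS-B's relative-f and projected-gradient
criteria (ftol 1e-10, gtol 1e-5); hitting the iteration cap returns a
flagged partial result instead of raising.

Starting values come from cell-wise least squares: per (spectrum,
intensity) cell, a logarithmic grid over b (50–5000 ppm, 160 points, with
a bounded local refinement between neighbouring grid points) and a
closed-form linear solve for (c, d) given b — the mean is c(1−g) + dg,
linear in (c, d). The 70 cell triples are then projected onto the additive
main-effects space by least squares. If the projection leaves some
assembled b non-positive (possible when noisy low-light cells rail), the
b intercept is shifted up uniformly — a transformation that preserves
every contrast and restores positivity. Residual SDs start at per-intensity
RMS residuals; σᵤ starts at the SD over plants of each plant's g-weighted
mean residual.

b positivity during optimization is kept by a large finite penalty when
any assembled b falls below a floor (10⁻³ ppm); with the cell-wise start
the optimizer never visits that region in practice.

Standard errors come from the inverse of a central-finite-difference
Hessian of the analytic gradient at the optimum (step 1e-4 relative),
i.e. the observed-information Wald covariance. No Kenward–Roger or
Satterthwaite correction and no degrees-of-freedom adjustment are applied.

### Pairwise comparisons and letters

Marginal summaries (d and b per intensity at the reference spectrum, and
per spectrum at the reference intensity) are compared all-pairwise with
Wald z statistics. The default multiplicity adjustment is the Tukey-style
studentized-range approximation — |z|·√2 referred to the studentized range
of k means with infinite df — matching the convention of
estimated-marginal-means software; Bonferroni and unadjusted are options,
as is a finite-df t reference. Letters are assigned by the standard
insert-and-absorb algorithm, alphabetical from the smallest estimate, ties
broken by factor-level order.

### Diagnostics

Residuals are conditional: each plant's u is replaced by its BLUP
(σᵤ² gᵀΣ⁻¹r via the same rank-one identity) before standardizing by the
fitted SD of the reading's intensity stratum. Normality is summarized
numerically — QQ-plot correlation, skewness, excess kurtosis — with no
accept/reject verdict.

## The synthetic-data generator

`protocol_sequence()` reproduces the measurement protocol exactly: CO₂
stepped 200→900 ppm in 100-ppm triplicate steps, direction alternating
between consecutive intensity blocks as the cuvette is stepped up through
30, 90, 200, 350, 500, 700, 1000 µmol m⁻² s⁻¹ — 56 conditions, three
readings each, 168 readings per plant, 5040 per full experiment.

`simulate_experiment` draws one u per plant and adds it through the same
g(CO₂; b) weight the estimator assumes, so simulation and fit are exactly
conjugate — the property that makes parameter recovery a fair test of the
estimator rather than of model misspecification. Readings are simulated
as equilibrated: no ramp lag, drift, or autocorrelation within a
condition. One named RNG per call, seeded explicitly; plant-level draws
are consumed before observation-level draws in deterministic order, so a
seed fixes the dataset byte-for-byte.

Defaults are the study design: the bundled parameter reconstruction as
truth, 3 plants per spectrum, σᵤ = 0.7 µmol m⁻² s⁻¹, residual SDs rising
0.3 → 0.8 from 30 to 1000 PPFD. The variance components are this
package's choice (plausible for a CIRAS-class gas-exchange system, noise
growing with flux); the source tables print no variance components, so
recovery can only be judged against synthetic truth. What passing
recovery tests show is therefore internal consistency of
generator + estimator under Gaussian assumptions — not robustness to
instrument drift, ramp artefacts, or non-Gaussian noise, none of which
the generator emulates.

`perturb_truth(truth, scale)` rescales every treatment offset; scale 0
yields a null generator (all cells identical) used to measure the false
positive rate of the letter stage: 20/900 spectrum pairs (2.2%) declared
different at α 0.05 under Tukey adjustment over twenty replicates.

## The bundled parameter table

`load_reference_effects()` ships the published 10 × 7 parameter table in
baseline + offset form. Two printed c rows (spectra 80B20G and 80G20R)
are typographically corrupted in the source (they form arithmetic
sequences incompatible with the table's own additive structure); they are
reconstructed from the per-spectrum additive shift column (+0.51, −0.01),
and the reconstruction — not the printed rows — reproduces the published
scenario grid (e.g. Aₙ = 6.03 at 80B20G, 350 PPFD, 400 ppm). With this
table the package regenerates all 210 published Aₙ scenario cells within
±0.01 and all 210 relative increments within ±1 percentage point.

The published PLUE grid reproduces within ±0.02 everywhere except the
90-PPFD column (12 cells off by 0.03–0.10), where b ≈ 1265 amplifies the
2-dp rounding of the printed parameters beyond what any reconstruction
from printed precision can recover, and one internally inconsistent
published cell (80R20B at 30 PPFD / 400 ppm prints 25.12 although its own
Aₙ value of 1.19 implies ≈39.8). These are irreducible properties of the
printed tables, not of the pipeline.

## Derived metrics

Scenario grids evaluate the mean curve at 200/400/850 ppm (CO₂-starved,
atmospheric, carbon-fertilized greenhouse). Relative increments are
100·(Aₙᵢ − Aₙ_ref)/Aₙ_ref against the solar-reference cell at 400 ppm.
PLUE (photosynthetic light-use efficiency, mmol CO₂ per mol photons) is
computed as 1000·Aₙ/PPFD — the secant slope from the origin, which is
exactly how the published efficiency grid relates to the published Aₙ
grid; a fitted Aₙ-vs-PPFD slope would be a different quantity. All
chained computation uses unrounded values; display rounding is half away
from zero, two decimals for Aₙ and PLUE, integers for percent increments
(the published 49.5% → 50 confirms rounding happens after the ratio).
Negative PLUE at low light is meaningful (respiration exceeds fixation)
and is never clamped.

## Known limitations and numerical notes

* **ML small-sample bias.** With only 3 plants per spectrum, 10 of the 48
  fixed effects absorb plant-mean directions and plain ML estimates σᵤ²
  with an (n−p)/n-type downward bias (≈ 0.33 recovered vs 0.49 generating
  over 60 replicates). Wald SEs of d coefficients are deflated ~20% as a
  consequence (pooled 95% interval coverage ≈ 0.89), a property of the
  estimator — an R `nlme` ML fit of the same data reports the same σᵤ and
  SEs — not of the implementation. REML would reduce the bias but is
  deliberately out of scope. Point estimates are unbiased (mean recovered
  d at the reference spectrum / 700 PPFD: 11.93 over 60 replicates,
  generating value 12.01).
* The 90-PPFD b (≈1265 ppm) is weakly identified from data capped at
  900 ppm CO₂ (saturation weight ≈ 0.5 at the sweep's top); its cell-wise
  estimates are noisy and the start-value repair above exists for this
  reason.
* σᵤ = 0 inputs are carried internally as a 10⁻⁶ floor on the log scale;
  exact-zero-variance likelihoods agree with the closed form to ~1e-9
  absolute rather than machine precision.
* Degenerate inputs: cells with fewer than three distinct CO₂ levels are
  rejected by name; d ≤ c (a non-increasing curve) warns but does not
  raise, since shade-level fits can legitimately approach it.
* The letter algorithm's output depends only on the significance pattern;
  with an empty pattern all levels share "a".

## Problem sizes used

Simulation studies in the test suite and the analysis scripts use the
full 5040-row design per replicate and 20 replicates per study; a single
ML fit takes on the order of a second, a 20-replicate study about a
minute. The likelihood-oracle comparison uses 100 random datasets of up
to ~50 observations.
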