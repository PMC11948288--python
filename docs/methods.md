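# Methods

This note documents the models, numerical choices and limitations behind
`lifegap`. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## The estimand

The pipeline targets an ecological summary of health inequality: the fitted
difference in period life expectancy at birth (e₀) between areas at the
extremes of a metric deprivation index. Per sex and 3-year window, area e₀
values are regressed on the index by unweighted ordinary least squares.
Because the index is min–max normalised to [0, 1], the regression
coefficient β₁ is the average e₀ difference across the full deprivation
range; the reported gap is −β₁ (positive when deprived areas fare worse),
and the fitted values at index 0 and 1 are the endpoint life expectancies.
This is the slope-index-of-inequality construction specialised to life
expectancy, using every area's value rather than quantile groups — which is
why it yields a larger figure than quintile contrasts would. It describes
areas, not individuals: no individual-level (causal) interpretation is
licensed.

Unweighted OLS is the default because every area is a unit of observation
of the place-based estimand; a population-weighted fit
(`SlopeIndexOfInequality(weighted=True)` with person-years as weights) is
available for sensitivity analysis.

## Abridged life tables

* **Age schema**: 0, 1–4, 5–9, …, 80–84, 85+ (19 bands). Configurable via
  `AgeSchema`; edges must be integers so they align with the quadrature
  grid of the generator.
* **Pooling**: deaths and person-years are summed separately over the 3
  calendar years of each window, per band; the central rate is m = D/PY.
  Windows move in 1-year steps (2003–2005, 2004–2006, …), so a 20-year
  range yields 18 windows. A cell missing any year or band is a
  completeness error, never silently imputed.
* **Rate→probability**: Chiang's q = n·m / (1 + (n − aₓ)·m), capped at 1.
  Separation fractions aₓ: 0.3 y for the infant band (infant deaths
  concentrate early), width/2 elsewhere; configurable per band.
* **Open interval**: L = l/m (constant-hazard closure). m = 0 there with
  survivors present is a degenerate-input error. A closed band with
  D = PY = 0 gets m = 0, q = 0 (explicit survival, not NaN).
* **Radix** 100 000 for reporting; e₀ is radix-invariant (tested).

## Deprivation index

* Indicators are z-scored across areas (population sd). Correlation-based
  PCA is the conventional choice for indicators on unrelated scales.
* Within each dimension the first principal component of its three
  indicators is extracted; weights are the squared loadings normalised to
  sum to 1. Squared loadings (explained-variance shares) are non-negative
  and scale-free, avoiding the sign ambiguity of raw loadings; raw-loading
  weighting (normalised absolute loadings) is available via
  `weighting="raw"`.
* **Orientation**: the sign of a principal component is arbitrary, so each
  dimension is oriented against a declared anchor (e.g. unemployment rate,
  direction +1; household income, direction −1): the dimension score must
  correlate positively with "more deprived" as defined by the anchor.
* Dimension scores (Σ weight·sign·z-value) are averaged with equal weight
  and min–max normalised over the supplied area set, so exactly one area
  attains 0 and one attains 1 when raw scores are distinct.
* Weights are fitted per cross-section. In the moving-window analysis the
  index of a window comes from the middle year's indicator table; a single
  static table is reused for all windows (the synthetic generator's latent
  deprivation is time-constant).

## Synthetic generator

The generator emulates the data environment of a national district-level
mortality analysis with a planted ground truth.

* **Areas**: default 400; populations log-normal around a mean of 200 000
  persons with sigma 0.8 (heterogeneous district sizes); latent deprivation
  z drawn standard-normal in fixed area order and standardised exactly to
  mean 0, sd 1.
* **Hazard**: Gompertz–Makeham h(x) = c + a·e^{bx}, per sex, times
  exp(γz + δz·t)·ρᵗ with t the year offset. Defaults (calibrated once,
  analytically, against the quadrature oracle): female (c = 1e-4,
  a = 6.4e-6, b = 0.11) → e₀ ≈ 83.1; male (c = 2e-4, a = 3.0e-5,
  b = 0.095) → e₀ ≈ 78.2; γ = 0.148 so that the analytic
  e₀(z = −2) − e₀(z = +2) difference averages ≈ 6.0 years over the sexes.
  Drift ρ and its deprivation dependence δ default to off.
* **Exposure**: person-years per band = population × the band's share of a
  stationary population under the area's hazard (shares sum to 1, so bands
  conserve the population each year). This is a modelling choice — real
  within-district age structures are not stationary — made because the
  analysis needs realistic marginals, not demographic projection.
* **Deaths**: Poisson with mean m·PY, where m is the exact stationary
  central rate (S(lo) − S(hi)) / ∫band S. Poisson (not binomial) is
  standard for event counts over person-time. One RNG child stream per
  (area, sex, year), derived deterministically from the root seed, so
  partial regeneration is stable and identical configs are byte-identical.
* **Indicators**: indicator_j = loading_j·z + noise, sd 0.5, with mixed
  signs (income-like indicators load negatively). Loading magnitudes
  0.6–0.9 give per-indicator correlations with z of ≈ 0.77–0.87 —
  realistic for administrative deprivation indicators — and a composite
  that tracks z closely (Spearman ≈ 0.97 at 400 areas).

### What the generator does not emulate

Migration, cohort effects, cause-of-death structure, spatial
autocorrelation between neighbouring areas, non-stationary age structures,
and time-varying indicator systems. Passing tests therefore demonstrate
correctness of the *method* under a known data-generating process, not the
behaviour of any real registry data.

## Numerical choices

* Survival quadrature: trapezoid on a 0.05-year grid to age 130 (the
  Gompertz term makes survival beyond that numerically zero); band
  integrals by cumulative trapezoid at band edges.
* The bundled `examples/widening_gap.yaml` was solved analytically (fsolve
  on the quadrature e₀ against an expected-order-statistics z grid) so
  that the *latent* gap moves 2.6 → 4.3 y (women) and 5.7 → 7.2 y (men)
  over 2003–2022 while mean e₀ rises 81.8 → 83.2 and 76.2 → 78.3 —
  plausible magnitudes for a high-income country. Estimated gaps exceed
  the latent calibration by ≈ 10 %: min–max normalising a *noisy*
  composite compresses the index relative to the latent score's span, so
  the unit interval maps to a wider latent range. This is a real property
  of slope-index estimates computed on measured deprivation indices, not
  an artefact; the planted-gap recovery test therefore compares the
  pipeline against an analytic oracle that uses the *same* realised index.
* Life-table discretisation: with exact stationary rates and 5-year bands
  the Chiang table reproduces the analytic e₀ to within ≈ 0.06 y at the
  default mortality levels (tested at 10⁸ population, where Poisson noise
  is negligible against the discretisation term).
* The Monte-Carlo cohort oracle draws lifetimes by inverse transform of
  the piecewise-exponential survival function, with stratified driving
  uniforms so the 10⁶-individual mean is tight; the piecewise-exponential
  model and the Chiang table differ by ≈ 0.02 y for the frozen rate
  vector, inside the 0.05-y agreement band.
* Degenerate inputs raise typed errors (constant indicator, constant
  index, < 3 areas, zero open-interval rate) rather than propagating NaN.

## Problem sizes

Defaults throughout are the full study conditions: 400 areas, 2 sexes,
20 years, 19 bands. The planted-gap recovery test averages 20 seeds of a
single-window 400-area run; unit tests use 25–80 areas where the property
under test does not depend on scale.

## Known limitations

* No confidence intervals for e₀ or the gap (the indicator is reported as
  a point summary; r² is retained as a diagnostic only).
* No smoothing/graduation of rates and no small-area estimation models;
  very small areas rely entirely on the 3-year pooling.
* The index normalisation is per cross-section; comparing index *values*
  (not gaps) across periods assumes the area set is fixed.
* Quintile-based contrasts are intentionally not part of the indicator.
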