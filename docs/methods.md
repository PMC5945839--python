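# Methods

## Model

Each subset/measure pair is modelled independently as

    y = a + b·exp(c·x),   x = age in years (age_days / 365; leap days ignored)

with `a` the late-adolescence asymptote (response units), `b` the
amplitude at birth relative to the asymptote, and `c` the rate per year.
Negative `c` with positive `b` gives monotone decline (naïve fraction,
total count); negative `c` with negative `b` gives monotone saturation
(memory fractions). The curve is fitted by unweighted least squares —
heteroscedasticity is deliberately not modelled in the mean fit, because
the reference bands are built non-parametrically from the pooled
residuals rather than from a variance model.

### Fitting

The model is separable: at fixed `c`, `(a, b)` solve a 2-parameter linear
least-squares problem exactly via the normal equations. The fit is
therefore a profiled 1-D minimisation of SSR(c):

1. a 401-point grid over `c ∈ [−8, 8]` /year (rates beyond ±8/year are
   indistinguishable from step functions on a 0–18 y domain);
2. Brent refinement (scipy `minimize_scalar`, bounded, `xatol = 1e-10`)
   inside the bracketing grid interval;
3. ties in the grid SSR (relative tolerance 1e−12) break toward smaller
   `|c|`, the smoother curve; exactly constant responses short-circuit to
   the degenerate fit `(a=const, b=0, c=0)`.

The exponential basis is evaluated as `exp(c·(x − x0))` with `x0` the age
extreme matching the sign of `c`, keeping the design column in (0, 1] so
no overflow occurs anywhere in the bracket; the canonical amplitude
`b = b_scaled·exp(−c·x0)` is derived on demand. This construction is
checked in the tests against a brute-force grid oracle (exact linear
subproblem at every grid point) and against an independent
Levenberg–Marquardt route (`scipy.optimize.curve_fit`).

Inputs need ≥ 4 observations and ≥ 3 distinct ages (3 parameters + 1 df).
Predictions are restricted to ages 0–18 y unless extrapolation is
explicitly requested, and patients older than 18 y are rejected by the
calculator rather than extrapolated.

### Reference bands

The band at confidence probability `p` adds the empirical `(1−p)/2` and
`1−(1−p)/2` residual quantiles to the predicted curve. Choices:

* **Quantile rule**: linear interpolation between order statistics
  (`numpy.quantile`, method `"linear"`). Rank-based rules differ
  noticeably at n ≈ 200, so the rule is fixed and documented.
* **Equal tail split** (α/2 per side) and **age-constant additive
  offsets**: one quantile pair shifted along the curve. The band width is
  constant in age; asymmetry of the residual distribution is inherited by
  the band.
* **Clamping**, applied after band construction: fraction limits clipped
  to [0, 100] %, count lower limits floored at 0 cells/μl. Biologically
  forced; band nesting remains non-strict where clamps bind.
* **Defaults**: confidence probabilities 0.90 and 0.95. Below 20
  residuals a warning is raised (tail quantiles unstable).
* Containment tests in `empirical_coverage` use closed intervals with an
  absolute slack of `1e-7·(max|value| + 1)` so that a numerically perfect
  fit counts its own points as covered.

Because the offsets are order statistics of the fitting residuals, the
band's coverage on exchangeable new data is nominal regardless of the
noise distribution — the property the skewed-noise simulations verify
(coverage 0.90 ± 0.02 and 0.95 ± 0.015 at n_fit = 500,
n_test = 10,000).

## Synthetic cohort generator

The generator emulates a single-center cross-sectional study of healthy
children aged 2 days–18 years (default n = 184, the published cohort
size; the reported per-age-group enrollment and sex counts do not sum to
that total, so only the total is used). Per subject it draws age, sex,
screening flags, and the measurement panel.

* **Ages**: log-uniform over days by default, over-representing infancy
  where the curves bend fastest; a uniform option exists. This is a much
  stronger infancy weighting than real enrollment (roughly half the
  subjects fall under one year), which benefits fit stability near birth
  and costs nothing downstream because the reference construction is
  age-agnostic.
* **Primary trajectories** (exponential, parameters in
  `bcellref.cohort.default_trajectories`): naïve fraction 98 % of B cells
  at birth declining to an asymptote of 62 % (c = −0.30 /year); memory
  fractions 0.3–0.4 % at birth saturating at 10.5 % (switched) and 6.5 %
  (non-switched) within ~5 years; total CD19⁺ count 1,800 cells/μl at
  birth falling to 250 (c = −0.45 /year); lymphocytes 5,500 → 2,300
  cells/μl. Anchors are the published birth values (98 %, 1,800 cells/μl)
  and the qualitative course of pediatric B cell development; asymptotes
  sit inside the adolescent ranges reported across pediatric studies.
* **Derived quantities**: fractions are primary; subset absolute counts
  are `total × fraction / 100` exactly, so panels are internally
  consistent by construction. The peaked early-childhood memory-count
  curve emerges as the product of a falling total and a rising fraction
  (peak near age 2). A biexponential
  (`a + b·exp(c·x) + b2·exp(c2·x)`) trajectory kind is available and can
  be set as a primary absolute-count trajectory, in which case the
  fraction is derived instead; the fitted model is always the
  three-parameter exponential — the biexponential is generator-only.
* **Noise**: additive after the curve, clamped afterwards to the
  observable range ([0, 100] % or [0, ∞) cells/μl) — the generative model
  matches what a laboratory can report. The default is a shifted-gamma
  shape (skewness 1, shape `k = 4/skew²`) because the band construction
  is explicitly distribution-free and Gaussian-only fixtures would not
  exercise that; counts carry proportional (heteroscedastic) components
  (10–22 % of the curve level), the naïve fraction a left-skewed
  constant scale of 3.5 % points (its ceiling is biological; its tail
  points down). A Gaussian option is kept for closed-form oracle tests.
  If the three subset fractions exceed 100 % after noise they are
  rescaled proportionally.
* **CD20 side**: per-subject CD20 co-expression on CD19⁺ B cells is
  Beta-distributed with mean 0.99 (sd 0.005); CD20-only cells add up to
  1 % of the CD19 count. The naïve fraction runs 2 % points higher and
  the switched fraction 2 % points lower under the CD20 denominator,
  with 0.5 % points of jitter — the systematic marker shifts reported
  for this panel.
* **Screening flags**: independent Bernoulli draws at the published
  exclusion frequencies (16/227 abnormal counts or CRP, 21/227 missing
  labs, 6/227 insufficient material); insufficient-material subjects
  carry no panel.

What the generator does **not** emulate: raw flow-cytometry events,
gating or compensation, between-operator drift, correlated exclusion
reasons, and secular or seasonal enrollment structure. Passing tests
therefore demonstrate the statistical machinery — not the biological
accuracy of any particular laboratory's data.

## Screening

Categories are assigned in fixed priority order: abnormal screening
(positive CRP / abnormal counts, and ages ≥ 18·365 days) first, then
missing labs, then insufficient material, else included. The order is a
package decision — it makes multi-flag subjects count once so that the
categories always partition the manifest, matching mutually exclusive
published accountings. Whether any child was ever excluded on age alone
is not separable from the abnormal-screening count in this scheme.

## Group comparison

Binned references use the same interpolated-quantile rule as the bands
(comparability), half-open age bins with the last bin closed, default
edges {0–1, 1–2, 2–5, 5–11, 11–18} years. Externally published grouped
tables are ingested as-is (explicit edges required, one row per
group × column) and never refitted. The smooth curve's change over any
single day is bounded by `|b·c|·exp(max(0, 18c))/365`, the yardstick
against which boundary jumps of the step reference are measured.

## Problem sizes

Simulation-based checks run at the sizes a desk validation of this design
calls for: n = 500 fitting cohorts with 10,000-subject test sets for
coverage, n = 1,000 default cohorts for calibration, 200 replicates at
n = 500 for rate-parameter recovery, 50 random small datasets against the
brute-force oracle. The full suite completes in well under a minute.

## Known limitations

* A single exponential cannot represent non-monotone trajectories; peaked
  absolute-count curves are fitted by their best monotone approximation.
  Residual quantiles absorb the lack of fit into wider bands, which is
  conservative but age-uniform.
* Age-constant band width ignores any true age-dependence of the spread;
  strongly heteroscedastic measures get bands that are too wide where the
  spread is small and too narrow where it is large, even though marginal
  coverage stays nominal.
* Confidence intervals for (a, b, c) themselves are out of scope, as is
  model selection between curve families.
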