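# Methods

## Model

An annual record is `y_i = f(t_i) + ε_i` with independent Gaussian noise
`ε_i ~ N(0, σ²)` and `f` drawn from one of the model classes

* **constant** — a single level (`M = 1` coefficient);
* **linear** — a straight line through the record span (`M = 2`);
* **k change points** (`k = 1 … max_cpt`, default 2) — a continuous
  piecewise-linear polygon whose `n_p = k + 2` pivots are the record
  endpoints plus `k` interior change points (`M = n_p`).

Change points are restricted to *observed* years strictly inside the
record.  This matches the combinatorics of the one-change-point special
case (`N − 2` possible placements), guarantees a nonsingular Gram matrix
(every pivot owns at least its own observation), and handles missing
years with no special casing — gaps simply contribute no rows to the
basis.  Adjacent-year change points are allowed; no minimum segment
length is imposed.

The polygon enters the likelihood linearly through the hat-function
(linear interpolation) basis: column `j` of the design matrix `A` is 1 at
pivot `j`, 0 at the other pivots, linear between neighbours.  Rows of `A`
sum to one for every segment model, and a pivot's own row is a unit
vector.

## Evidence

Per configuration the vertex values get a flat prior with normalization
width `Δ` per coefficient and the noise scale a Jeffreys `1/σ` prior.
Integrating the Gaussian likelihood over both gives, in closed form,

    E(c) = Δ^−M (2π)^−(ν/2) |AᵀA|^−1/2 · ½ Γ(ν/2) (rss/2)^−(ν/2),
    ν = N − M,

with `rss` the least-squares residual sum of the configuration.  Two
notes on this construction:

* `Δ = (1 + 2·margin) × (data range)` with `margin = 0.05` by default.
  The flat prior is treated as a *density* `1/Δ` with the Gaussian
  coefficient integral taken over its full support (the standard Ockham
  factor form); the test suite verifies the expression against
  brute-force tensor quadrature of likelihood × priors to ~10⁻⁴
  relative on short records.
* The margin acts only through the per-dimension Ockham penalty `Δ^−M`.
  Because the change-point classes differ in dimension, the split
  between the 1- and 2-change-point classes is sensitive to it:
  on hockey-stick test data the 1-cpt selection frequency moves from
  ~0.83 (margin 0) through ~0.85–0.90 (margin 0.05) to ~0.97
  (margin 0.30).  `prior_sensitivity()` reports class probabilities
  across margins so users can check robustness on their own records.
  Rank order of classes is far more stable than absolute probabilities.

All evidence arithmetic is in log space with log-sum-exp reductions:
`(rss)^−(ν/2)` under/overflows in double precision at `N ≈ 110`.

Class evidence is the mean of configuration evidences (uniform prior
over the `C(N−2, k)` placements) and the posterior over classes applies
a uniform class prior.  Probabilities are therefore invariant under
translation and positive scaling of the data (scaling shifts every
configuration's log evidence by the same `−N log s`).

**Enumeration vs Monte Carlo.**  Configuration sums are evaluated by
exact enumeration whenever the space has at most 10⁵ configurations —
which covers everything up to two change points at `N ≈ 112`
(`C(110,2) = 5995`).  Beyond that, configurations are drawn uniformly
with replacement (`n_mc` draws, default 10⁴) and weighted by evidence;
the weighted mean of any per-configuration functional is a consistent
estimate of its enumerated value, and the class-evidence estimate
carries a Monte Carlo standard error.

**Degenerate exact fits.**  `rss = 0` makes the evidence diverge, so the
per-configuration evidence raises a hard error.  At the aggregation
level (relevant only for noise-free data) the `σ → 0` limit is applied:
posterior mass collapses onto the lowest-dimension class containing an
exact-fit configuration, uniformly over its exact-fit configurations,
with zero posterior variance.  This makes noiseless synthetic records
identify their generating class exactly.

## Model averaging and uncertainty

The reported fit is `mean(t) = Σ_class P(class) Σ_config w(c) · polygon_c(t)`
and the rate of change is the same average over the piecewise-constant
segment slopes.  The derivative of a single polygon is undefined at a
pivot; the **left-segment slope** is used there.  After averaging over
thousands of configurations the rate curve is effectively smooth, so the
convention only matters at isolated points.  The *end-of-record rate* —
the quantity compared between truncations — is the averaged derivative
evaluated exactly at the last observed year.

Pointwise variance combines, by the law of total variance,

* the within-configuration posterior variance of the polygon value or
  slope — the multivariate Student form `hᵀ (AᵀA)^−1 h · rss/(N − M − 2)`
  with `h` the basis (or slope-functional) row at the grid year; if
  `N − M − 2 ≤ 0` (records shorter than ~6 years) a draw-based estimate
  replaces the closed form, with a warning;
* the between-configuration spread of the polygon means.

The reported `sd` is the standard error of the *fit function*, not a
predictive interval — matching the convention of displaying ± one
standard error around the expectation.  Uncertainty grows toward the
record ends and near change points, where fewer observations constrain
the local segments.

**Credible bands** at an arbitrary level come from exact posterior
sampling (no Markov chain is needed at this scale): draw a
(class, configuration) pair by posterior weight, `σ²` from its scaled
inverse-χ² marginal (`rss/σ² ~ χ²_ν`), the vertex vector from the
conditional Gaussian `N(f̂, σ² (AᵀA)^−1)`, then evaluate the polygon and
its slopes on the grid and take pointwise central quantiles.  Default
2000 draws; all sampling is reproducible from `RunConfig.seed`.

For curve evaluation, configurations carrying less than 10⁻¹⁴ of their
class's weight are skipped and the remainder renormalized; the induced
error is orders of magnitude below the reported standard errors.

## Fit quality

`ME = (SS_tot − SS_res)/SS_tot`, with `SS_res` computed from the
**model-averaged** fit at the observation years (one could instead use
the best single model's fit; the averaged fit is the package's primary
output, so its ME is the one reported).  `ME = 1` for an interpolating
fit, `0` for the constant mean, and the identity holds exactly by
construction.

## Truncation comparison

`compare_end_years` refits the record truncated at two end years — both
analyses completely independent, sharing only the run configuration —
and differences the end rates, `delta = rate_short − rate_long`.
Classification: for phenology (advance = negative rate) `delta < −tol`
is a *slowdown* of the advance; for temperature (warming = positive
rate) `delta > +tol` is a slowdown of the warming; `|delta| ≤ tol` is
*unchanged*, with `tol = 0.005` units/year — below the resolution of a
rate printed to two decimals.

## Synthetic data

`SyntheticSpec` generates records with the statistical structure the
analysis assumes: a continuous piecewise-linear mean, iid Gaussian noise,
and a random subset of interior years removed.  Defaults emulate a
century-long flowering record: 1901–2012, one break in 1985, flat then
−0.5 days/year, 5 days noise, ~5% missing years, day-of-year level 60.
The paired generator drives a phenology record from a temperature draw
(`pheno = baseline + sensitivity × temperature anomaly + noise`,
sensitivity in days/°C, typically negative) so temperature change points
propagate into phenology with slopes scaled by the sensitivity.

What the generator deliberately does **not** emulate — and hence what
passing tests do not demonstrate about real records: year-to-year noise
autocorrelation (real spring temperatures are weakly autocorrelated; an
AR(1) option is out of scope), heteroscedasticity, observer or station
relocation artifacts, and outliers (the analysis performs no outlier
removal).  Under misspecified noise the class probabilities remain
well-defined but their calibration is not guaranteed.

**Experiment sizes.**  The replicated experiments (model-class recovery,
change-point location error, band coverage, truncation classification)
use 200 replicates at the default record scale; a full enumeration-based
analysis of one `N ≈ 110` record takes ~0.1 s, so each experiment
completes in well under a minute.  For the slowdown experiment the
generator uses a snowdrop-like profile — break 1985, −0.9 days/year
until 2002 (the magnitude such records show at that end year), flat
afterwards — since the question is whether a genuine flattening of a
*strong* advance is detected.

## Known limitations

* Absolute class probabilities depend on the coefficient prior width
  (see above); comparisons across records are meaningful when the same
  margin is used, and rank order is the robust summary.
* Change points live on observed years; a break between two observed
  years is attributed to a neighbour.  Location uncertainty is available
  through the posterior weights within the 1-cpt class.
* The noise model is iid Gaussian; heavy-tailed interannual variability
  will inflate the apparent support for extra change points.
* The 1-cpt vs 2-cpt split on strongly bent records is intrinsically
  close (a 2-cpt configuration with both pivots near the true break
  reproduces the 1-cpt shape); selecting by highest class probability on
  such data picks the 1-cpt class in roughly 85% of replicates, not
  always.
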