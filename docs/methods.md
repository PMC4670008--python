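# Methods

## Data model

The unit of observation is one embryo followed from before cellularization to
hatching.  Nine morphological landmarks are annotated, in canonical order:
pole-bud appearance, membrane reaching the yolk (end of cellularization),
pole-cell invagination, amnioproctodeal invagination, amnioserosa exposure,
clypeolabrum retraction, cephalic lobes even with the clypeolabrum,
heart-shaped midgut, tracheal filling.  Times are hours since the first
recorded frame; only differences ever enter an analysis, so the time origin is
immaterial.

Arrest is modeled as right-censoring: once development halts no later landmark
is recorded, so missing events must form a suffix of the catalog order — an
interior gap is a data error, not censoring.  Missing values are empty CSV
fields (no numeric sentinels, which would collide with a legitimate 0.0).

"End of cellularization" is identified with the membrane-reaches-yolk
landmark: it is the only cellularization endpoint in the catalog and one event
must anchor normalized time 0.

**Ordering relaxation.**  Strict catalog ordering is enforced for every pair
of landmarks except (cephalic lobes even, heart-shaped midgut).  The relative
timing of head involution and gut formation is precisely the quantity under
study — the two events complete in opposite orders under hypoxia versus
hyperoxia — so a validator that demanded catalog order there would reject
exactly the embryos that carry the signal (and would silently bias the
inversion estimate if enforced inside the generator's noise resampling).
Both events must still fall between clypeolabrum retraction and tracheal
filling.

## Timeline normalization and heterochrony

Each embryo with both anchors is rescaled to
`p(e) = (t_e − t_cell) / (t_trachea − t_cell)`, placing the end of
cellularization at 0 and tracheal filling at 1; the pole bud maps to a
negative value.  Normalization is exactly invariant to shifting or positively
scaling an embryo's clock.

For each landmark and temperature, `p(e)` is regressed on oxygen (% O₂, linear
scale) by ordinary least squares with one point per embryo — animals are
weighted equally rather than collapsing to condition means.  A slope of zero
is uniform scaling; a nonzero slope is heterochrony.

Slopes of two events are compared with the pooled-variance statistic

```
s²_p = (SSE_a + SSE_b) / (n_a + n_b − 4)
t    = (β_a − β_b) / sqrt(s²_p (1/Sxx_a + 1/Sxx_b)),   df = n_a + n_b − 4
```

two-sided, with Bonferroni correction over the family of all event pairs
within one temperature (the family size m is attached to every result so
alternative families are auditable).  If both fits are exact (s²_p = 0) the
statistic is defined as 0 with p = 1 for equal slopes and ±∞ with p = 0
otherwise.

**Known conservativeness.**  The two regressions entering a comparison are
fitted on the *same* embryos, and each embryo's normalized residuals share
the anchor annotation noise: for an event at position p the residual is
approximately `ε_e − (1−p)·ε_cell − p·ε_trachea`, so two events a, b have
residual correlation `[(1−p_a)(1−p_b) + p_a p_b] / (σ_a σ_b)` — up to ≈0.5
for late event pairs, which share the trachea term.  The pooled test assumes
the two samples are independent and therefore overestimates the variance of
the slope difference; under a uniform-scaling null its family-average
rejection rate at nominal α = 0.05 is close to 0.02 rather than 0.05.  The
test is implemented in its classical form because that is the standard
instrument for this design; users should read its p-values as conservative.

**Inversion point.**  Two fitted lines with slope difference above a 10⁻¹²
tolerance cross at `[O₂]* = (α_b − α_a)/(β_a − β_b)`; parallel lines give a
distinguished no-inversion result.  The estimate is flagged by whether it
falls inside the observed oxygen range (closed interval — a crossing at the
boundary counts as observed).

## Rate models

Total developmental time is anchored at the end of cellularization by default
(`t = t_trachea − t_cell`); an option measures from pole-bud appearance when
that landmark is recorded.

Six single-predictor families are supported: linear `a + bx`, exponential
`a·e^(bx)`, logarithmic `a + b·ln x`, quadratic, cubic, and
inverse-proportional `a + b/x` (the Monod-style law).  Logarithmic and
inverse-proportional fits are closed-form OLS on the transformed predictor.
The exponential family is initialized by log-linear regression and refined by
nonlinear least squares on the original scale (iteration cap 200·(n+1)
evaluations, relative tolerance 10⁻¹⁰, no random restarts — fits are
deterministic).

Family selection maximizes the Pearson correlation between fitted and
observed responses on the original scale (making families with different
link scales comparable), with correlations tied within 10⁻⁹ resolved by
fewer parameters, then by fixed family order.  A family whose parameter
count is ≥ the number of *distinct* predictor values is excluded as
saturated: it can reproduce the level means exactly, so goodness of fit
cannot rank it against genuinely parametric alternatives.  This matters for
the temperature axis, where only three levels exist.

Temperature enters the Arrhenius-style fits as 1/T with T in °C.  This is
deliberately nonstandard (Arrhenius laws are usually written in kelvin): the
fit is purely empirical, and on the Celsius scale the coefficient magnitudes
reproduce the observed ~2× slowdown from 27.5 to 17.5 °C directly.

**Combined surface.**  Four candidate surfaces combine an exponential
temperature component with inverse-proportional oxygen components (inside
the exponent, as a multiplicative Monod prefactor, as a linear divisor, and
as the plain no-interaction Arrhenius×Monod product); each is fitted by
nonlinear least squares and the highest adjusted R² wins (ties → fewer
parameters → catalogue order).  Candidates that fail to converge are recorded
and skipped; the full candidate table is attached to the result for audit.
Every catalogue form factorizes as g(T)·h(O₂), while the three
per-temperature Monod fits are *not* separable (their b/a ratios differ), so
the selected surface is a compromise: on noiseless default-grid data it
tracks the per-temperature fits to ~2% in the median but deviates up to
~11% at the grid corners.  No single form is hard-coded as "the" model.

## Viability

Unhatched embryos are binned by last recorded landmark: before
amnioproctodeal invagination (pre-gastrulation failure — amnioproctodeal
invagination is the last gastrulation landmark in the catalog), from there up
to but excluding the heart-shaped midgut (gastrulation→midgut failure), the
heart-shaped midgut itself (late pre-tracheal failure — arrest after that
stage but before tracheal filling), and tracheal filling without hatching
(hatching failure).  Bins are half-open on the right; classification is total
and deterministic, and tabulation is an exact cross-count with per-condition
fractions.

## Synthetic generator

The generator emulates the study design, not embryo physiology:

* **Grid** — six oxygen levels {10, 14, 17, 21, 25, 29}% × three temperatures
  {17.5, 22.5, 27.5} °C, n embryos per condition (default 20).
* **Total time** — `t = a(T) + b(T)/[O₂]` with defaults (30.13, 280.92),
  (17.58, 167.39), (8.55, 204.03) hours — the fitted per-temperature
  coefficients — so recovery tests target published-scale values.
* **Landmark positions** — `p(e, O₂) = p₀_e + s_e·([O₂] − 21)`, renormalized
  so the anchors sit exactly at 0 and 1.  Baselines are fixture choices
  (only graphical data exist for them), strictly increasing, with the
  head/gut gap small (0.03) so realistic slopes produce an inversion inside
  the observed range.  A per-temperature shift on the heart-shaped-midgut
  baseline (−0.045, 0, +0.03) places the ground-truth inversion at 19, 25
  and 29% O₂ at 17.5, 22.5 and 27.5 °C; the two extreme values are the
  study's reported inversion points, the middle one is interpolation.
* **Noise** — additive Gaussian (default sd 0.5 h, roughly annotation-scale
  error; anchors included), redrawn until the event order is valid
  (rank-preserving rejection, with the head/gut swap permitted).  Additive
  rather than multiplicative because hand-annotation error does not grow
  with developmental time.
* **Fate** — one categorical draw per embryo from a per-condition
  distribution over the five bins; defaults qualitatively reproduce the
  observed pattern (hypoxia → mid-embryogenesis arrest, worse when warm;
  mild hypoxia → hatching failure; hyperoxia → early failure; survival
  optimum at 25%).  A failing embryo's timeline is censored at a uniformly
  drawn landmark within its bin's stage range.
* **Determinism** — one seeded generator per dataset, conditions consumed in
  grid order; identical (config, seed) gives byte-identical output.

What the generator does *not* emulate: rapid hypoxic metaphase arrest and
revival, inter-embryo heterogeneity in oxygen sensitivity (no random
effects), correlated annotation errors, drifting incubator conditions, or
any mechanistic link between slowed development and death.  Tests passing on
synthetic data therefore demonstrate the *estimators* are correct under the
assumed noise model, not that the biology is as simple as the model.

## Numerical choices

* OLS via `numpy.linalg.lstsq`; t-tail probabilities via `scipy.stats.t`;
  nonlinear refinement via `scipy.optimize.curve_fit` with fixed, documented
  caps and tolerances.
* Event tables serialize floats at 12 significant digits (round-trip error
  < 10⁻⁹ relative); report-bundle outputs use 9 significant digits so two
  runs can be compared byte-for-byte.
* Parallel-slope tolerance 10⁻¹²; inversion range checks on the closed
  interval; zero-variance responses report r = 0 with an explicit flag.
* Degenerate inputs raise typed errors (sample size, degenerate design,
  domain, censoring) rather than returning NaNs.

## Problem sizes in the shipped checks

The test suite and the reproduction script run entirely on simulated data:
200 replicates of the 18-condition × 20-embryo grid for stochastic Monod
recovery, 2000 single-temperature null datasets for the type-I calibration of
the slope test, 20 replicates for inversion recovery, and 50 embryos per
condition in the reproduction script.  These sizes were chosen to put Monte
Carlo error well below the tolerances being asserted while keeping a full run
in the minutes range.

## Known limitations

* The pooled slope-comparison test is conservative on shared-embryo data
  (see above); a paired/seemingly-unrelated-regressions formulation would be
  exact but is not the field-standard instrument this package implements.
* Per-event oxygen-response magnitudes and the fate distributions are
  fixture parameters, not measured constants; only the per-temperature Monod
  coefficients and the inversion oxygen levels are anchored to reported
  values.
* No survival-time modelling (the fate analysis is a cross-tabulation), no
  mixed effects, and no physical model of oxygen diffusion into the embryo.
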