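# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices a maintainer should know about.

## The modelling problem

Presence-only species distribution modelling: given occurrence records of a
species (here, indigenous Arabica coffee in the Afromontane forests of the
Ethiopian highlands region) and gridded bioclimatic variables, estimate a
habitat-suitability surface, then project it onto perturbed climate stacks
representing emission scenarios at future dates. The species is assumed
effectively non-dispersing on the projection horizon, which motivates the
no-migration rules in the area analysis.

## Occurrence cleaning

Records carry a positional-confidence *diameter* in km (GPS readings
0.01–0.05 km, estimated historical localities 1–100 km). The chain is:

* **Confidence filter** (`max_diameter_km = 5`, matching the ~5 arc-minute
  precision floor of the analysis): records with missing coordinates are
  rejected as `no_georeference`, records with diameter strictly above the
  limit as `low_precision`. A diameter exactly at the limit is kept.
* **Deduplication** to unique localities after rounding coordinates to
  4 decimal places (~11 m — finer than any stated confidence; configurable).
* **One sample per grid cell**, first-seen in input order (deterministic
  given sorted input; the retention rule is a free choice and is documented
  as such). Idempotent.
* **Minimum-distance thinning** (default off in the pipeline; 0.2° when
  used): greedy accept/reject in seeded-shuffle order. Distances are planar
  Euclidean in decimal degrees, matching a degrees-based separation
  criterion, not great-circle km. The retained set is maximal (no discarded
  point can be added back) but not guaranteed maximum-cardinality.
* **Clark–Evans nearest-neighbour index** as a clustering diagnostic:
  R = observed mean NN distance / `0.5·√(A/n)`. The z score uses the
  Donnelly edge-corrected expectation and variance, because the uncorrected
  statistic has a positive edge bias of order perimeter/n (≈0.8 standard
  errors for 500 points in a unit square) that misclassifies uniform
  patterns as dispersed well above the nominal 5 % rate. With the
  correction the test is calibrated (measured rejection 4.7 % over 1000
  uniform patterns). Classification is two-sided at |z| = 1.96.

## The maximum-entropy model

The habitat distribution over the background is the Gibbs distribution
`P(x_i) = exp(λ·f(x_i)) / Z`, `Z = Σ_background exp(λ·f)`. Weights maximise
the penalised presence log-likelihood

```
J(λ) = mean_presence[λ·f] − log Z − Σ_f β·m_class(f)·s_f·|λ_f|
```

with `s_f` the presence standard error of feature f (floored at 1e-4) and
`m_class` the published per-feature-class multipliers of the reference
maxent tool: linear/quadratic/product interpolated over
{10 → 0.16, 30 → 0.10, 100 → 0.05} presence samples, hinge fixed at 0.5.
A single uniform multiplier was tried first and rejected: it cannot be made
simultaneously tight enough on hinge features and loose enough on the
linear/quadratic features that carry a Gaussian niche, and ground-truth
recovery stalled below rank correlation 0.9. The global scale β defaults
to 1.0.

*Features.* Variables are min–max scaled to [0, 1] on bounds taken from the
training data; outside the bounds values are **clamped** (and counted), the
conservative choice when projecting onto novel future climates given the
no-migration reading. Classes: linear, quadratic, pairwise products, and
one-sided hinge features `max(0, (x−k)/(1−k))` at `hinge_knots = 5` interior
knots. Constant features over the background are dropped with a warning.

*Optimisation.* The L1 penalty is handled exactly by splitting
`λ = λ⁺ − λ⁻`, bounding both at zero, and running L-BFGS-B with the analytic
gradient (tolerance 1e-6 on the projected gradient, 500 iterations). At the
optimum the maxent box constraints `|E_model[f] − mean_presence[f]| ≤
β·m·s_f` hold to solver tolerance; `NicheModel.constraint_violation`
recomputes the worst excess for assertion in tests (observed ≤ 1e-3,
typically ≤ 1e-5).

*Output scales.* Raw scores sum to 1 over the fitting background. The
logistic scale is pivoted on the entropy H of the fitted raw distribution:
`p = e^H r / (1 + e^H r)`, computed on the log scale for stability, so a
cell with a typical raw score maps to 0.5 and output is in (0, 1).

*Evaluation.* A seeded random 20 % of presences is held out; AUC is the
Mann–Whitney probability that a random presence outranks a random background
point (ties 0.5), computed by ranking and checked in tests against the
brute-force pairwise count. Variable contributions are permutation
importances on training AUC normalised to 100 %; the jackknife refits
with-only/without each variable and reports training gain relative to a
uniform background distribution. Background defaults to 10,000 seeded
uniform non-nodata cells (capped at the number of valid cells; a warning is
emitted when the background is smaller than 10× presences).

## Thresholds and classification

With n present-day locality scores, the cutoff for level ℓ ∈ {0.68, 0.95,
1.00} is the score of the k-th highest locality, `k = ⌈ℓ·n⌉`. A score
classifies *optimal* if ≥ τ_optimal, else *intermediate* if
≥ τ_intermediate, else *marginal* if ≥ τ_marginal, else *unsuitable*.
Ties at a cutoff join the better class; the attained counts are recorded in
the `ThresholdSet` when ties make a level inexact. Consequences, by
construction: at baseline exactly k localities are optimal when scores are
distinct (⌈0.68·349⌉ = 238 on a 349-locality set), every locality is at
least marginal at baseline, and an all-equal score set is entirely optimal.
Raising a score never worsens its class.

## Locality and area analyses

Locality scores are read from the cell containing the point (half-open edge
convention: points on an interior cell edge resolve to the north-west cell;
row 0 is north). Localities on nodata cells are flagged, excluded from
counts, and reported. Class counts are disjoint per scenario × date column
and sum to the locality count; cumulative counts at a level are recovered by
summation. Score histograms for the trajectory figures use 40 equal bins on
[0, 1].

The area analysis reclassifies whole surfaces with the same thresholds, then
applies two temporal rules:

* **no-gain** (always on): cells unsuitable at baseline are forced
  unsuitable at all future dates — the future suitable set is a subset of
  the baseline suitable set, cell by cell;
* **ratchet** (flag, default off): within a scenario a cell's class is
  additionally capped by its class at every earlier date. Off by default
  because the no-gain rule is the stated method, while class "exclusivity"
  through time is an interpretation; both behaviours are exposed.

Cell areas are `(cell·111.195 km)² · cos(latitude)` at the cell-center
latitude. Percent change is reported against the baseline *cumulative* area
at the same level — on a synthetic regional grid relative change is the
meaningful quantity, absolute area is not.

## Core localities and protected areas

Each locality's logistic scores are summed over all scenario × date surfaces
*including baseline* (so a locality good today and stable scores highest);
the population standard deviation over the same set measures variability.
Ranking is by total, ties broken by lower standard deviation then id. The
*core* flag marks the top `core_fraction` (default 0.1 — the study gives no
numeric criterion; top-decile is this package's interpretation, and it is
configurable). The protected-area overlay is a point-in-polygon test
(boundary counts as inside) against GeoJSON polygons, reporting per-polygon
core counts and the gap list of core localities outside all polygons.

## Synthetic data: what it emulates, what it does not

`generate_baseline` produces layers `mean + gradient·latitude +
amplitude·noise` where the noise is Gaussian, smoothed with a Gaussian
kernel of sigma `autocorrelation_length` cells (periodic boundaries, so the
field is stationary) and renormalised to unit variance; at length 0 the raw
noise is used. The four default layers mirror the dominant predictors of
montane-forest coffee suitability: temperature seasonality,
warmest-quarter temperature, driest-month precipitation, wettest-quarter
temperature.

`ScenarioSpec` applies the delta-method convention: temperature anomalies
additive, precipitation multiplicative, seasonality additive. Defaults:
the strongest scenario warms +1.0/+2.0/+3.0 °C at 2020/2050/2080, the
milder two scale those by 0.9 and 0.7; each degree of warming dries
precipitation by 4 % and adds 1.5 units of seasonality. `delta_downscale`
interpolates a coarse anomaly grid bilinearly to the fine grid
(thin-plate-spline interpolation would be the faithful reproduction of
GCM-anomaly downscaling; bilinear is adequate for testing the pipeline
contract and is noted as an extension point).

The ground-truth niche is an axis-aligned Gaussian bell. The default optima
sit at — slightly beyond — the cool, wet, low-seasonality margin of the
attainable climate space, which is the situation of a montane-forest
species: warming, drying and rising seasonality all push the environment
*away* from the optimum, so scenarios erode suitable space rather than
relocating it. With mid-range optima the perturbations merely shift all
gradient bands coherently and landscape-mean suitability can *increase*
under warming; the edge placement is what makes the generator
warming-sensitive. Caveat: strict date-monotonicity of the landscape-mean
suitability is a typical-case property, not a per-realisation guarantee —
multiplicative drying genuinely benefits cells wetter than the
precipitation optimum, and for some noise seeds this produces a small
early-date uptick before the end-of-century collapse.

`sample_occurrences` draws presence cells with probability proportional to
true suitability, optionally through a cluster process (suitability-weighted
cluster centers, records scattered in the 3×3 neighbourhood) to mimic survey
clustering, injects coordinate duplicates (re-collections), and can make a
fraction of records rejectable (half no coordinates, half confidence 6–100
km). `make_survey_fixture` builds a raw record set with an exact cleaning
chain — 719 raw, 6 rejectable, 713 usable at 349 distinct points over 197
grid cells — by construction: points lie on a 0.001° sub-cell lattice,
strictly interior to their cells, so they survive 4-decimal deduplication
and never sit on a cell edge.

What the synthetic data does **not** emulate: real GCM physics and
inter-variable climate covariance, elevation and terrain, vegetation and
land use, observer bias unrelated to suitability, georeferencing error
structure. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers known truth under its own assumptions —
not that any particular real-world projection is right.

## Problem sizes and determinism

Default study sizes: 50×50 cells (~1 km analogue) for the end-to-end
pipeline and fixtures, 100×100 with 200 presences and a 10,000-cell
background for ground-truth recovery, 719-record survey fixture for the
cleaning chain. At these sizes a full run completes in a few seconds and
recovery of the known niche is strong (rank correlation with truth
typically 0.95–0.99, held-out AUC 0.92–0.98). Every stochastic component
(landscape noise, sampling, shuffles, splits, background draw) is driven by
explicit seeds; identical config + seed reproduces byte-identical CSV/JSON
artifacts, which the pipeline manifest checksums verify.

## Known limitations

* The maxent implementation targets the reference tool's documented
  behaviour, not bit-for-bit output; per-class regularisation uses the
  published table rather than the tool's full internal schedule.
* Thinning is greedy, not maximum-cardinality.
* Bilinear (not thin-plate-spline) anomaly interpolation.
* Planar-degree distances in thinning and the NN index; areas use a
  spherical cos-latitude correction but no ellipsoid.
* The locality-count structure of the bundled fixture (713/349/197) is
  constructed, not estimated; it verifies the cleaning chain's arithmetic,
  not any field sampling process.
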