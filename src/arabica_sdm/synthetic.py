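"""Synthetic bioclimatic landscapes, climate-change scenarios and survey data.

The real analysis this package supports runs on interpolated climate surfaces
(19 "bioclim" summary variables at ~1 km resolution) and on field/herbarium
occurrence records that are not publicly deposited.  This module generates
stand-ins with the statistical structure the downstream stages assume:

* spatially autocorrelated climate-like layers on a shared grid, with a
  deterministic latitudinal gradient (smoothed Gaussian noise);
* scenario x date "future" stacks obtained by shifting temperature layers,
  scaling precipitation layers and shifting the seasonality layer — the
  standard delta-method convention (temperature anomalies additive,
  precipitation anomalies multiplicative);
* a known Gaussian ("bell product") niche, so model-recovery can be scored
  against ground truth;
* clustered presence-only occurrence records with realistic positional
  confidence metadata, including deliberately rejectable records and
  duplicated localities.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, GridError, Raster, RasterStack
from .occurrences import OccurrenceRecord


class ScenarioError(ValueError):
    """Invalid climate-change scenario specification."""


class SamplingError(ValueError):
    """Occurrence sampling cannot proceed (e.g. all-zero suitability)."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One emission-scenario x date climate perturbation.

    ``temp_delta`` (degC) is added to temperature-kind layers,
    ``precip_factor`` (unitless) multiplies precipitation-kind layers and
    ``seasonality_delta`` is added to the seasonality layer.  The baseline
    (date "2000") must be the identity perturbation.
    """

    scenario_id: str
    date: str
    temp_delta: float = 0.0
    precip_factor: float = 1.0
    seasonality_delta: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.temp_delta, self.precip_factor, self.seasonality_delta):
            if not math.isfinite(v):
                raise ScenarioError(f"non-finite scenario delta in {self.scenario_id}/{self.date}")
        if self.precip_factor < 0:
            raise ScenarioError(f"precip_factor must be >= 0, got {self.precip_factor}")
        if self.date == "2000" and (self.temp_delta != 0.0 or self.precip_factor != 1.0
                                    or self.seasonality_delta != 0.0):
            raise ScenarioError("baseline (2000) scenario must have zero deltas")

    @property
    def is_baseline(self) -> bool:
        return self.temp_delta == 0.0 and self.precip_factor == 1.0 \
            and self.seasonality_delta == 0.0


FUTURE_DATES = ("2020", "2050", "2080")


def default_scenarios(
    max_deltas: tuple[float, float, float] = (1.0, 2.0, 3.0),
    scenario_scales: dict[str, float] | None = None,
    drying_per_degree: float = 0.04,
    seasonality_per_degree: float = 1.5,
) -> list[ScenarioSpec]:
    """Three-scenario x three-date default perturbation set plus baseline.

    The strongest scenario (an A1B analogue) warms by ``max_deltas`` degC at
    the three future dates; the milder two (A2A-, B2A-like) scale those
    deltas by 0.9 and 0.7.  Each degree of warming dries precipitation by
    ``drying_per_degree`` (multiplicative) and raises temperature seasonality
    by ``seasonality_per_degree`` layer units.
    """
    if scenario_scales is None:
        scenario_scales = {"A1B": 1.0, "A2A": 0.9, "B2A": 0.7}
    out = [ScenarioSpec("baseline", "2000")]
    for sid, scale in scenario_scales.items():
        for date, dt in zip(FUTURE_DATES, max_deltas):
            delta = scale * dt
            out.append(ScenarioSpec(
                scenario_id=sid, date=date, temp_delta=delta,
                precip_factor=max(0.0, 1.0 - drying_per_degree * delta),
                seasonality_delta=seasonality_per_degree * delta,
            ))
    return out


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth habitat suitability: an axis-aligned Gaussian bell.

    ``suitability(x) = max_suitability * prod_v exp(-(x_v - opt_v)^2 / (2 tol_v^2))``

    Optima and tolerances are in the units of the named layers.
    """

    optima: dict[str, float]
    tolerances: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must name the same variables")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be > 0")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must be in (0, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.optima)


# ---------------------------------------------------------------------------
# Baseline landscape
# ---------------------------------------------------------------------------

# (name, kind, mean, noise amplitude, south->north gradient over full extent)
# Names mirror the bioclim variables that dominate montane-forest coffee
# suitability: temperature seasonality, warmest/wettest-quarter temperature
# and driest-month precipitation.
DEFAULT_LAYER_DEFS: list[tuple[str, str, float, float, float]] = [
    ("temp_seasonality", "seasonality", 55.0, 8.0, -10.0),
    ("temp_warmest_quarter", "temperature", 21.0, 2.5, -4.0),
    ("precip_driest_month", "precipitation", 35.0, 15.0, 20.0),
    ("temp_wettest_quarter", "temperature", 18.0, 2.5, -4.0),
]


def generate_baseline(grid_spec: GridSpec, n_layers: int = 4,
                      autocorrelation_length: float = 5.0,
                      seed: int = 0) -> RasterStack:
    """Generate a baseline stack of spatially autocorrelated climate layers.

    Each layer is ``mean + gradient * latitude + amplitude * noise`` where the
    noise field is standard Gaussian noise smoothed with a Gaussian kernel of
    sigma ``autocorrelation_length`` (in cells; 0 disables smoothing).
    Precipitation layers are clipped at zero.
    """
    if n_layers < 2:
        raise GridError(f"n_layers must be >= 2, got {n_layers}")
    defs = list(DEFAULT_LAYER_DEFS)
    k = 0
    while len(defs) < n_layers:  # extra generic layers beyond the core four
        k += 1
        kind = "temperature" if k % 2 else "precipitation"
        mean = 15.0 if kind == "temperature" else 60.0
        defs.append((f"bio_extra_{k}", kind, mean, 3.0, 2.0 * (-1) ** k))
    defs = defs[:n_layers]

    rng = np.random.default_rng(seed)
    _, lat = grid_spec.cell_centers()
    lat_span = max(grid_spec.n_rows * grid_spec.cell_size, grid_spec.cell_size)
    lat_norm = (lat - grid_spec.lat_min) / lat_span  # 0 at south edge, 1 at north

    stack = RasterStack(grid_spec, "baseline", "2000")
    for name, kind, mean, amp, grad in defs:
        noise = rng.standard_normal(grid_spec.shape)
        if autocorrelation_length > 0:
            # periodic smoothing keeps the field stationary (no edge-variance
            # artefacts); renormalise so amplitude = standard deviation
            noise = gaussian_filter(noise, sigma=autocorrelation_length, mode="wrap")
            noise /= max(noise.std(), 1e-12)
        vals = mean + grad * lat_norm + amp * noise
        if kind == "precipitation":
            vals = np.clip(vals, 0.0, None)
        stack.add_layer(name, Raster(grid_spec, vals), kind)
    return stack


# ---------------------------------------------------------------------------
# Future scenarios
# ---------------------------------------------------------------------------

def generate_future(baseline: RasterStack, scenario: ScenarioSpec) -> RasterStack:
    """Apply a scenario perturbation to a baseline stack.

    Temperature layers are shifted by ``temp_delta``, precipitation layers
    scaled by ``precip_factor`` and the seasonality layer shifted by
    ``seasonality_delta``.  Nodata masks are preserved untouched.
    """
    out = baseline.copy(scenario_id=scenario.scenario_id, date=scenario.date)
    for name, raster in out:
        kind = out.layer_kinds[name]
        valid = ~raster.mask
        if kind == "temperature":
            raster.values[valid] += scenario.temp_delta
        elif kind == "precipitation":
            raster.values[valid] *= scenario.precip_factor
        elif kind == "seasonality":
            raster.values[valid] += scenario.seasonality_delta
    return out


def delta_downscale(coarse_anomaly: Raster, fine_baseline: Raster,
                    mode: str = "additive") -> Raster:
    """Downscale a coarse anomaly grid onto a fine baseline (delta method).

    The coarse anomaly (e.g. a GCM cell average) is interpolated bilinearly
    between coarse cell centers to the fine cell centers, then *added to*
    (``mode="additive"``, temperature) or *multiplied into*
    (``mode="multiplicative"``, precipitation) the fine baseline.  Outside the
    coarse cell-center lattice but inside the coarse extent the edge value is
    linearly extrapolated.  Nodata cells of the fine baseline stay nodata.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown mode {mode!r}")
    cg, fg = coarse_anomaly.grid, fine_baseline.grid
    if not (cg.origin_lon <= fg.origin_lon and cg.lon_max >= fg.lon_max
            and cg.origin_lat >= fg.origin_lat and cg.lat_min <= fg.lat_min):
        raise GridError("coarse anomaly grid does not cover the fine baseline extent")

    # coarse cell-center axes, ascending for the interpolator
    clon = cg.origin_lon + (np.arange(cg.n_cols) + 0.5) * cg.cell_size
    clat = cg.origin_lat - (np.arange(cg.n_rows) + 0.5) * cg.cell_size
    interp = RegularGridInterpolator(
        (clat[::-1], clon), coarse_anomaly.values[::-1, :],
        method="linear", bounds_error=False, fill_value=None)

    flon, flat = fg.cell_centers()
    anom = interp(np.column_stack([flat.ravel(), flon.ravel()])).reshape(fg.shape)

    out = fine_baseline.copy()
    valid = ~out.mask
    if mode == "additive":
        out.values[valid] += anom[valid]
    else:
        out.values[valid] *= anom[valid]
    return out


# ---------------------------------------------------------------------------
# Ground-truth suitability and occurrence sampling
# ---------------------------------------------------------------------------

def true_suitability(stack: RasterStack, niche: TrueNiche) -> Raster:
    """Evaluate the ground-truth Gaussian niche over a stack."""
    missing = [v for v in niche.variables if v not in stack]
    if missing:
        raise KeyError(f"stack lacks niche variables: {missing}")
    logs = np.zeros(stack.grid.shape)
    for v in niche.variables:
        z = (stack[v].values - niche.optima[v]) / niche.tolerances[v]
        logs += -0.5 * z ** 2
    vals = niche.max_suitability * np.exp(logs)
    mask = stack.mask
    vals = np.where(mask, 0.0, vals)
    return Raster(stack.grid, vals, mask)


def sample_occurrences(suitability: Raster, n_records: int,
                       clustering: float = 0.0, frac_bad: float = 0.0,
                       duplicate_frac: float = 0.15,
                       seed: int = 0) -> list[OccurrenceRecord]:
    """Draw presence-only occurrence records from a suitability surface.

    Cells are drawn with probability proportional to suitability.  With
    ``clustering`` > 1 (expected records per survey cluster) records are
    generated around suitability-weighted cluster centers, mimicking the
    spatial clustering of field surveys.  ``frac_bad`` of the records are made
    rejectable: half lose their coordinates, half get a positional-confidence
    diameter above 5 km.  ``duplicate_frac`` of the good records repeat an
    earlier record's coordinates (re-collections at a known locality).
    """
    if not 0 <= frac_bad <= 1:
        raise ValueError("frac_bad must be in [0, 1]")
    if n_records == 0:
        return []
    g = suitability.grid
    w = np.where(suitability.mask, 0.0, np.clip(suitability.values, 0.0, None)).ravel()
    total = w.sum()
    if total <= 0:
        raise SamplingError("suitability is zero everywhere; cannot sample presences")
    p = w / total

    rng = np.random.default_rng(seed)
    n_bad = int(round(frac_bad * n_records))
    n_good = n_records - n_bad

    if clustering > 1 and n_good > 0:
        n_clusters = max(1, int(math.ceil(n_good / clustering)))
        centers = rng.choice(w.size, size=n_clusters, p=p)
        assign = rng.integers(0, n_clusters, size=n_good)
        cells = centers[assign]
        # scatter records into the 3x3 neighbourhood of their cluster center
        rr, cc = np.unravel_index(cells, g.shape)
        rr = np.clip(rr + rng.integers(-1, 2, size=n_good), 0, g.n_rows - 1)
        cc = np.clip(cc + rng.integers(-1, 2, size=n_good), 0, g.n_cols - 1)
    else:
        cells = rng.choice(w.size, size=n_good, p=p)
        rr, cc = np.unravel_index(cells, g.shape)

    records: list[OccurrenceRecord] = []
    coords: list[tuple[float, float]] = []
    for i in range(n_good):
        if coords and rng.random() < duplicate_frac:
            lon, lat = coords[rng.integers(0, len(coords))]
        else:
            u, v = rng.random(2)
            lon = g.origin_lon + (cc[i] + 0.1 + 0.8 * u) * g.cell_size
            lat = g.origin_lat - (rr[i] + 0.1 + 0.8 * v) * g.cell_size
            lon, lat = round(lon, 6), round(lat, 6)
        coords.append((lon, lat))
        records.append(OccurrenceRecord(
            record_id=f"R{i + 1:05d}", lon=lon, lat=lat,
            confidence_km=float(round(rng.uniform(0.01, 0.05), 3)),
            source="field_survey", year=int(rng.integers(1941, 2007))))

    for j in range(n_bad):
        rid = f"R{n_good + j + 1:05d}"
        if j % 2 == 0:  # ungeoreferenceable historical record
            records.append(OccurrenceRecord(rid, None, None, None,
                                            "literature", int(rng.integers(1941, 2007))))
        else:           # imprecise historical locality, 6-100 km confidence
            cell = rng.choice(w.size, p=p)
            r0, c0 = np.unravel_index(cell, g.shape)
            lon, lat = g.cell_center(int(r0), int(c0))
            records.append(OccurrenceRecord(rid, round(lon, 6), round(lat, 6),
                                            float(round(rng.uniform(6.0, 100.0), 1)),
                                            "specimen", int(rng.integers(1941, 2007))))
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


# ---------------------------------------------------------------------------
# Survey fixture with the historical count structure
# ---------------------------------------------------------------------------

def make_survey_fixture(grid_spec: GridSpec,
                        suitability: Raster | None = None,
                        n_raw: int = 719, n_used: int = 713,
                        n_localities: int = 349, n_cells: int = 197,
                        seed: int = 0) -> list[OccurrenceRecord]:
    """Build a raw record set with a prescribed cleaning-chain structure.

    Defaults mirror the historical Arabica survey: 719 raw records of which 6
    are rejectable (3 without coordinates, 3 with confidence diameter > 5 km),
    leaving 713 usable records at exactly 349 distinct georeferenced points
    spread over exactly 197 grid cells.  Point coordinates are multiples of
    0.001 degrees strictly inside their cell, so they survive 4-decimal
    deduplication unchanged and never sit on a cell edge.
    """
    n_bad = n_raw - n_used
    if not (n_cells <= n_localities <= n_used and n_bad >= 0):
        raise ValueError("need n_cells <= n_localities <= n_used <= n_raw")
    g = grid_spec
    if n_cells > g.n_rows * g.n_cols:
        raise GridError("grid too small for the requested number of occupied cells")
    rng = np.random.default_rng(seed)

    if suitability is not None:
        w = np.where(suitability.mask, 0.0, np.clip(suitability.values, 0, None)).ravel()
        if w.sum() <= 0:
            raise SamplingError("suitability is zero everywhere")
        cells = rng.choice(w.size, size=n_cells, replace=False, p=w / w.sum())
    else:
        cells = rng.choice(g.n_rows * g.n_cols, size=n_cells, replace=False)

    # distribute localities over cells: each occupied cell gets >= 1
    extra = rng.integers(0, n_cells, size=n_localities - n_cells)
    per_cell = np.bincount(extra, minlength=n_cells) + 1

    # sub-cell offsets on a 0.001-degree lattice, strictly interior
    n_steps = max(2, int(g.cell_size / 0.001) - 1)
    points: list[tuple[float, float]] = []
    for cell, k in zip(cells, per_cell):
        r0, c0 = np.unravel_index(cell, g.shape)
        combos = rng.choice(n_steps * n_steps, size=int(k), replace=False)
        for cmb in combos:
            i, j = divmod(int(cmb), n_steps)
            lon = round(g.origin_lon + c0 * g.cell_size + (j + 1) * 0.001, 4)
            lat = round(g.origin_lat - r0 * g.cell_size - (i + 1) * 0.001, 4)
            points.append((lon, lat))
    assert len(points) == n_localities

    # distribute records over localities: each point >= 1 record
    extra = rng.integers(0, n_localities, size=n_used - n_localities)
    per_point = np.bincount(extra, minlength=n_localities) + 1

    records: list[OccurrenceRecord] = []
    rid = 0
    for (lon, lat), k in zip(points, per_point):
        for _ in range(int(k)):
            rid += 1
            gps = rng.random() < 0.9
            records.append(OccurrenceRecord(
                record_id=f"R{rid:05d}", lon=lon, lat=lat,
                confidence_km=float(round(rng.uniform(0.01, 0.05), 3)) if gps
                else float(round(rng.uniform(1.0, 5.0), 2)),
                source="field_survey" if gps else "specimen",
                year=int(rng.integers(1941, 2007))))
    for j in range(n_bad):
        rid += 1
        if j < (n_bad + 1) // 2:
            records.append(OccurrenceRecord(f"R{rid:05d}", None, None, None,
                                            "literature", int(rng.integers(1900, 1960))))
        else:
            lon, lat = points[int(rng.integers(0, n_localities))]
            records.append(OccurrenceRecord(f"R{rid:05d}", lon, lat,
                                            float(round(rng.uniform(10.0, 100.0), 1)),
                                            "literature", int(rng.integers(1900, 1960))))
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]
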