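"""Occurrence-record cleaning for presence-only niche modelling.

Raw records (field surveys, herbarium specimens, literature) carry a
positional-confidence diameter in km.  The cleaning chain is:

1. ``filter_records`` — reject records without coordinates or with confidence
   diameter above 5 km (coarser than the modelling grid);
2. ``deduplicate`` — collapse records at identical georeferenced points into
   unique *localities*;
3. ``one_per_cell`` — keep at most one locality per modelling grid cell (the
   MaxEnt sample set);
4. ``thin_min_distance`` — optional spatial thinning to a minimum pairwise
   separation in degrees, to reduce spatial sorting bias;
5. ``nearest_neighbour_index`` — a Clark-Evans style clustering diagnostic
   (clustered / random / dispersed).

Counts are non-increasing along the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec, GridError

CSV_COLUMNS = ["record_id", "lon", "lat", "confidence_km", "source", "year"]

REASON_NO_GEOREFERENCE = "no_georeference"
REASON_LOW_PRECISION = "low_precision"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One raw presence observation.

    ``confidence_km`` is the diameter (km) of the circle the observation is
    confident to lie in; GPS readings are typically 0.01-0.05 km, estimated
    historical localities 1-100 km.  ``lon``/``lat`` may be missing for
    records that could not be georeferenced.
    """

    record_id: str
    lon: float | None
    lat: float | None
    confidence_km: float | None
    source: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise ValueError(f"{self.record_id}: lon {self.lon} outside [-180, 180]")
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise ValueError(f"{self.record_id}: lat {self.lat} outside [-90, 90]")

    @property
    def has_coordinates(self) -> bool:
        return self.lon is not None and self.lat is not None


@dataclass
class Locality:
    """A unique georeferenced point with the ids of its member records."""

    lon: float
    lat: float
    member_record_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CSV I/O (dialect shared with the synthetic generator)
# ---------------------------------------------------------------------------

def write_records_csv(records: list[OccurrenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.record_id, r.lon, r.lat, r.confidence_km, r.source, r.year) for r in records],
        columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(OccurrenceRecord(
            record_id=str(row.record_id),
            lon=None if pd.isna(row.lon) else float(row.lon),
            lat=None if pd.isna(row.lat) else float(row.lat),
            confidence_km=None if pd.isna(row.confidence_km) else float(row.confidence_km),
            source="" if pd.isna(row.source) else str(row.source),
            year=None if pd.isna(row.year) else int(row.year)))
    return out


def write_rejection_report(rejected: list[tuple[OccurrenceRecord, str]],
                           path: str | Path) -> None:
    pd.DataFrame([(r.record_id, reason) for r, reason in rejected],
                 columns=["record_id", "reason"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning chain
# ---------------------------------------------------------------------------

def filter_records(records: list[OccurrenceRecord], max_diameter_km: float = 5.0,
                   ) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]]]:
    """Partition records into accepted and rejected-with-reason.

    Rejects records with no coordinates (``no_georeference``) and records
    whose confidence diameter strictly exceeds ``max_diameter_km``
    (``low_precision``); a diameter exactly at the limit is kept.  Records
    without a stated confidence but with coordinates are kept.
    """
    if max_diameter_km <= 0:
        raise ValueError("max_diameter_km must be > 0")
    accepted: list[OccurrenceRecord] = []
    rejected: list[tuple[OccurrenceRecord, str]] = []
    for r in records:
        if not r.has_coordinates:
            rejected.append((r, REASON_NO_GEOREFERENCE))
        elif r.confidence_km is not None and r.confidence_km > max_diameter_km:
            rejected.append((r, REASON_LOW_PRECISION))
        else:
            accepted.append(r)
    return accepted, rejected


def deduplicate(records: list[OccurrenceRecord], precision: int = 4) -> list[Locality]:
    """Collapse records at identical points into unique localities.

    Coordinates are compared after rounding to ``precision`` decimal places
    (4 d.p. is ~11 m, finer than any stated confidence).  Localities keep the
    first-seen order; member record ids are preserved.
    """
    out: dict[tuple[float, float], Locality] = {}
    for r in records:
        if not r.has_coordinates:
            raise ValueError(f"record {r.record_id} has no coordinates; filter first")
        key = (round(r.lon, precision), round(r.lat, precision))
        loc = out.get(key)
        if loc is None:
            out[key] = Locality(lon=key[0], lat=key[1], member_record_ids=[r.record_id])
        else:
            loc.member_record_ids.append(r.record_id)
    return list(out.values())


def one_per_cell(localities: list[Locality], grid_spec: GridSpec) -> list[Locality]:
    """Retain at most one locality per grid cell (first in input order).

    Idempotent; raises listing the offenders when a locality falls outside
    the grid extent.
    """
    outside = [loc for loc in localities if not grid_spec.contains(loc.lon, loc.lat)]
    if outside:
        pts = ", ".join(f"({loc.lon}, {loc.lat})" for loc in outside[:10])
        raise GridError(f"{len(outside)} localities outside grid extent: {pts}")
    seen: set[tuple[int, int]] = set()
    kept = []
    for loc in localities:
        cell = grid_spec.cell_index(loc.lon, loc.lat)
        if cell not in seen:
            seen.add(cell)
            kept.append(loc)
    return kept


def thin_min_distance(localities: list[Locality], min_sep_degrees: float = 0.2,
                      seed: int = 0) -> list[Locality]:
    """Greedy spatial thinning to a minimum pairwise separation.

    Distances are planar Euclidean in decimal degrees (matching a
    degrees-based separation criterion, not great-circle km).  Candidates are
    visited in seeded-shuffle order and kept when at least
    ``min_sep_degrees`` from every already-kept point; the retained set is
    maximal but not guaranteed maximum.
    """
    if min_sep_degrees < 0:
        raise ValueError("min_sep_degrees must be >= 0")
    if min_sep_degrees == 0 or len(localities) < 2:
        return list(localities)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(localities))
    kept: list[Locality] = []
    kept_xy: list[tuple[float, float]] = []
    min_sq = min_sep_degrees ** 2
    for i in order:
        loc = localities[i]
        ok = all((loc.lon - x) ** 2 + (loc.lat - y) ** 2 >= min_sq for x, y in kept_xy)
        if ok:
            kept.append(loc)
            kept_xy.append((loc.lon, loc.lat))
    return kept


# ---------------------------------------------------------------------------
# Clustering diagnostic
# ---------------------------------------------------------------------------

CLUSTERED, RANDOM, DISPERSED = "clustered", "random", "dispersed"


@dataclass(frozen=True)
class NearestNeighbourResult:
    r_statistic: float
    z_score: float
    classification: str
    mean_observed: float
    mean_expected: float


def nearest_neighbour_index(points: np.ndarray,
                            study_area: tuple[float, float, float, float],
                            z_critical: float = 1.96) -> NearestNeighbourResult:
    """Average nearest-neighbour (Clark-Evans) clustering diagnostic.

    ``points`` is an (n, 2) array of (lon, lat); ``study_area`` the analysis
    rectangle ``(lon_min, lat_min, lon_max, lat_max)``.  The ratio R is the
    observed mean nearest-neighbour distance over the CSR expectation
    ``0.5 * sqrt(A / n)``; R < 1 indicates clustering, R > 1 dispersion.  The
    z score uses the Donnelly edge-corrected expectation and variance (the
    uncorrected statistic has a positive edge bias of order perimeter/n that
    misclassifies uniform patterns as dispersed); classification is two-sided
    at ``z_critical``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n>=2, 2) array of points")
    lon_min, lat_min, lon_max, lat_max = study_area
    area = (lon_max - lon_min) * (lat_max - lat_min)
    if area <= 0:
        raise ValueError("study area must have positive area")
    n = len(pts)

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    d_obs = float(dists[:, 1].mean())

    d_exp = 0.5 * math.sqrt(area / n)
    perimeter = 2 * ((lon_max - lon_min) + (lat_max - lat_min))
    # Donnelly edge correction to expectation and variance
    d_exp_corr = d_exp + (0.0514 + 0.041 / math.sqrt(n)) * perimeter / n
    var_corr = 0.0703 * area / n ** 2 + 0.037 * perimeter * math.sqrt(area / n ** 5)

    r = d_obs / d_exp if d_exp > 0 else 0.0
    z = (d_obs - d_exp_corr) / math.sqrt(var_corr)
    if z < -z_critical:
        cls = CLUSTERED
    elif z > z_critical:
        cls = DISPERSED
    else:
        cls = RANDOM
    return NearestNeighbourResult(r, z, cls, d_obs, d_exp)


def localities_to_frame(localities: list[Locality]) -> pd.DataFrame:
    """Tabular view: one row per locality with a member count."""
    return pd.DataFrame(
        [(i, loc.lon, loc.lat, len(loc.member_record_ids)) for i, loc in enumerate(localities)],
        columns=["locality_id", "lon", "lat", "n_records"])
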