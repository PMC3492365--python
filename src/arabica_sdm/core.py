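"""Core-locality persistence scoring and protected-area overlay.

A *core locality* keeps a consistently high predicted suitability across all
scenarios and dates (baseline included) — a candidate long-term in-situ
refugium.  Each locality's logistic scores are summed over every surface;
the top fraction by total are flagged as core, with ties broken by lower
variability (std dev across surfaces) and then by id.  An optional overlay
reports which scored localities fall inside protected-area polygons.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape


class CompletenessError(ValueError):
    """Trajectory table does not cover every surface for every locality."""


def score_core(trajectory: pd.DataFrame, core_fraction: float = 0.1) -> pd.DataFrame:
    """Persistence scores from a locality x surface trajectory table.

    ``trajectory`` needs columns ``locality_id, lon, lat, scenario, date,
    score`` with one row per locality per surface (as produced by
    ``tabulate_localities``).  Returns one row per locality with ``total``
    (sum of scores over all surfaces), ``mean``, ``std_dev`` (population),
    ``rank`` (1 = most persistent) and ``is_core`` for the top
    ``core_fraction`` by total.
    """
    if not 0 < core_fraction <= 1:
        raise ValueError("core_fraction must be in (0, 1]")
    surfaces = trajectory[["scenario", "date"]].drop_duplicates()
    n_surfaces = len(surfaces)
    per_loc = trajectory.groupby("locality_id")
    bad = per_loc.size()[per_loc.size() != n_surfaces]
    if len(bad):
        raise CompletenessError(
            f"localities missing surfaces (expected {n_surfaces} rows each): "
            f"{bad.index.tolist()[:10]}")
    if trajectory["score"].isna().any():
        raise CompletenessError("trajectory contains nodata scores")

    agg = per_loc.agg(lon=("lon", "first"), lat=("lat", "first"),
                      total=("score", "sum"), mean=("score", "mean"),
                      std_dev=("score", lambda s: float(np.std(s, ddof=0))))
    agg = agg.reset_index()
    agg = agg.sort_values(["total", "std_dev", "locality_id"],
                          ascending=[False, True, True], kind="mergesort")
    agg["rank"] = np.arange(1, len(agg) + 1)
    n_core = max(1, math.ceil(core_fraction * len(agg)))
    agg["is_core"] = agg["rank"] <= n_core
    return agg.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Protected-area overlay
# ---------------------------------------------------------------------------

class GeometryError(ValueError):
    pass


def load_protected_polygons(path: str | Path) -> list[tuple[str, object]]:
    """(name, shapely polygon) pairs from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    out = []
    for i, feat in enumerate(feats):
        name = str(feat.get("properties", {}).get("name", f"feature_{i}"))
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"{name}: expected polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise GeometryError(f"invalid polygon geometry in feature {name!r}")
        out.append((name, geom))
    return out


def overlay_protected(core_scores: pd.DataFrame,
                      polygons: list[tuple[str, object]],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-in-polygon overlay of scored localities on protected areas.

    Boundary points count as inside.  Returns the per-locality table with
    ``protected_area`` (first containing polygon or empty) and ``inside``,
    plus a per-polygon summary of locality and core-locality counts; the
    summary ends with an ``(outside)`` row — core localities not covered by
    any protected area are the conservation gap.
    """
    names, geoms = zip(*polygons) if polygons else ((), ())
    area_col, inside_col = [], []
    for row in core_scores.itertuples(index=False):
        pt = Point(row.lon, row.lat)
        hit = ""
        for name, geom in polygons:
            if geom.covers(pt):
                hit = name
                break
        area_col.append(hit)
        inside_col.append(bool(hit))
    out = core_scores.copy()
    out["protected_area"] = area_col
    out["inside"] = inside_col

    rows = []
    for name in names:
        sub = out[out["protected_area"] == name]
        rows.append((name, len(sub), int(sub["is_core"].sum())))
    outside = out[~out["inside"]]
    rows.append(("(outside)", len(outside), int(outside["is_core"].sum())))
    summary = pd.DataFrame(rows, columns=["protected_area", "n_localities", "n_core"])
    return out, summary


def core_scores_to_geojson(scored: pd.DataFrame, path: str | Path) -> None:
    feats = []
    for row in scored.itertuples(index=False):
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.lon, row.lat]},
            "properties": {"locality_id": int(row.locality_id),
                           "total": float(row.total),
                           "std_dev": float(row.std_dev),
                           "rank": int(row.rank),
                           "is_core": bool(row.is_core)}})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=2))
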