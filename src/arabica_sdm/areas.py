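"""Area analysis: reclassify suitability surfaces into threshold classes
through time, apply the no-migration exclusion, and account class areas.

Two temporal rules reflect the species' negligible dispersal:

* **no-gain** (always on): a cell unsuitable at baseline stays unsuitable at
  every future date — newly suitable space cannot be colonised;
* **ratchet** (optional): within a scenario a cell's class can never improve
  on its class at any earlier date — once habitat degrades it does not
  recover within the projection horizon.

Areas are in km^2 from the grid cell size with a cos-latitude correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridError, GridSpec, Raster
from .localities import ScenarioProjection
from .thresholds import CLASSES, MASKED_CODE, ThresholdSet, classify_codes


@dataclass
class ClassGrid:
    """Per-cell threshold class for one scenario x date.

    Codes: 0 unsuitable, 1 marginal, 2 intermediate, 3 optimal, 255 masked
    (nodata in the baseline stack)."""

    scenario_id: str
    date: str
    grid: GridSpec
    codes: np.ndarray

    @property
    def key(self) -> tuple[str, str]:
        return (self.scenario_id, self.date)

    def to_raster(self) -> Raster:
        masked = self.codes == MASKED_CODE
        return Raster(self.grid, self.codes.astype(float), masked)


def _classify_surface(proj: ScenarioProjection,
                      thresholds: ThresholdSet) -> np.ndarray:
    codes = classify_codes(proj.surface.values, thresholds)
    codes = codes.astype(np.uint8)
    codes[proj.surface.mask] = MASKED_CODE
    return codes


def reclassify_surfaces(projections: list[ScenarioProjection],
                        thresholds: ThresholdSet,
                        baseline: ScenarioProjection,
                        ratchet: bool = False) -> list[ClassGrid]:
    """Classify every projection surface and apply the temporal rules.

    ``projections`` must be date-ordered within each scenario (raises
    otherwise).  The baseline surface defines the mask and the no-gain set;
    with ``ratchet=True`` the per-cell class within each scenario is
    additionally capped by its class at every earlier date.
    """
    base_codes = _classify_surface(baseline, thresholds)
    base_unsuitable = base_codes == 0
    out = [ClassGrid(baseline.scenario_id, baseline.date, baseline.surface.grid,
                     base_codes)]

    by_scenario: dict[str, list[ScenarioProjection]] = {}
    for proj in projections:
        if proj.key == baseline.key:
            continue
        by_scenario.setdefault(proj.scenario_id, []).append(proj)

    for scenario_id, projs in by_scenario.items():
        dates = [p.date for p in projs]
        if dates != sorted(dates):
            raise ValueError(
                f"projections for scenario {scenario_id} not date-ordered: {dates}")
        prev: np.ndarray | None = None
        for proj in projs:
            if proj.surface.grid != baseline.surface.grid:
                raise GridError("projection does not share the baseline GridSpec")
            codes = _classify_surface(proj, thresholds)
            codes[base_unsuitable] = 0                      # no-gain rule
            if ratchet and prev is not None:
                valid = codes != MASKED_CODE
                codes[valid] = np.minimum(codes[valid], prev[valid])
            codes[base_codes == MASKED_CODE] = MASKED_CODE
            out.append(ClassGrid(scenario_id, proj.date, proj.surface.grid, codes))
            prev = codes
    return out


def compute_area_change(class_grids: list[ClassGrid],
                        baseline: ClassGrid) -> pd.DataFrame:
    """Class areas (disjoint and cumulative) and percent change vs baseline.

    The cumulative area at a level counts every cell at that class or better
    (optimal <= intermediate-cumulative <= marginal-cumulative = all suitable
    space).  Percent change compares each cumulative area to the baseline
    cumulative area at the same level — relative change is the meaningful
    quantity on a synthetic or regional grid.
    """
    cell_area = baseline.grid.cell_areas_km2()

    def class_areas(cg: ClassGrid) -> dict[str, float]:
        if cg.grid != baseline.grid:
            raise GridError("class grids must share the baseline GridSpec")
        return {name: float(cell_area[cg.codes == code].sum())
                for code, name in enumerate(CLASSES)}

    base = class_areas(baseline)
    base_cum = {"optimal": base["optimal"],
                "intermediate": base["optimal"] + base["intermediate"],
                "marginal": base["optimal"] + base["intermediate"] + base["marginal"]}

    rows = []
    for cg in class_grids:
        areas = class_areas(cg)
        cum = {"optimal": areas["optimal"],
               "intermediate": areas["optimal"] + areas["intermediate"],
               "marginal": areas["optimal"] + areas["intermediate"] + areas["marginal"]}
        for name in CLASSES:
            cum_area = cum.get(name)
            if cum_area is None:       # 'unsuitable' has no cumulative level
                pct = float("nan")
            elif base_cum[name] > 0:
                pct = 100.0 * (cum_area - base_cum[name]) / base_cum[name]
            else:
                pct = float("nan")
            rows.append((cg.scenario_id, cg.date, name, areas[name],
                         cum_area if cum_area is not None else float("nan"), pct))
    return pd.DataFrame(rows, columns=["scenario", "date", "class",
                                       "area_km2", "cumulative_area_km2",
                                       "pct_change_vs_baseline"])
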