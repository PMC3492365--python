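"""Locality analysis: project the niche model through scenarios and dates,
score every unique locality on every surface, and tabulate threshold-class
counts per scenario x date (plus per-locality score trajectories for
histogramming)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Raster, RasterStack
from .maxent import NicheModel
from .occurrences import Locality
from .thresholds import CLASSES, ThresholdSet, classify


@dataclass
class ScenarioProjection:
    """One logistic suitability surface for a scenario x date."""

    scenario_id: str
    date: str
    surface: Raster

    @property
    def key(self) -> tuple[str, str]:
        return (self.scenario_id, self.date)


def project_scenarios(model: NicheModel,
                      stacks: list[RasterStack]) -> list[ScenarioProjection]:
    """Project the fitted model onto every stack (baseline included).

    Environment values outside the training bounds are clamped by the
    feature scaler, so novel future climates never extrapolate the fitted
    response.  Raises when a stack lacks one of the model's variables.
    """
    out = []
    for stack in stacks:
        surface = model.predict_stack(stack, output="logistic")
        out.append(ScenarioProjection(stack.scenario_id, stack.date, surface))
    return out


@dataclass
class ClassificationTable:
    """Locality counts per threshold class for each scenario x date column."""

    counts: pd.DataFrame  # index: class name; columns: (scenario, date)
    n_localities: int

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def suitable_counts(self) -> pd.Series:
        """Localities in any suitable class (optimal+intermediate+marginal)."""
        return self.counts.loc[["optimal", "intermediate", "marginal"]].sum(axis=0)

    def unsuitable_fraction(self) -> pd.Series:
        return self.counts.loc["unsuitable"] / self.column_sums()

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.columns = [f"{s}_{d}" for s, d in out.columns]
        out.to_csv(path, index_label="class")

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], dict[str, int]],
                    n_localities: int) -> "ClassificationTable":
        df = pd.DataFrame(counts).reindex(list(CLASSES)[::-1]).fillna(0).astype(int)
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["scenario", "date"])
        return cls(counts=df, n_localities=n_localities)


def tabulate_localities(localities: list[Locality],
                        projections: list[ScenarioProjection],
                        thresholds: ThresholdSet,
                        ) -> tuple[ClassificationTable, pd.DataFrame]:
    """Score and classify every locality on every projection surface.

    Locality scores are read from the cell whose center is nearest the point
    (the containing cell under the half-open edge convention).  Localities
    falling on nodata are flagged, excluded from the counts, and reported in
    the trajectory table with class ``"nodata"``.

    Returns the class-count table (columns sum to ``n_localities`` minus
    nodata-flagged) and the per-locality trajectory table with raw scores.
    """
    rows = []
    counts: dict[tuple[str, str], dict[str, int]] = {}
    n_excluded: set[int] = set()
    for proj in projections:
        col = {c: 0 for c in CLASSES}
        for i, loc in enumerate(localities):
            score = proj.surface.value_at(loc.lon, loc.lat)
            if np.isnan(score):
                cls_name = "nodata"
                n_excluded.add(i)
            else:
                cls_name = classify(score, thresholds)
                col[cls_name] += 1
            rows.append((i, loc.lon, loc.lat, proj.scenario_id, proj.date,
                         score, cls_name))
        counts[proj.key] = col
    trajectory = pd.DataFrame(
        rows, columns=["locality_id", "lon", "lat", "scenario", "date",
                       "score", "class"])
    table = ClassificationTable.from_counts(counts, len(localities) - len(n_excluded))
    return table, trajectory


def score_histograms(trajectory: pd.DataFrame, n_bins: int = 40) -> pd.DataFrame:
    """Histogram locality scores per scenario x date on equal bins in [0, 1]."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    ok = trajectory[trajectory["class"] != "nodata"]
    for (sc, date), grp in ok.groupby(["scenario", "date"], sort=False):
        hist, _ = np.histogram(grp["score"].to_numpy(), bins=edges)
        for b in range(n_bins):
            out.append((sc, date, edges[b], edges[b + 1], int(hist[b])))
    return pd.DataFrame(out, columns=["scenario", "date", "bin_lo", "bin_hi", "count"])
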