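"""End-to-end pipeline: simulate -> prep -> fit -> project -> localities ->
areas -> core, with a serialized config, per-stage outputs and a checksummed
run manifest.  On a stage failure the manifest records the completed stages
and the failing one before the exception propagates."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import areas as areas_mod
from . import core as core_mod
from .grids import GridSpec, Raster, RasterStack, write_ascii_grid
from .localities import (ClassificationTable, project_scenarios,
                         score_histograms, tabulate_localities)
from .maxent import FeatureSet, evaluate, fit_maxent
from .occurrences import (deduplicate, filter_records, localities_to_frame,
                          nearest_neighbour_index, one_per_cell,
                          read_records_csv, thin_min_distance,
                          write_records_csv, write_rejection_report)
from .synthetic import (ScenarioSpec, TrueNiche, default_scenarios,
                        generate_baseline, generate_future, sample_occurrences,
                        true_suitability)
from .thresholds import derive_thresholds

log = logging.getLogger("arabica_sdm")

STAGES = ("simulate", "prep", "fit", "project", "localities", "areas", "core")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    output_dir: str
    seed: int = 0
    # synthetic landscape (used unless occurrence_csv + raster dirs provided)
    grid: dict = field(default_factory=lambda: {
        "n_rows": 50, "n_cols": 50, "cell_size": 0.02,
        "origin_lon": 35.0, "origin_lat": 8.0})
    n_layers: int = 4
    autocorrelation_length: float = 5.0
    # a strong, narrow niche at the cool/wet margin of the regional climate
    # space (montane-forest envelope): warming, drying and rising seasonality
    # all push the environment away from the optima, so scenario projections
    # erode suitable space rather than relocating it
    niche: dict = field(default_factory=lambda: {
        "optima": {"temp_seasonality": 42.5, "temp_warmest_quarter": 16.2,
                   "precip_driest_month": 60.0, "temp_wettest_quarter": 13.2},
        "tolerances": {"temp_seasonality": 3.6, "temp_warmest_quarter": 1.08,
                       "precip_driest_month": 7.2, "temp_wettest_quarter": 1.08},
        "max_suitability": 1.0})
    n_records: int = 719
    clustering: float = 4.0
    frac_bad: float = 0.01
    scenarios: list[dict] | None = None
    occurrence_csv: str | None = None
    # modelling
    beta: float = 1.0
    hinge_knots: int = 5
    background_size: int = 10000
    test_fraction: float = 0.2
    threshold_levels: tuple[float, float, float] = (0.68, 0.95, 1.00)
    ratchet: bool = False
    core_fraction: float = 0.1
    dedup_precision: int = 4
    max_confidence_km: float = 5.0
    thin_min_sep: float = 0.0   # 0 = no thinning for the main analysis

    def __post_init__(self) -> None:
        if self.n_records < 20:
            raise ConfigError("n_records must be >= 20")
        if not 0 < self.core_fraction <= 1:
            raise ConfigError("core_fraction must be in (0, 1]")
        if self.background_size < 100:
            raise ConfigError("background_size must be >= 100")
        levels = tuple(self.threshold_levels)
        if len(levels) != 3 or levels[-1] != 1.0:
            raise ConfigError("threshold_levels must be 3 values ending at 1.0")
        self.threshold_levels = levels
        GridSpec(**self.grid)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["threshold_levels"] = list(self.threshold_levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid)

    def scenario_specs(self) -> list[ScenarioSpec]:
        if self.scenarios is None:
            return default_scenarios()
        return [ScenarioSpec(**s) for s in self.scenarios]

    def true_niche(self) -> TrueNiche:
        return TrueNiche(optima=dict(self.niche["optima"]),
                         tolerances=dict(self.niche["tolerances"]),
                         max_suitability=self.niche.get("max_suitability", 1.0))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stateful execution of the pipeline stages against one RunConfig."""

    def __init__(self, config: RunConfig) -> None:
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "artifacts": {}, "status": "pending"}
        self.rng = np.random.default_rng(config.seed)
        # in-memory state shared between stages
        self.stacks: list[RasterStack] = []
        self.true_suit: Raster | None = None
        self.records = None
        self.samples = None
        self.unique_localities = None
        self.model = None
        self.eval_report = None
        self.thresholds = None
        self.projections = None
        self.table: ClassificationTable | None = None
        self.trajectory = None
        self.class_grids = None
        self.core_scores = None

    # -- helpers -----------------------------------------------------------
    def _register(self, *paths: Path) -> None:
        for p in paths:
            self.manifest["artifacts"][str(p.relative_to(self.out))] = _sha256(p)

    def _run_stage(self, name: str, fn) -> None:
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        fn()
        dt = time.perf_counter() - t0
        self.manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        log.info("stage %s: done in %.2fs", name, dt)

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        grid = cfg.grid_spec()
        baseline = generate_baseline(grid, cfg.n_layers,
                                     cfg.autocorrelation_length, seed=cfg.seed)
        self.stacks = [baseline]
        for spec in cfg.scenario_specs():
            if spec.is_baseline:
                continue
            self.stacks.append(generate_future(baseline, spec))
        niche = cfg.true_niche()
        self.true_suit = true_suitability(baseline, niche)
        self.records = sample_occurrences(
            self.true_suit, cfg.n_records, clustering=cfg.clustering,
            frac_bad=cfg.frac_bad, seed=cfg.seed + 1)

        grids_dir = self.out / "grids"
        grids_dir.mkdir(exist_ok=True)
        written = []
        for stack in self.stacks:
            for name, raster in stack:
                p = grids_dir / f"{stack.scenario_id}_{stack.date}_{name}.asc"
                write_ascii_grid(raster, p)
                written.append(p)
        p = self.out / "occurrences_raw.csv"
        write_records_csv(self.records, p)
        tp = grids_dir / "true_suitability.asc"
        write_ascii_grid(self.true_suit, tp)
        self._register(p, tp, *written)

    def prep(self) -> None:
        cfg = self.cfg
        if self.records is None:
            if cfg.occurrence_csv:
                self.records = read_records_csv(cfg.occurrence_csv)
            else:
                self.records = read_records_csv(self.out / "occurrences_raw.csv")
        accepted, rejected = filter_records(self.records, cfg.max_confidence_km)
        self.unique_localities = deduplicate(accepted, cfg.dedup_precision)
        samples = one_per_cell(self.unique_localities, cfg.grid_spec())
        if cfg.thin_min_sep > 0:
            samples = thin_min_distance(samples, cfg.thin_min_sep, seed=cfg.seed + 2)
        self.samples = samples

        g = cfg.grid_spec()
        pts = np.array([(l.lon, l.lat) for l in samples])
        nn = nearest_neighbour_index(
            pts, (g.origin_lon, g.lat_min, g.lon_max, g.origin_lat))

        rej = self.out / "rejected_records.csv"
        write_rejection_report(rejected, rej)
        locs = self.out / "unique_localities.csv"
        localities_to_frame(self.unique_localities).to_csv(locs, index=False)
        samp = self.out / "model_samples.csv"
        localities_to_frame(self.samples).to_csv(samp, index=False)
        nnp = self.out / "nearest_neighbour.json"
        nnp.write_text(json.dumps({
            "r_statistic": nn.r_statistic, "z_score": nn.z_score,
            "classification": nn.classification}, indent=2))
        self._register(rej, locs, samp, nnp)
        log.info("prep: %d raw -> %d accepted -> %d localities -> %d samples "
                 "(clustering: %s, R=%.3f)", len(self.records), len(accepted),
                 len(self.unique_localities), len(self.samples),
                 nn.classification, nn.r_statistic)

    def _baseline_stack(self) -> RasterStack:
        for s in self.stacks:
            if s.date == "2000":
                return s
        raise ConfigError("no baseline (date 2000) stack available")

    def _background_env(self, stack: RasterStack) -> np.ndarray:
        mask = stack.mask
        rows, cols = np.nonzero(~mask)
        n = min(self.cfg.background_size, len(rows))
        idx = self.rng.choice(len(rows), size=n, replace=False)
        return stack.env_matrix(rows[idx], cols[idx])

    def fit(self) -> None:
        cfg = self.cfg
        baseline = self._baseline_stack()
        rc = [baseline.grid.cell_index(l.lon, l.lat) for l in self.samples]
        rows = np.array([r for r, _ in rc])
        cols = np.array([c for _, c in rc])
        presence_env = baseline.env_matrix(rows, cols)
        background_env = self._background_env(baseline)

        self.eval_report = evaluate(
            presence_env, background_env, variables=baseline.layer_names,
            feature_kwargs={"hinge_knots": cfg.hinge_knots}, beta=cfg.beta,
            test_fraction=cfg.test_fraction, seed=cfg.seed + 3)
        # final model on all samples
        fs = FeatureSet.from_data(baseline.layer_names,
                                  np.vstack([presence_env, background_env]),
                                  hinge_knots=cfg.hinge_knots)
        self.model = fit_maxent(presence_env, background_env,
                                feature_set=fs, beta=cfg.beta)
        self._presence_env = presence_env
        self._background_env_cache = background_env

        mp = self.out / "model.json"
        self.model.to_json(mp)
        ep = self.out / "evaluation.json"
        self.eval_report.to_json(ep)
        self._register(mp, ep)
        log.info("fit: train AUC %.3f, test AUC %.3f",
                 self.eval_report.train_auc, self.eval_report.test_auc)

    def project(self) -> None:
        self.projections = project_scenarios(self.model, self.stacks)
        surf_dir = self.out / "surfaces"
        surf_dir.mkdir(exist_ok=True)
        written = []
        for proj in self.projections:
            p = surf_dir / f"suitability_{proj.scenario_id}_{proj.date}.asc"
            write_ascii_grid(proj.surface, p)
            written.append(p)
        self._register(*written)

    def localities(self) -> None:
        cfg = self.cfg
        baseline_proj = next(p for p in self.projections if p.date == "2000")
        scores = np.array([baseline_proj.surface.value_at(l.lon, l.lat)
                           for l in self.unique_localities])
        ok = ~np.isnan(scores)
        self.thresholds = derive_thresholds(scores[ok], cfg.threshold_levels)
        self.table, self.trajectory = tabulate_localities(
            self.unique_localities, self.projections, self.thresholds)

        tp = self.out / "thresholds.json"
        self.thresholds.to_json(tp)
        ct = self.out / "classification_table.csv"
        self.table.to_csv(ct)
        lc = self.out / "locality_classes.csv"
        self.trajectory.to_csv(lc, index=False)
        hp = self.out / "score_histograms.csv"
        score_histograms(self.trajectory).to_csv(hp, index=False)
        figs = self._locality_figures()
        self._register(tp, ct, lc, hp, *figs)

    def areas(self) -> None:
        baseline_proj = next(p for p in self.projections if p.date == "2000")
        self.class_grids = areas_mod.reclassify_surfaces(
            self.projections, self.thresholds, baseline_proj,
            ratchet=self.cfg.ratchet)
        baseline_grid = next(g for g in self.class_grids if g.date == "2000")
        change = areas_mod.compute_area_change(self.class_grids, baseline_grid)
        cg_dir = self.out / "class_grids"
        cg_dir.mkdir(exist_ok=True)
        written = []
        for cg in self.class_grids:
            p = cg_dir / f"classes_{cg.scenario_id}_{cg.date}.asc"
            write_ascii_grid(cg.to_raster(), p)
            written.append(p)
        ap = self.out / "area_change.csv"
        change.to_csv(ap, index=False)
        self._register(ap, *written)

    def core(self) -> None:
        # exclude nodata-flagged localities from persistence scoring
        traj = self.trajectory[self.trajectory["class"] != "nodata"]
        bad_ids = self.trajectory.loc[self.trajectory["class"] == "nodata",
                                      "locality_id"].unique()
        traj = traj[~traj["locality_id"].isin(bad_ids)]
        self.core_scores = core_mod.score_core(traj, self.cfg.core_fraction)
        cp = self.out / "core_localities.csv"
        self.core_scores.to_csv(cp, index=False)
        gj = self.out / "core_localities.geojson"
        core_mod.core_scores_to_geojson(self.core_scores, gj)
        self._register(cp, gj)

    # -- figures -----------------------------------------------------------
    def _locality_figures(self) -> list[Path]:
        out = []
        table = self.table.counts
        fig, ax = plt.subplots(figsize=(10, 4))
        cols = [f"{s}\n{d}" for s, d in table.columns]
        bottom = np.zeros(len(cols))
        for cls, color in zip(["optimal", "intermediate", "marginal", "unsuitable"],
                              ["#1a7832", "#7fc97f", "#e8d44f", "#b5b5b5"]):
            vals = table.loc[cls].to_numpy(float)
            ax.bar(cols, vals, bottom=bottom, label=cls, color=color)
            bottom += vals
        ax.set_ylabel("localities")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = self.out / "locality_classes_stacked.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)

        hist = score_histograms(self.trajectory)
        keys = hist[["scenario", "date"]].drop_duplicates().to_numpy()
        fig, axes = plt.subplots(1, len(keys), figsize=(2.2 * len(keys), 2.4),
                                 sharey=True)
        for ax, (sc, date) in zip(np.atleast_1d(axes), keys):
            sub = hist[(hist.scenario == sc) & (hist.date == date)]
            ax.bar(sub.bin_lo, sub["count"], width=0.025, align="edge")
            for tau in self.thresholds.taus:
                ax.axvline(tau, color="red", lw=0.6, ls="--")
            ax.set_title(f"{sc} {date}", fontsize=8)
        fig.tight_layout()
        p2 = self.out / "locality_score_histograms.png"
        fig.savefig(p2, dpi=120)
        plt.close(fig)
        out.append(p2)
        return out


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    On a stage failure the manifest records the completed stages and the
    failing one, is written to disk, and the exception propagates.
    """
    run = PipelineRun(config)
    config.to_yaml(run.out / "config.yaml")
    manifest_path = run.out / "manifest.json"
    try:
        for name in stages:
            run._run_stage(name, getattr(run, name))
        run.manifest["status"] = "complete"
    except Exception as exc:
        run.manifest["status"] = "failed"
        run.manifest["failed_stage"] = name
        run.manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(run.manifest, indent=2))
        raise
    manifest_path.write_text(json.dumps(run.manifest, indent=2))
    run._register(run.out / "config.yaml")
    return run.manifest
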