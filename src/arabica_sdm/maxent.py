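"""Presence-background maximum-entropy niche model.

A compact re-implementation of the maxent species-distribution model: the
habitat distribution over background cells is the Gibbs distribution

    P(x) = exp(lambda . f(x)) / Z,     Z = sum_background exp(lambda . f(x)),

whose weights maximise the L1-penalised presence log-likelihood

    J(lambda) = mean_presence[lambda . f] - log Z - beta * sum_f s_f |lambda_f|.

At the optimum every feature satisfies the maxent box constraint
``|E_model[f] - mean_presence[f]| <= beta * s_f`` where ``s_f`` is the
presence standard error of the feature.  Feature classes are the familiar
linear / quadratic / pairwise-product / hinge expansions of the environmental
variables scaled to [0, 1].  Predictions are exposed on the raw scale
(normalised over the fitting background) and on the entropy-pivoted logistic
scale in (0, 1): ``p = e^H r / (1 + e^H r)`` where ``H`` is the entropy of
the fitted raw distribution, so a cell with a "typical" raw score maps to
0.5.

The L1 term is handled exactly by splitting each weight into its positive and
negative parts and bound-constraining both at zero (L-BFGS-B); no smoothing
of the penalty is involved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import Raster, RasterStack


class ConvergenceError(RuntimeError):
    pass


class NotFittedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Maxent feature classes and the per-variable scaling bounds.

    Variables are min-max scaled to [0, 1] using ``bounds`` before expansion;
    values outside the bounds are clamped (the conservative choice when
    projecting onto novel future climates) and counted in
    ``clamp_warnings``.
    """

    variables: list[str]
    linear: bool = True
    quadratic: bool = True
    product: bool = True
    hinge: bool = True
    hinge_knots: int = 5
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    clamp_warnings: int = 0

    def __post_init__(self) -> None:
        if not (self.linear or self.quadratic or self.product or self.hinge):
            raise ValueError("at least one feature class must be enabled")

    @classmethod
    def from_data(cls, variables: list[str], env: np.ndarray, **kwargs) -> "FeatureSet":
        env = np.asarray(env, dtype=float)
        bounds = {v: (float(env[:, j].min()), float(env[:, j].max()))
                  for j, v in enumerate(variables)}
        for v, (lo, hi) in bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"non-finite scaling bounds for {v}")
            if hi <= lo:
                bounds[v] = (lo, lo + 1e-12)
        return cls(variables=list(variables), bounds=bounds, **kwargs)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        V = self.variables
        if self.linear:
            names += V
        if self.quadratic:
            names += [f"{v}^2" for v in V]
        if self.product:
            names += [f"{u}*{v}" for i, u in enumerate(V) for v in V[i + 1:]]
        if self.hinge:
            knots = self._knots()
            names += [f"hinge({v},{k:.4f})" for v in V for k in knots]
        return names

    def _knots(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.hinge_knots + 2)[1:-1]

    def feature_classes(self) -> list[str]:
        """Feature class per design-matrix column (aligned with
        :attr:`feature_names`)."""
        V = len(self.variables)
        classes: list[str] = []
        if self.linear:
            classes += ["linear"] * V
        if self.quadratic:
            classes += ["quadratic"] * V
        if self.product:
            classes += ["product"] * (V * (V - 1) // 2)
        if self.hinge:
            classes += ["hinge"] * (V * self.hinge_knots)
        return classes

    def scale(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(np.asarray(env, dtype=float))
        if env.shape[1] != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} variables, got {env.shape[1]}")
        out = np.empty_like(env)
        for j, v in enumerate(self.variables):
            lo, hi = self.bounds[v]
            x = (env[:, j] - lo) / (hi - lo)
            n_out = int(np.sum((x < 0) | (x > 1)))
            if n_out:
                self.clamp_warnings += n_out
            out[:, j] = np.clip(x, 0.0, 1.0)
        return out

    def build(self, env: np.ndarray) -> np.ndarray:
        """Design matrix for raw environment vectors; all entries in [0, 1].

        Column order matches :attr:`feature_names`: linear, quadratic,
        pairwise products (i < j), then hinge features grouped by variable
        with knots innermost."""
        x = self.scale(env)
        V = x.shape[1]
        cols: list[np.ndarray] = []
        if self.linear:
            cols.append(x)
        if self.quadratic:
            cols.append(x ** 2)
        if self.product:
            cols += [(x[:, i] * x[:, j])[:, None]
                     for i in range(V) for j in range(i + 1, V)]
        if self.hinge:
            knots = self._knots()
            for j in range(V):
                cols.append(np.clip((x[:, j][:, None] - knots) / (1.0 - knots),
                                    0.0, None))
        return np.hstack(cols)


def build_features(env: np.ndarray, feature_set: FeatureSet) -> np.ndarray:
    """Functional alias for :meth:`FeatureSet.build`."""
    return feature_set.build(env)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class NicheModel:
    """A fitted maxent model: features, weights, normaliser and entropy."""

    feature_set: FeatureSet
    weights: np.ndarray | None = None
    linear_predictor_offset: float = 0.0
    log_z: float | None = None
    entropy: float | None = None
    n_presence: int = 0
    n_background: int = 0
    dropped_features: list[str] = field(default_factory=list)

    @property
    def is_fitted(self) -> bool:
        return self.weights is not None

    def _require_fitted(self) -> None:
        if not self.is_fitted:
            raise NotFittedError("model has not been fitted")

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, env: np.ndarray) -> np.ndarray:
        self._require_fitted()
        F = self.feature_set.build(env)
        return F @ self.weights + self.linear_predictor_offset

    def predict(self, env: np.ndarray, output: str = "logistic") -> np.ndarray:
        """Suitability scores: ``raw`` (sums to 1 over the fitting
        background) or ``logistic`` (entropy-pivoted, in (0, 1))."""
        self._require_fitted()
        eta = self.linear_predictor(env)
        if output == "raw":
            return np.exp(eta - self.log_z)
        if output == "logistic":
            # p = e^H r / (1 + e^H r), numerically via the log scale
            log_odds = self.entropy + eta - self.log_z
            return 1.0 / (1.0 + np.exp(-log_odds))
        raise ValueError(f"unknown output {output!r}")

    def predict_stack(self, stack: RasterStack, output: str = "logistic") -> Raster:
        """Project the model over a raster stack; nodata propagates."""
        missing = [v for v in self.feature_set.variables if v not in stack]
        if missing:
            raise KeyError(f"stack {stack.scenario_id}/{stack.date} lacks layers {missing}")
        mask = stack.mask
        rows, cols = np.nonzero(~mask)
        env = stack.env_matrix(rows, cols, self.feature_set.variables)
        scores = self.predict(env, output=output)
        vals = np.zeros(stack.grid.shape)
        vals[rows, cols] = scores
        return Raster(stack.grid, vals, mask.copy())

    # -- diagnostics -------------------------------------------------------
    def constraint_violation(self, presence_env: np.ndarray,
                             background_env: np.ndarray, beta: float) -> float:
        """Max excess over the maxent box constraints
        ``|E_model[f] - mean_presence[f]| <= beta_f * s_f`` (<= 0 at a true
        optimum, up to solver tolerance).  Features dropped at fit time
        (constant over the background) are excluded."""
        self._require_fitted()
        Fp = self.feature_set.build(presence_env)
        Fb = self.feature_set.build(background_env)
        keep = Fb.std(axis=0) > 1e-12
        eta = Fb @ self.weights
        q = np.exp(eta - logsumexp(eta))
        gap = np.abs(q @ Fb - Fp.mean(axis=0))
        reg = beta * _class_multipliers(self.feature_set.feature_classes(),
                                        len(Fp)) * _feature_se(Fp)
        return float(np.max((gap - reg)[keep]))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        self._require_fitted()
        fs = self.feature_set
        payload = {
            "variables": fs.variables,
            "features": {"linear": fs.linear, "quadratic": fs.quadratic,
                         "product": fs.product, "hinge": fs.hinge,
                         "hinge_knots": fs.hinge_knots},
            "bounds": {v: list(b) for v, b in fs.bounds.items()},
            "weights": self.weights.tolist(),
            "linear_predictor_offset": self.linear_predictor_offset,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "dropped_features": self.dropped_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NicheModel":
        d = json.loads(Path(path).read_text())
        fs = FeatureSet(variables=d["variables"],
                        bounds={v: tuple(b) for v, b in d["bounds"].items()},
                        **d["features"])
        return cls(feature_set=fs, weights=np.asarray(d["weights"]),
                   linear_predictor_offset=d["linear_predictor_offset"],
                   log_z=d["log_z"], entropy=d["entropy"],
                   n_presence=d["n_presence"], n_background=d["n_background"],
                   dropped_features=d["dropped_features"])


def _feature_se(Fp: np.ndarray) -> np.ndarray:
    """Per-feature regularisation scale: presence standard error, floored."""
    n = Fp.shape[0]
    s = Fp.std(axis=0, ddof=0) / np.sqrt(n)
    return np.maximum(s, 1e-4)


# Published default regularisation multipliers per feature class, keyed by
# presence sample size (linear/quadratic/product shrink as samples grow;
# hinge stays at 0.5).  Linearly interpolated, clamped outside the table.
_LQP_BETA_TABLE = ([10, 30, 100], [0.16, 0.10, 0.05])
_HINGE_BETA = 0.5


def _class_multipliers(classes: list[str], n_presence: int) -> np.ndarray:
    lqp = float(np.interp(n_presence, *_LQP_BETA_TABLE))
    per = {"linear": lqp, "quadratic": lqp, "product": lqp, "hinge": _HINGE_BETA}
    return np.array([per[c] for c in classes])


def fit_maxent(presence_env: np.ndarray, background_env: np.ndarray,
               feature_set: FeatureSet | None = None, beta: float = 1.0,
               tol: float = 1e-6, max_iter: int = 500, seed: int = 0,
               ) -> NicheModel:
    """Fit the L1-penalised maxent model.

    ``presence_env``/``background_env`` are (n, n_variables) raw environment
    matrices.  When ``feature_set`` is None, the full default feature set
    (linear + quadratic + product + hinge) is built with scaling bounds from
    the pooled data.  Constant features over the background are dropped with
    a warning.  Raises :class:`ConvergenceError` when the optimiser stops
    with a large projected gradient.
    """
    presence_env = np.atleast_2d(np.asarray(presence_env, dtype=float))
    background_env = np.atleast_2d(np.asarray(background_env, dtype=float))
    if len(presence_env) < 10:
        raise ValueError(f"need >= 10 presences, got {len(presence_env)}")
    if len(background_env) < 10 * len(presence_env):
        warnings.warn("background smaller than 10x presences; estimates of the "
                      "background expectation may be noisy", stacklevel=2)
    if beta < 0:
        raise ValueError("beta must be >= 0")

    if feature_set is None:
        n_vars = presence_env.shape[1]
        pooled = np.vstack([presence_env, background_env])
        feature_set = FeatureSet.from_data(
            [f"var_{j}" for j in range(n_vars)], pooled)

    Fp = feature_set.build(presence_env)
    Fb = feature_set.build(background_env)
    names = feature_set.feature_names

    keep = Fb.std(axis=0) > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant features: {dropped[:5]}",
                      stacklevel=2)
    Fp_k, Fb_k = Fp[:, keep], Fb[:, keep]
    p_mean = Fp_k.mean(axis=0)
    classes_k = [c for c, k in zip(feature_set.feature_classes(), keep) if k]
    # per-feature penalty: global beta x published class multiplier x
    # presence standard error of the feature
    reg = beta * _class_multipliers(classes_k, len(Fp_k)) * _feature_se(Fp_k)
    d = Fp_k.shape[1]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = theta[:d] - theta[d:]
        eta = Fb_k @ lam
        lse = logsumexp(eta)
        q = np.exp(eta - lse)
        nll = -float(p_mean @ lam) + float(lse)
        pen = float(reg @ (theta[:d] + theta[d:]))
        g_lam = -p_mean + q @ Fb_k
        grad = np.concatenate([g_lam + reg, -g_lam + reg])
        return nll + pen, grad

    theta0 = np.zeros(2 * d)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * d),
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12,
                            "maxls": 60})
    # projected gradient at the solution (components free to decrease J)
    _, grad = objective(res.x)
    proj = np.where((res.x <= 1e-12) & (grad > 0), 0.0, grad)
    pg_norm = float(np.max(np.abs(proj)))
    if not res.success and pg_norm > 1e-3:
        raise ConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(projected gradient max {pg_norm:.3e}): {res.message}")

    lam_k = res.x[:d] - res.x[d:]
    lam = np.zeros(len(names))
    lam[keep] = lam_k

    eta_b = Fb_k @ lam_k
    log_z = float(logsumexp(eta_b))
    log_raw = eta_b - log_z
    entropy = float(-(np.exp(log_raw) @ log_raw))

    return NicheModel(feature_set=feature_set, weights=lam, log_z=log_z,
                      entropy=entropy, n_presence=len(presence_env),
                      n_background=len(background_env),
                      dropped_features=dropped)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc_presence_background(presence_scores: np.ndarray,
                            background_scores: np.ndarray) -> float:
    """Probability a random presence outranks a random background point
    (ties count 0.5); the Mann-Whitney statistic computed by ranking."""
    pos = np.asarray(presence_scores, float)
    neg = np.asarray(background_scores, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need non-empty score sets")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass
class EvalReport:
    train_auc: float
    test_auc: float
    contributions: dict[str, float]          # percentages, sum to 100
    jackknife: pd.DataFrame                  # with_only / without gain per variable
    model: NicheModel
    n_train: int
    n_test: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_auc": self.train_auc, "test_auc": self.test_auc,
            "contributions": self.contributions,
            "jackknife": self.jackknife.to_dict(orient="index"),
            "n_train": self.n_train, "n_test": self.n_test}, indent=2))


def _training_gain(model: NicheModel, presence_env: np.ndarray) -> float:
    """Mean presence log-probability relative to the uniform background
    distribution (zero gain = no better than uniform)."""
    eta = model.linear_predictor(presence_env)
    return float(np.mean(eta) - model.log_z + np.log(model.n_background))


def evaluate(presence_env: np.ndarray, background_env: np.ndarray,
             variables: list[str] | None = None,
             feature_kwargs: dict | None = None, beta: float = 1.0,
             test_fraction: float = 0.2, seed: int = 0,
             jackknife: bool = True) -> EvalReport:
    """Train/test evaluation of a maxent fit.

    A seeded random ``test_fraction`` of the presences is held out; the model
    is fitted on the remainder and scored by presence-vs-background AUC on
    both partitions.  Per-variable contributions are permutation importances
    (drop in training AUC when one variable is shuffled across presences and
    background), normalised to sum to 100%.  The jackknife refits the model
    with only / without each variable and reports the training gain.
    """
    presence_env = np.atleast_2d(np.asarray(presence_env, float))
    background_env = np.atleast_2d(np.asarray(background_env, float))
    n = len(presence_env)
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n - n_test < 10:
        raise ValueError(f"cannot split {n} presences with test_fraction={test_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train_env, test_env = presence_env[train_idx], presence_env[test_idx]

    n_vars = presence_env.shape[1]
    if variables is None:
        variables = [f"var_{j}" for j in range(n_vars)]
    pooled = np.vstack([presence_env, background_env])
    fkw = feature_kwargs or {}
    fs = FeatureSet.from_data(variables, pooled, **fkw)
    model = fit_maxent(train_env, background_env, feature_set=fs, beta=beta)

    bg_scores = model.predict(background_env, "raw")
    train_auc = auc_presence_background(model.predict(train_env, "raw"), bg_scores)
    test_auc = auc_presence_background(model.predict(test_env, "raw"), bg_scores)

    # permutation importance on the training AUC
    drops = {}
    for j, v in enumerate(variables):
        tr, bg = train_env.copy(), background_env.copy()
        pool = np.concatenate([tr[:, j], bg[:, j]])
        rng.shuffle(pool)
        tr[:, j], bg[:, j] = pool[:len(tr)], pool[len(tr):]
        perm_auc = auc_presence_background(model.predict(tr, "raw"),
                                           model.predict(bg, "raw"))
        drops[v] = max(0.0, train_auc - perm_auc)
    total = sum(drops.values())
    if total > 0:
        contributions = {v: 100.0 * d / total for v, d in drops.items()}
    else:
        contributions = {v: 100.0 / n_vars for v in variables}

    jk_rows = {}
    if jackknife:
        for j, v in enumerate(variables):
            only_fs = FeatureSet.from_data([v], pooled[:, [j]], **fkw)
            m_only = fit_maxent(train_env[:, [j]], background_env[:, [j]],
                                feature_set=only_fs, beta=beta)
            rest = [k for k in range(n_vars) if k != j]
            rest_fs = FeatureSet.from_data([variables[k] for k in rest],
                                           pooled[:, rest], **fkw)
            m_wo = fit_maxent(train_env[:, rest], background_env[:, rest],
                              feature_set=rest_fs, beta=beta)
            jk_rows[v] = {"with_only": _training_gain(m_only, train_env[:, [j]]),
                          "without": _training_gain(m_wo, train_env[:, rest])}
    jk = pd.DataFrame.from_dict(jk_rows, orient="index",
                                columns=["with_only", "without"])

    return EvalReport(train_auc=train_auc, test_auc=test_auc,
                      contributions=contributions, jackknife=jk, model=model,
                      n_train=len(train_idx), n_test=len(test_idx))


def response_curve(model: NicheModel, variable: str,
                   background_env: np.ndarray, n_points: int = 100) -> pd.DataFrame:
    """Logistic response to one variable, others fixed at background means."""
    fs = model.feature_set
    if variable not in fs.variables:
        raise KeyError(f"model has no variable {variable!r}; has {fs.variables}")
    j = fs.variables.index(variable)
    background_env = np.atleast_2d(np.asarray(background_env, float))
    base = background_env.mean(axis=0)
    lo, hi = fs.bounds[variable]
    sweep = np.linspace(lo, hi, n_points)
    env = np.tile(base, (n_points, 1))
    env[:, j] = sweep
    return pd.DataFrame({variable: sweep,
                         "logistic": model.predict(env, "logistic")})
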