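"""Maxent niche model: feature expansion, the penalised fit against a
brute-force oracle, prediction scales, evaluation and response curves."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from arabica_sdm import (FeatureSet, NicheModel, NotFittedError,
                         auc_presence_background, build_features, evaluate,
                         fit_maxent, response_curve)


@pytest.fixture(scope="module")
def toy_1d():
    """20 presences concentrated at high values of one variable, 200
    uniform background points."""
    rng = np.random.default_rng(42)
    background = rng.uniform(0.0, 1.0, size=(200, 1))
    presence = rng.uniform(0.55, 0.95, size=(20, 1))
    fs = FeatureSet(variables=["x"], bounds={"x": (0.0, 1.0)},
                    quadratic=False, product=False, hinge=False)
    return presence, background, fs


class TestFeatureSet:
    def test_linear_quadratic_column_count(self):
        fs = FeatureSet(variables=["a", "b"], bounds={"a": (0, 1), "b": (0, 1)},
                        product=False, hinge=False)
        env = np.random.default_rng(0).uniform(size=(7, 2))
        assert build_features(env, fs).shape == (7, 4)
        assert fs.feature_names == ["a", "b", "a^2", "b^2"]

    def test_full_feature_count(self):
        fs = FeatureSet(variables=list("abc"),
                        bounds={v: (0, 1) for v in "abc"}, hinge_knots=5)
        env = np.random.default_rng(0).uniform(size=(4, 3))
        # 3 linear + 3 quadratic + 3 products + 3*5 hinge
        assert build_features(env, fs).shape[1] == 3 + 3 + 3 + 15
        assert len(fs.feature_names) == 24
        assert len(fs.feature_classes()) == 24

    def test_linear_feature_spans_unit_interval(self):
        fs = FeatureSet(variables=["a"], bounds={"a": (10.0, 30.0)},
                        quadratic=False, product=False, hinge=False)
        F = build_features(np.array([[10.0], [30.0], [20.0]]), fs)
        np.testing.assert_allclose(F.ravel(), [0.0, 1.0, 0.5])

    def test_hinge_closed_form(self):
        fs = FeatureSet(variables=["a"], bounds={"a": (0.0, 1.0)},
                        linear=False, quadratic=False, product=False,
                        hinge=True, hinge_knots=5)
        knots = np.linspace(0, 1, 7)[1:-1]
        F = build_features(np.array([[0.5]]), fs)
        expected = np.clip((0.5 - knots) / (1 - knots), 0, None)
        np.testing.assert_allclose(F.ravel(), expected)

    def test_out_of_bounds_clamped_and_counted(self):
        fs = FeatureSet(variables=["a"], bounds={"a": (0.0, 1.0)},
                        quadratic=False, product=False, hinge=False)
        F = build_features(np.array([[2.0], [-1.0]]), fs)
        np.testing.assert_allclose(F.ravel(), [1.0, 0.0])
        assert fs.clamp_warnings == 2

    def test_all_entries_in_unit_interval(self):
        rng = np.random.default_rng(3)
        env = rng.uniform(-5, 5, size=(50, 3))
        fs = FeatureSet.from_data(list("abc"), env)
        F = build_features(env, fs)
        assert F.min() >= 0.0 and F.max() <= 1.0


class TestFitMaxent:
    def test_raw_normalises_over_background(self, toy_1d):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        assert m.predict(background, "raw").sum() == pytest.approx(1.0, abs=1e-6)

    def test_positive_weight_for_high_value_presences(self, toy_1d):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        assert m.weights[0] > 0

    def test_uniform_presences_large_beta_gives_max_entropy(self):
        """With presences drawn from the background and heavy regularisation
        the fit collapses to the uniform distribution: H -> log(n_bg)."""
        rng = np.random.default_rng(1)
        background = rng.uniform(size=(300, 2))
        presence = background[rng.choice(300, 40, replace=False)]
        fs = FeatureSet.from_data(["a", "b"], background, hinge=False)
        m = fit_maxent(presence, background, feature_set=fs, beta=100.0)
        assert m.entropy == pytest.approx(np.log(300), abs=1e-3)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-6)

    def test_weights_match_grid_search_oracle(self, toy_1d):
        """1-D linear-only fit agrees with a brute-force scan of the
        penalised likelihood over a fine weight grid."""
        presence, background, fs = toy_1d
        beta = 0.5
        m = fit_maxent(presence, background, feature_set=fs, beta=beta)

        # independent objective: penalised negative log-likelihood
        xp = presence.ravel()
        xb = background.ravel()
        mult = np.interp(len(xp), [10, 30, 100], [0.16, 0.10, 0.05])
        s = max(xp.std() / np.sqrt(len(xp)), 1e-4)

        def J(lam):
            return -lam * xp.mean() + logsumexp(lam * xb) \
                + beta * mult * s * abs(lam)

        grid = np.arange(-20.0, 20.0, 0.005)
        lam_star = grid[np.argmin([J(l) for l in grid])]
        assert m.weights[0] == pytest.approx(lam_star, abs=0.01)
        assert J(m.weights[0]) <= J(lam_star) + 1e-9

    def test_box_constraints_hold_after_fit(self, toy_1d,
                                            presence_background100):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        assert m.constraint_violation(presence, background, 0.5) <= 1e-6

        pres_env, bg_env, _ = presence_background100
        fs4 = FeatureSet.from_data(
            ["temp_seasonality", "temp_warmest_quarter",
             "precip_driest_month", "temp_wettest_quarter"],
            np.vstack([pres_env, bg_env]))
        m4 = fit_maxent(pres_env, bg_env, feature_set=fs4, beta=1.0)
        assert m4.constraint_violation(pres_env, bg_env, 1.0) <= 1e-3

    def test_beta_monotonicity_of_weight_norm(self, toy_1d):
        presence, background, _ = toy_1d
        rng = np.random.default_rng(2)
        pres2 = np.column_stack([presence.ravel(),
                                 rng.uniform(size=len(presence))])
        bg2 = np.column_stack([background.ravel(),
                               rng.uniform(size=len(background))])
        norms = []
        for beta in (0.1, 0.5, 1.0, 2.0, 5.0):
            fs = FeatureSet.from_data(["x", "y"], np.vstack([pres2, bg2]),
                                      hinge=False)
            m = fit_maxent(pres2, bg2, feature_set=fs, beta=beta)
            norms.append(np.abs(m.weights).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_too_few_presences_rejected(self, toy_1d):
        _, background, fs = toy_1d
        with pytest.raises(ValueError):
            fit_maxent(np.full((5, 1), 0.5), background, feature_set=fs)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        bg = np.column_stack([rng.uniform(size=200), np.full(200, 3.0)])
        pres = np.column_stack([rng.uniform(0.5, 1.0, 30), np.full(30, 3.0)])
        fs = FeatureSet(variables=["x", "c"],
                        bounds={"x": (0.0, 1.0), "c": (3.0, 3.0 + 1e-12)},
                        quadratic=False, product=False, hinge=False)
        with pytest.warns(UserWarning, match="constant"):
            m = fit_maxent(pres, bg, feature_set=fs, beta=0.5)
        assert "c" in m.dropped_features
        assert m.weights[fs.feature_names.index("c")] == 0.0


class TestPredict:
    def test_logistic_pivot_is_half(self, toy_1d):
        """A cell whose raw score is e^{-H} maps to logistic 0.5."""
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        raw = m.predict(background, "raw")
        logi = m.predict(background, "logistic")
        pivot = np.exp(-m.entropy)
        # interpolate the logistic value at raw = pivot
        order = np.argsort(raw)
        assert np.interp(pivot, raw[order], logi[order]) == pytest.approx(0.5, abs=1e-3)

    def test_logistic_monotone_in_raw(self, toy_1d):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        raw = m.predict(background, "raw")
        logi = m.predict(background, "logistic")
        assert np.array_equal(np.argsort(raw), np.argsort(logi))
        assert np.all((logi > 0) & (logi < 1))

    def test_unfitted_model_raises(self):
        fs = FeatureSet(variables=["x"], bounds={"x": (0, 1)})
        with pytest.raises(NotFittedError):
            NicheModel(feature_set=fs).predict(np.array([[0.5]]))

    def test_json_roundtrip_preserves_predictions(self, toy_1d, tmp_path):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = NicheModel.from_json(p)
        np.testing.assert_allclose(back.predict(background, "logistic"),
                                   m.predict(background, "logistic"))


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc_presence_background([3, 4, 5], [0, 1, 2]) == 1.0

    def test_all_equal_scores_is_half(self):
        assert auc_presence_background([1, 1], [1, 1, 1]) == 0.5

    def test_matches_brute_force_pairwise_count(self):
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 10, 30).astype(float)  # integer scores force ties
        neg = rng.integers(0, 10, 50).astype(float)
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert auc_presence_background(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestEvaluate:
    def test_split_sizes_and_auc_on_synthetic_niche(self, presence_background100):
        pres, bg, _ = presence_background100
        rep = evaluate(pres, bg, variables=["temp_seasonality",
                                            "temp_warmest_quarter",
                                            "precip_driest_month",
                                            "temp_wettest_quarter"],
                       test_fraction=0.2, seed=0, jackknife=False)
        assert rep.n_test == round(0.2 * len(pres))
        assert rep.n_train + rep.n_test == len(pres)
        assert rep.test_auc > 0.9
        assert rep.train_auc > 0.9

    def test_contributions_sum_to_100(self, presence_background100):
        pres, bg, _ = presence_background100
        rep = evaluate(pres, bg, test_fraction=0.2, seed=0, jackknife=True)
        assert sum(rep.contributions.values()) == pytest.approx(100.0, abs=0.1)
        assert all(c >= 0 for c in rep.contributions.values())
        assert set(rep.jackknife.columns) == {"with_only", "without"}
        assert len(rep.jackknife) == 4

    def test_impossible_split_raises(self, toy_1d):
        presence, background, _ = toy_1d
        with pytest.raises(ValueError):
            evaluate(presence, background, test_fraction=0.0)


class TestResponseCurve:
    def test_flat_curve_for_zero_weight_variable(self):
        fs = FeatureSet(variables=["x", "y"],
                        bounds={"x": (0, 1), "y": (0, 1)},
                        quadratic=False, product=False, hinge=False)
        m = NicheModel(feature_set=fs, weights=np.array([2.0, 0.0]),
                       log_z=0.0, entropy=1.0, n_background=100)
        rng = np.random.default_rng(0)
        bg = rng.uniform(size=(50, 2))
        curve = response_curve(m, "y", bg)
        assert curve["logistic"].nunique() == 1

    def test_monotone_curve_for_positive_linear_weight(self):
        fs = FeatureSet(variables=["x"], bounds={"x": (0, 1)},
                        quadratic=False, product=False, hinge=False)
        m = NicheModel(feature_set=fs, weights=np.array([3.0]),
                       log_z=0.0, entropy=1.0, n_background=100)
        curve = response_curve(m, "x", np.array([[0.5]]))
        assert curve["logistic"].is_monotonic_increasing

    def test_quadratic_niche_peaks_at_true_optimum(self):
        """A 1-D Gaussian niche fitted with linear+quadratic features yields
        a unimodal response whose peak lands within one sweep step of the
        true optimum."""
        rng = np.random.default_rng(21)
        bg = rng.uniform(0.0, 1.0, size=(2000, 1))
        opt, tol = 0.6, 0.07
        weights = np.exp(-0.5 * ((bg.ravel() - opt) / tol) ** 2)
        idx = rng.choice(len(bg), size=150, p=weights / weights.sum())
        pres = bg[idx]
        fs = FeatureSet(variables=["x"], bounds={"x": (0.0, 1.0)},
                        product=False, hinge=False)
        m = fit_maxent(pres, bg, feature_set=fs, beta=1.0)
        curve = response_curve(m, "x", bg, n_points=101)
        vals = curve["logistic"].to_numpy()
        peak_i = int(np.argmax(vals))
        peak = curve["x"].iloc[peak_i]
        assert abs(peak - opt) <= 0.01 + 1e-9
        # unimodal: increases to the peak, decreases after
        assert np.all(np.diff(vals[:peak_i + 1]) >= -1e-12)
        assert np.all(np.diff(vals[peak_i:]) <= 1e-12)

    def test_multivariate_response_peaks_near_niche_optimum(self, strong_niche,
                                                            presence_background100):
        """With the other variables at background means, each marginal
        response peaks in the neighbourhood of the true optimum (within a
        niche tolerance)."""
        pres, bg, _ = presence_background100
        variables = ["temp_seasonality", "temp_warmest_quarter",
                     "precip_driest_month", "temp_wettest_quarter"]
        fs = FeatureSet.from_data(variables, np.vstack([pres, bg]))
        m = fit_maxent(pres, bg, feature_set=fs, beta=1.0)
        for v in variables:
            curve = response_curve(m, v, bg, n_points=101)
            peak = curve.loc[curve["logistic"].idxmax(), v]
            lo, hi = fs.bounds[v]
            target = np.clip(strong_niche.optima[v], lo, hi)
            assert abs(peak - target) <= 1.5 * strong_niche.tolerances[v]

    def test_unknown_variable_raises(self, toy_1d):
        presence, background, fs = toy_1d
        m = fit_maxent(presence, background, feature_set=fs, beta=0.5)
        with pytest.raises(KeyError):
            response_curve(m, "nope", background)


def test_recovery_of_known_gaussian_niche(baseline100, suitability100,
                                          presence_background100):
    """The fitted logistic surface rank-correlates > 0.9 with the true
    suitability over the whole landscape."""
    pres, bg, _ = presence_background100
    fs = FeatureSet.from_data(["temp_seasonality", "temp_warmest_quarter",
                               "precip_driest_month", "temp_wettest_quarter"],
                              np.vstack([pres, bg]))
    m = fit_maxent(pres, bg, feature_set=fs, beta=1.0)
    pred = m.predict_stack(baseline100, "logistic")
    rho = spearmanr(pred.values.ravel(), suitability100.values.ravel()).statistic
    assert rho > 0.9
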