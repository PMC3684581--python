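"""The eight model families: shared contract plus family-specific oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import nichecast as nc
from nichecast.sdm_engines import (
    BioclimModel, MahalanobisModel, fit_bioclim, fit_brt, fit_cart,
    fit_domain, fit_gam_k3, fit_glm_quadratic, fit_mahalanobis,
    fit_maxent_like, rescale_unit, FAMILY_FITTERS,
)
from nichecast.weighting_selection import TrainingTable, build_training_table

FAMILIES = list(FAMILY_FITTERS)
WEIGHTED = ["GAM", "GLM", "CART", "BRT"]


# ---------------------------------------------------------------------------
# Shared contract
# ---------------------------------------------------------------------------

class TestSharedContract:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_maps_in_unit_interval_and_masked(self, family, table, grid):
        model = FAMILY_FITTERS[family](table)
        m = nc.predict_map(model, grid)
        vals = m[grid.mask]
        assert np.isfinite(vals).all()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert np.isnan(m[~grid.mask]).all()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_refit_and_repredict_deterministic(self, family, table, grid):
        a = nc.predict_map(FAMILY_FITTERS[family](table), grid)
        b = nc.predict_map(FAMILY_FITTERS[family](table), grid)
        np.testing.assert_array_equal(a[grid.mask], b[grid.mask])

    @pytest.mark.parametrize("family", WEIGHTED)
    def test_weight_scale_invariance(self, family, table, grid):
        # invariance is exact in exact arithmetic; boosting accumulates
        # float noise through hundreds of stage-wise split searches
        atol = 0.02 if family == "BRT" else 1e-8
        scaled = TrainingTable(cells=table.cells, y=table.y, w=table.w * 7.0,
                               X=table.X, phi=table.phi)
        a = nc.predict_map(FAMILY_FITTERS[family](table), grid)
        b = nc.predict_map(FAMILY_FITTERS[family](scaled), grid)
        np.testing.assert_allclose(a[grid.mask], b[grid.mask], atol=atol)

    def test_prediction_ignores_unused_layers(self, table, grid):
        model = fit_glm_quadratic(table, variables=["env1"])
        a = nc.predict_map(model, grid)
        perturbed = grid.copy()
        perturbed.layers["env2"] = perturbed.layers["env2"] + 5.0
        b = nc.predict_map(model, perturbed)
        np.testing.assert_array_equal(a[grid.mask], b[grid.mask])


# ---------------------------------------------------------------------------
# Regression families
# ---------------------------------------------------------------------------

class TestRegressionFamilies:
    def test_intercept_only_gam_predicts_prevalence(self, grid, presences, background):
        for phi in (0.3, 0.7):
            t = nc.build_training_table(grid, presences, background, phi=phi)
            model = fit_gam_k3(t, variables=[])
            p = model.predict_rows(t.X.iloc[:5])
            np.testing.assert_allclose(p, phi, atol=1e-8)

    @pytest.mark.parametrize("fitter", [fit_gam_k3, fit_glm_quadratic])
    def test_duplicated_rows_with_halved_weights_equivalent(self, fitter, table, grid):
        dup = TrainingTable(
            cells=table.cells + table.cells,
            y=np.concatenate([table.y, table.y]),
            w=np.concatenate([table.w, table.w]) / 2.0,
            X=pd.concat([table.X, table.X], ignore_index=True),
        )
        a = nc.predict_map(fitter(table), grid)
        b = nc.predict_map(fitter(dup), grid)
        np.testing.assert_allclose(a[grid.mask], b[grid.mask], atol=1e-7)

    def test_gam_recovers_true_suitability_ranks(self, table, grid, suitability):
        model = fit_gam_k3(table, variables=["env1", "env2"])
        m = nc.predict_map(model, grid)
        rho = spearmanr(suitability[grid.mask], m[grid.mask]).statistic
        assert rho >= 0.9

    def test_glm_coefficient_recovery_at_large_n(self, grid):
        cfg = nc.VirtualSpeciesConfig()
        rng = np.random.default_rng(0)
        X = grid.table(["env1", "env2"]).sample(
            20_000, replace=True, random_state=1).reset_index(drop=True)
        eta = cfg.beta0
        for v, l, q in zip(cfg.true_variables, cfg.beta_linear, cfg.beta_quadratic):
            eta = eta + l * X[v] + q * X[v] ** 2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        t = TrainingTable(cells=[(0, 0)] * len(y), y=y, w=np.ones(len(y)), X=X)
        est = fit_glm_quadratic(t).params  # [b0, x1, x1^2, x2, x2^2]
        true = np.array([-0.14, 16.0, -20.0, 9.6, -16.0])
        # slopes: signs and relative error; intercept is near zero, so a
        # relative criterion is ill-posed there — check it absolutely
        assert np.all(np.sign(est[1:]) == np.sign(true[1:]))
        assert np.max(np.abs((est[1:] - true[1:]) / true[1:])) < 0.2
        assert abs(est[0] - true[0]) < 0.5


# ---------------------------------------------------------------------------
# Tree families
# ---------------------------------------------------------------------------

class TestCart:
    def test_perfect_separator_gives_depth_one_tree(self):
        x = np.linspace(-2, 2, 400)
        t = TrainingTable(cells=[(0, 0)] * 400, y=(x > 0).astype(int),
                          w=np.ones(400), X=pd.DataFrame({"x": x}))
        model = fit_cart(t, seed=0)
        assert model.tree.get_depth() == 1
        p = model.predict_rows(t.X)
        assert set(np.unique(p)) == {0.0, 1.0}
        assert nc.auc(p[x > 0], p[x <= 0]) == 1.0

    def test_pure_noise_prunes_to_constant_prevalence(self):
        roots = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((600, 3)), columns=list("abc"))
            y = rng.binomial(1, 0.3, 600)
            t = TrainingTable(cells=[(0, 0)] * 600, y=y, w=np.ones(600), X=X)
            model = fit_cart(t, seed=seed)
            if model.tree.get_depth() == 0:
                roots += 1
                p = model.predict_rows(X.iloc[:3])
                np.testing.assert_allclose(p, y.mean(), atol=1e-12)
        assert roots >= 9


class TestBrt:
    def test_training_deviance_non_increasing(self, table):
        model = fit_brt(table, n_estimators=150, seed=0)
        assert np.all(np.diff(model.train_deviance) <= 1e-12)

    def test_monotone_signal_recovered(self):
        """Boosted stumps recover y = logistic(2x) monotonically (a
        univariate signal has no interactions, so depth 1 is the natural
        tree depth)."""
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(-2, 2, 800))
        y = rng.binomial(1, 1 / (1 + np.exp(-2 * x)))
        t = TrainingTable(cells=[(0, 0)] * 800, y=y, w=np.ones(800),
                          X=pd.DataFrame({"x": x}))
        p = fit_brt(t, max_depth=1, seed=0).predict_rows(t.X)
        from sklearn.isotonic import IsotonicRegression
        iso = IsotonicRegression().fit(x, p).predict(x)
        assert np.max(np.abs(p - iso)) <= 0.02

    def test_zero_iterations_gives_weighted_prevalence(self, table):
        model = fit_brt(table, n_estimators=0)
        prev = float((table.w * table.y).sum() / table.w.sum())
        np.testing.assert_allclose(model.predict_rows(table.X.iloc[:4]), prev)


# ---------------------------------------------------------------------------
# Presence-only families
# ---------------------------------------------------------------------------

class TestBioclim:
    # presence fixture: 5 records, 2 variables
    P = pd.DataFrame({"A": [1.0, 2, 3, 4, 5], "B": [10.0, 20, 30, 40, 50]})

    def fit(self):
        return fit_bioclim(self.P)

    def test_median_cell_scores_one(self):
        p = self.fit().predict_rows(pd.DataFrame({"A": [3.0], "B": [30.0]}))
        assert p[0] == pytest.approx(1.0)

    def test_beyond_envelope_scores_zero(self):
        p = self.fit().predict_rows(pd.DataFrame({"A": [5.5], "B": [30.0]}))
        assert p[0] == 0.0

    def test_hand_computed_percentile_scores(self):
        # A=2: F=(1+2)/10=0.3 -> 0.6; B=30: F=0.5 -> 1.0; min = 0.6
        # A=4: F=0.7 -> 0.6;  B=50: F=(4+5)/10=0.9 -> 0.2; min = 0.2
        X = pd.DataFrame({"A": [2.0, 4.0], "B": [30.0, 50.0]})
        np.testing.assert_allclose(self.fit().predict_rows(X), [0.6, 0.2])


class TestDomain:
    def test_identical_to_presence_scores_one(self):
        P = pd.DataFrame({"A": [0.0, 10.0], "B": [1.0, 3.0]})
        p = fit_domain(P).predict_rows(P)
        np.testing.assert_allclose(p, 1.0)

    def test_linear_distance_formula(self):
        P = pd.DataFrame({"A": [0.0, 10.0]})
        p = fit_domain(P).predict_rows(pd.DataFrame({"A": [5.0]}))
        assert p[0] == pytest.approx(0.5)

    def test_matches_brute_force_max_similarity(self):
        P = pd.DataFrame({"A": [0.0, 2.0, 5.0], "B": [1.0, 4.0, 2.0]})
        X = pd.DataFrame({"A": [1.0, 3.3, 6.0], "B": [2.0, 2.0, 0.5]})
        model = fit_domain(P)
        got = model.predict_rows(X)
        ranges = {"A": 5.0, "B": 3.0}
        for i in range(len(X)):
            sims = []
            for j in range(len(P)):
                d = np.mean([abs(X.iloc[i][v] - P.iloc[j][v]) / ranges[v]
                             for v in ("A", "B")])
                sims.append(1 - d)
            assert got[i] == pytest.approx(min(1.0, max(max(sims), 0.0)))

    def test_degenerate_variable_raises(self):
        P = pd.DataFrame({"A": [1.0, 1.0], "B": [0.0, 2.0]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_domain(P)


class TestMahalanobis:
    def identity_model(self):
        return MahalanobisModel(mean=np.zeros(2), cov=np.eye(2),
                                variables=("A", "B"))

    def test_centroid_scores_raw_one(self):
        m = self.identity_model()
        raw = m.raw_scores(pd.DataFrame({"A": [0.0], "B": [0.0]}))
        assert raw[0] == pytest.approx(1.0)

    def test_distance_two_scores_minus_three(self):
        raw = self.identity_model().raw_scores(pd.DataFrame({"A": [2.0], "B": [0.0]}))
        assert raw[0] == pytest.approx(-3.0)

    def test_singular_covariance_raises(self):
        P = pd.DataFrame({"A": [1.0, 1.0, 1.0, 1.0], "B": [0.0, 2.0, 1.0, 3.0]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_mahalanobis(P)

    def test_map_spans_unit_interval(self, table, grid):
        m = nc.predict_map(fit_mahalanobis(table), grid)
        assert np.nanmin(m) == pytest.approx(0.0)
        assert np.nanmax(m) == pytest.approx(1.0)


class TestRescaleUnit:
    def test_linear_transform(self):
        np.testing.assert_allclose(rescale_unit([-5.0, 0.0, 1.0]), [0, 5 / 6, 1])

    def test_unit_input_with_endpoints_unchanged(self):
        np.testing.assert_allclose(rescale_unit([0.0, 0.25, 1.0]), [0, 0.25, 1])

    def test_endpoints_attained(self):
        v = rescale_unit(np.random.default_rng(0).uniform(3, 9, 50))
        assert v.min() == 0.0 and v.max() == 1.0

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            rescale_unit([2.0, 2.0])


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, table, grid, tmp_path):
        model = fit_glm_quadratic(table)
        path = tmp_path / "glm.joblib"
        nc.save_model(model, path)
        back = nc.load_model(path)
        np.testing.assert_array_equal(nc.predict_map(model, grid)[grid.mask],
                                      nc.predict_map(back, grid)[grid.mask])


class TestMaxentLike:
    def test_high_x_presences_give_positive_coefficient(self):
        rng = np.random.default_rng(0)
        bg = rng.standard_normal(500)
        pres = rng.standard_normal(60) * 0.3 + 1.5
        X = pd.DataFrame({"x": np.concatenate([pres, bg])})
        y = np.array([1] * 60 + [0] * 500)
        t = TrainingTable(cells=[(0, 0)] * 560, y=y, w=np.ones(560), X=X)
        model = fit_maxent_like(t)
        assert model.beta[0] > 0  # linear feature of x

    def test_uniform_presences_predict_half(self, grid):
        rng = np.random.default_rng(3)
        Xall = grid.table(["env1", "env2"])
        bg_cells = sorted(nc.sample_background(grid, 3000, seed=2))
        pres_idx = rng.choice(len(Xall), 1000, replace=False)
        pres_cells = frozenset(Xall.index[i] for i in pres_idx)
        t = build_training_table(grid, nc.PresenceSet(pres_cells, "u"),
                                 bg_cells, 0.5, ["env1", "env2"])
        p = fit_maxent_like(t).predict_rows(Xall)
        assert np.max(np.abs(p - 0.5)) < 0.05

    def test_output_strictly_inside_unit_interval(self, table, grid):
        m = nc.predict_map(fit_maxent_like(table), grid)
        vals = m[grid.mask]
        assert (vals > 0).all() and (vals < 1).all()
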