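"""OMI niche analysis: ordination, specialization test, clade comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

import nichecast as nc
from nichecast.niche_omi import (
    clade_comparison, marginality, omi_ordination, omi_statistic,
    specialization_test, standardize_env,
)


def _z_frame(values, columns=("v1", "v2")):
    """Z table indexed by synthetic cell ids (0..n-1 in row 0)."""
    values = np.asarray(values, dtype=float)
    idx = pd.MultiIndex.from_tuples([(0, i) for i in range(len(values))],
                                    names=["row", "col"])
    return pd.DataFrame(values, index=idx, columns=list(columns[: values.shape[1]]))


class TestStandardize:
    def test_reference_has_zero_mean_unit_sd(self, grid, background):
        Z = standardize_env(grid, reference_cells=background)
        ref = Z.loc[sorted(background)]
        assert np.allclose(ref.mean(), 0.0, atol=1e-12)
        assert np.allclose(ref.std(ddof=1), 1.0, atol=1e-12)

    def test_roundtrip_destandardization(self, grid):
        Z = standardize_env(grid)
        X = grid.table()
        back = Z * X.std(ddof=1) + X.mean()
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-9)

    def test_constant_variable_rejected(self):
        layers = {"a": np.ones((2, 2)), "b": np.arange(4.0).reshape(2, 2)}
        g = nc.EnvGrid(cell_size_arcmin=10, origin=(0, 1), layers=layers,
                       mask=np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="a"):
            standardize_env(g)


class TestMarginality:
    def test_taxon_occupying_everything_has_zero_marginality(self, grid):
        Z = standardize_env(grid)
        m = marginality(Z, list(Z.index))
        assert np.allclose(m, 0.0, atol=1e-9)

    def test_hand_average_on_fixture(self):
        Z = _z_frame([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0], [3.0, -2.0]])
        m = marginality(Z, [(0, 0), (0, 2)])
        np.testing.assert_allclose(m, [0.0, 0.5])

    def test_duplicate_cells_have_set_semantics(self):
        Z = _z_frame([[1.0, 0.0], [0.0, 2.0]])
        a = marginality(Z, [(0, 0), (0, 1)])
        b = marginality(Z, [(0, 0), (0, 1), (0, 1)])
        np.testing.assert_allclose(a, b)


class TestOmiStatistic:
    def test_hand_fixture(self):
        Z = _z_frame([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0], [3.0, -2.0]])
        assert omi_statistic(Z, [(0, 0), (0, 2)]) == pytest.approx(0.25)

    def test_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        Z = _z_frame(rng.standard_normal((30, 3)), columns=("a", "b", "c"))
        cells = list(Z.index[:8])
        Q = ortho_group.rvs(3, random_state=1)
        ZQ = pd.DataFrame(Z.to_numpy() @ Q, index=Z.index, columns=Z.columns)
        assert omi_statistic(Z, cells) == pytest.approx(
            omi_statistic(ZQ, cells), abs=1e-10)


class TestOrdination:
    def test_single_taxon_rank_one(self):
        Z = _z_frame([[1.0, 1.0], [2.0, 2.0], [-1.0, 0.0], [0.0, -3.0]])
        cells = [(0, 0), (0, 1)]
        axes, eigval = omi_ordination(Z, [nc.PresenceSet(frozenset(cells), "t")])
        m = marginality(Z, cells)
        v1 = axes["OMI1"].to_numpy()
        np.testing.assert_allclose(np.abs(v1), np.abs(m / np.linalg.norm(m)),
                                   atol=1e-12)
        assert eigval[0] / eigval.sum() == pytest.approx(1.0)

    def test_orthogonal_equal_taxa_split_variance_evenly(self):
        Z = _z_frame([[2.0, 0.0], [0.0, 2.0], [-2.0, 0.0], [0.0, -2.0]])
        p1 = nc.PresenceSet(frozenset([(0, 0)]), "a")   # m = (2, 0)
        p2 = nc.PresenceSet(frozenset([(0, 1)]), "b")   # m = (0, 2)
        _, eigval = omi_ordination(Z, [p1, p2])
        assert eigval[0] == pytest.approx(eigval[1])

    def test_trace_identity_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Z = _z_frame(rng.standard_normal((40, 4)), columns=list("abcd"))
            sets, w_parts = [], []
            for k in range(3):
                n_k = int(rng.integers(3, 10))
                cells = [tuple(c) for c in
                         rng.choice(np.array(list(Z.index)), n_k, replace=False)]
                sets.append(nc.PresenceSet(frozenset(cells), f"t{k}"))
            counts = np.array([len(s) for s in sets], float)
            w = counts / counts.sum()
            expected = sum(
                wk * omi_statistic(Z, s.cells) for wk, s in zip(w, sets))
            _, eigval = omi_ordination(Z, sets)
            assert eigval.sum() == pytest.approx(expected, abs=1e-10)

    def test_no_taxa_rejected(self, grid):
        with pytest.raises(ValueError):
            omi_ordination(standardize_env(grid), [])


class TestSpecializationTest:
    def test_p_in_half_open_unit_interval(self, grid, background):
        Z = standardize_env(grid, reference_cells=background)
        cells = sorted(background)[:50]
        p = specialization_test(Z, cells, n_boot=99, seed=0,
                                reference_cells=background)
        assert 0.0 < p <= 1.0

    def test_monotone_in_specialization_strength(self, grid):
        """Mean p decreases as the synthetic taxon grows more specialized.

        Taxa are drawn with sampling weight exp(offset * z1): offset 0 is
        the exchangeable null, larger offsets tilt occupancy up the env1
        gradient and should be detected ever more strongly.
        """
        Z = standardize_env(grid)
        z1 = Z["env1"].to_numpy()
        mean_p = []
        for offset in (0.0, 0.25, 1.0):
            w = np.exp(offset * z1)
            w = w / w.sum()
            ps = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                idx = rng.choice(len(Z), 40, replace=False, p=w)
                cells = [Z.index[i] for i in idx]
                ps.append(specialization_test(Z, cells, n_boot=499, seed=seed))
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]

    def test_zero_bootstrap_rejected(self, grid):
        Z = standardize_env(grid)
        with pytest.raises(ValueError):
            specialization_test(Z, list(Z.index[:5]), n_boot=0)


class TestCladeComparison:
    def test_identical_samples_give_t_zero_p_half(self):
        Z = _z_frame(np.column_stack([np.tile([1.0, 2.0, 3.0], 2),
                                      np.zeros(6) + [1, 2, 3, 1, 2, 3]]),
                     columns=("a", "b"))
        axes = pd.DataFrame({"OMI1": [1.0, 0.0]}, index=["a", "b"])
        out = clade_comparison(Z, axes, list(Z.index[:3]), list(Z.index[3:]))
        row = out[out.gradient == "OMI1"].iloc[0]
        assert row.t == 0.0
        assert row.p_one_sided == 0.5

    def test_separated_means_detected_with_high_power(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
            Z = _z_frame(vals[:, None], columns=("a",))
            axes = pd.DataFrame({"OMI1": [1.0]}, index=["a"])
            out = clade_comparison(Z, axes, list(Z.index[:100]),
                                   list(Z.index[100:]))
            rejections += out[out.gradient == "a"].p_one_sided.iloc[0] < 0.001
        assert rejections >= 198

    def test_direction_reports_observed_ordering(self):
        Z = _z_frame(np.array([[0.0], [0.0], [5.0], [5.0]]), columns=("a",))
        axes = pd.DataFrame({"OMI1": [1.0]}, index=["a"])
        out = clade_comparison(Z, axes, list(Z.index[:2]), list(Z.index[2:]))
        assert (out.direction_taxon1 == "less").all()


class TestRunOmi:
    def test_two_clade_fixture_structure(self, grid, background):
        cfg = nc.VirtualSpeciesConfig(seed=3)
        c1, c2 = nc.make_two_clades(grid, cfg)
        res = nc.run_omi(grid, [c1, c2], reference_cells=background,
                         variables=("env1", "env2"), n_boot=199, seed=0)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert res.pct_variance[0] > 90.0
        assert res.axes["OMI1"].abs().idxmax() == "env1"
        # both clades are strongly specialized against the background
        assert max(res.specialization_p.values()) <= 0.005
        # loadings are unit-norm
        assert np.allclose(np.linalg.norm(res.axes.to_numpy(), axis=0), 1.0)

    def test_exports_csvs(self, grid, background, tmp_path):
        cfg = nc.VirtualSpeciesConfig(seed=3)
        c1, c2 = nc.make_two_clades(grid, cfg)
        res = nc.run_omi(grid, [c1, c2], reference_cells=background,
                         variables=("env1", "env2"), n_boot=9, seed=0)
        written = res.to_csvs(tmp_path)
        assert (tmp_path / "omi_loadings.csv").exists()
        assert (tmp_path / "omi_pairwise_tests.csv").exists()
        assert len(written) == 6
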