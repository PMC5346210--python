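import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from likertfa import (LikertDataset, estimate_polychoric_pair,
                      estimate_thresholds, polychoric_matrix, smooth_to_psd)
from likertfa.polychoric import CorrelationMatrix, DegenerateItemError
from likertfa._bvn import bvn_cdf

from oracles import grid_oracle_rho, random_table


def ordinal_pair(rho, n, seed, cuts=(-1.5, -0.5, 0.5, 1.5)):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    a = np.searchsorted(cuts, z[:, 0])
    b = np.searchsorted(cuts, z[:, 1])
    table = np.zeros((len(cuts) + 1, len(cuts) + 1))
    np.add.at(table, (a, b), 1.0)
    return table


class TestBivariateNormalKernel:
    def test_matches_scipy_cdf(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            r = rng.uniform(-0.9999, 0.9999)
            h, k = rng.uniform(-3.5, 3.5, 2)
            ref = multivariate_normal([0, 0], [[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-12)

    def test_infinite_limits(self):
        assert bvn_cdf(np.inf, 0.3, 0.5) == pytest.approx(norm.cdf(0.3))
        assert bvn_cdf(-np.inf, 0.3, 0.5) == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.7) == 1.0


class TestEstimateThresholds:
    def test_median_split(self):
        ts = estimate_thresholds([50, 50])
        np.testing.assert_allclose(ts.tau, [0.0], atol=1e-12)

    def test_inverse_normal_of_cumulative(self):
        ts = estimate_thresholds([8413, 1587])
        assert ts.tau[0] == pytest.approx(1.0, abs=1e-3)

    def test_empty_category_collapsed(self):
        ts = estimate_thresholds([10, 0, 10])
        assert ts.collapsed_categories == [1]
        np.testing.assert_allclose(ts.tau, [0.0], atol=1e-12)

    def test_degenerate_item_raises(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds([0, 20, 0])

    def test_thresholds_strictly_increasing(self):
        ts = estimate_thresholds([10, 20, 30, 25, 15])
        assert np.all(np.diff(ts.tau) > 0)


class TestEstimatePolychoricPair:
    def test_independence_table(self):
        est = estimate_polychoric_pair(
            [[25, 25], [25, 25]], xatol=1e-9)
        assert abs(est.rho) < 1e-6
        assert est.converged

    def test_perfect_concordance_clamped(self):
        est = estimate_polychoric_pair([[50, 0], [0, 50]])
        assert est.rho >= 0.9998

    def test_matches_grid_search_oracle(self):
        table = ordinal_pair(0.4, 500, seed=5, cuts=(-0.5, 0.5))
        est = estimate_polychoric_pair(table)
        assert est.rho == pytest.approx(grid_oracle_rho(table), abs=1e-3)

    def test_transpose_symmetry(self):
        table = ordinal_pair(0.6, 400, seed=9)
        a = estimate_polychoric_pair(table).rho
        b = estimate_polychoric_pair(table.T).rho
        assert a == pytest.approx(b, abs=1e-8)

    def test_reversing_one_item_negates_rho(self):
        table = ordinal_pair(0.6, 400, seed=9)
        a = estimate_polychoric_pair(table, xatol=1e-8).rho
        b = estimate_polychoric_pair(table[::-1, :], xatol=1e-8).rho
        assert b == pytest.approx(-a, abs=1e-5)

    def test_reversing_both_items_preserves_rho(self):
        table = ordinal_pair(-0.4, 400, seed=11)
        a = estimate_polychoric_pair(table, xatol=1e-8).rho
        b = estimate_polychoric_pair(table[::-1, ::-1], xatol=1e-8).rho
        assert b == pytest.approx(a, abs=1e-5)

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateItemError):
            estimate_polychoric_pair([[10, 20], [0, 0]])

    def test_consistency_with_sample_size(self):
        errors = []
        for n in (1_000, 100_000):
            table = ordinal_pair(0.55, n, seed=13)
            errors.append(abs(estimate_polychoric_pair(table).rho - 0.55))
        assert errors[1] < errors[0]


class TestPolychoricMatrix:
    def test_identical_items_near_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 5, size=300)
        ds = LikertDataset(data=np.column_stack([col, col]))
        R = polychoric_matrix(ds)
        assert R.values[0, 1] >= 0.999

    def test_independent_items_near_identity(self):
        rng = np.random.default_rng(7)
        ds = LikertDataset(data=rng.integers(0, 5, size=(5_000, 4)))
        R = polychoric_matrix(ds)
        off = R.values[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.07

    def test_recovers_known_latent_correlation(self):
        rng = np.random.default_rng(21)
        z = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=5_000)
        cuts = np.array([-1.0, 0.0, 1.0])
        data = np.column_stack([np.searchsorted(cuts, z[:, 0]),
                                np.searchsorted(cuts, z[:, 1])])
        R = polychoric_matrix(LikertDataset(data=data, n_categories=4))
        assert R.values[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_degenerate_item_error_names_item(self):
        data = np.column_stack([np.zeros(50, dtype=int),
                                np.arange(50) % 5])
        ds = LikertDataset(data=data, item_labels=["flat", "ok"])
        with pytest.raises(DegenerateItemError, match="flat"):
            polychoric_matrix(ds)


class TestSmoothToPsd:
    def test_identity_untouched(self):
        R = CorrelationMatrix(values=np.eye(4))
        out = smooth_to_psd(R)
        assert not out.smoothed
        np.testing.assert_array_equal(out.values, np.eye(4))

    def test_indefinite_matrix_repaired(self):
        # 3x3 equicorrelation at rho = -0.505 has min eigenvalue -0.01
        values = np.full((3, 3), -0.505)
        np.fill_diagonal(values, 1.0)
        R = CorrelationMatrix(values=values)
        assert np.linalg.eigvalsh(values)[0] == pytest.approx(-0.01, abs=1e-12)
        out = smooth_to_psd(R)
        assert out.smoothed
        assert np.linalg.eigvalsh(out.values)[0] >= 0
        assert np.max(np.abs(out.values - values)) < 0.02
        assert np.all(np.diag(out.values) == 1.0)
        assert out.min_eigenvalue_before == pytest.approx(-0.01, abs=1e-12)
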