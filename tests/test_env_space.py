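"""PCA-env calibration and kernel-density occupancy grids."""

import numpy as np
import pandas as pd
import pytest

from nicheshift import EnvMatrix, density_grid, fit_env_space, project, schoener_d
from nicheshift.env_space import DensityGrid, background_surface


def _env(x: np.ndarray, names=None) -> EnvMatrix:
    names = names or [f"V{i}" for i in range(x.shape[1])]
    return EnvMatrix(pd.DataFrame(x, columns=names),
                     ids=np.array([f"r{i}" for i in range(len(x))]))


def _exact_cov_sample(n: int, cov: np.ndarray, seed=0) -> np.ndarray:
    """Sample whose *empirical* covariance equals ``cov`` to machine precision."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, cov.shape[0]))
    x -= x.mean(0)
    chol_emp = np.linalg.cholesky(np.cov(x.T, ddof=1))
    white = x @ np.linalg.inv(chol_emp).T
    return white @ np.linalg.cholesky(cov).T


class TestFitEnvSpace:
    def test_all_variance_on_one_variable(self):
        x = np.zeros((50, 2))
        x[:, 0] = np.linspace(-1, 1, 50)
        x[:, 1] = 1e-9 * np.linspace(1, -1, 50)  # not constant, but negligible
        space = fit_env_space(_env(x[:25]), _env(x[25:]))
        assert space.explained[0] == pytest.approx(1.0, abs=1e-6)

    def test_explained_shares_sum_to_one(self, small_stack):
        from nicheshift import background_sample
        mask = np.ones(small_stack.shape, bool)
        bg = background_sample(small_stack, mask, max_cells=500, seed=0)
        space = fit_env_space(bg, bg)
        assert space.explained.sum() == pytest.approx(1.0)

    def test_shares_match_analytic_eigenvalues(self):
        # after unit-variance scaling the PCA sees the correlation matrix;
        # for 2 variables with correlation rho the eigenvalues are 1 +- rho
        rho = 0.6
        x = _exact_cov_sample(200, np.array([[2.0, rho * np.sqrt(2.0)],
                                             [rho * np.sqrt(2.0), 1.0]]))
        space = fit_env_space(_env(x[:100]), _env(x[100:]))
        np.testing.assert_allclose(space.explained, [(1 + rho) / 2, (1 - rho) / 2],
                                   atol=1e-9)

    def test_constant_variable_signalled(self):
        x = np.ones((10, 2))
        x[:, 1] = np.arange(10.0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_env_space(_env(x[:5]), _env(x[5:]))

    def test_mismatched_columns_rejected(self):
        a = _env(np.random.default_rng(0).normal(size=(5, 2)), ["A", "B"])
        b = _env(np.random.default_rng(1).normal(size=(5, 2)), ["A", "C"])
        with pytest.raises(ValueError, match="same variable columns"):
            fit_env_space(a, b)


class TestProject:
    def test_fitting_background_is_centered(self):
        x = _exact_cov_sample(100, np.array([[1.0, 0.3], [0.3, 1.0]]))
        a, b = _env(x[:50]), _env(x[50:])
        space = fit_env_space(a, b)
        scores = np.vstack([project(space, a), project(space, b)])
        np.testing.assert_allclose(scores.mean(0), [0.0, 0.0], atol=1e-12)

    def test_center_row_maps_to_origin(self):
        x = _exact_cov_sample(60, np.eye(2) + 0.4 * (1 - np.eye(2)))
        space = fit_env_space(_env(x[:30]), _env(x[30:]))
        center = _env(space.center[None, :])
        np.testing.assert_allclose(project(space, center), [[0.0, 0.0]], atol=1e-12)

    def test_scores_match_hand_arithmetic(self):
        # correlation rho > 0 between two standardized variables gives
        # loadings (1,1)/sqrt(2) and (1,-1)/sqrt(2); scores follow directly
        rho = 0.5
        x = _exact_cov_sample(80, np.array([[1.0, rho], [rho, 1.0]]))
        space = fit_env_space(_env(x[:40]), _env(x[40:]))
        env = _env(np.array([[1.0, 0.5], [-0.3, 0.2]]))
        scores = project(space, env)
        z = (env.data.to_numpy() - space.center) / space.scale
        u = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        expected = z @ u.T
        # PCA axis signs are arbitrary; compare up to per-axis sign
        for k in range(2):
            assert (np.allclose(scores[:, k], expected[:, k], atol=1e-9)
                    or np.allclose(scores[:, k], -expected[:, k], atol=1e-9))

    def test_missing_column_rejected(self):
        x = _exact_cov_sample(40, np.eye(2))
        space = fit_env_space(_env(x[:20]), _env(x[20:]))
        with pytest.raises(KeyError, match="V1"):
            project(space, _env(np.zeros((3, 1)), ["V0"]))


class _FakeSpace:
    def __init__(self, ranges):
        self.axis_ranges = ranges


RANGES = ((-4.0, 4.0), (-4.0, 4.0))


class TestDensityGrid:
    def test_surfaces_are_normalized_densities(self):
        rng = np.random.default_rng(0)
        occ = rng.normal(size=(100, 2))
        bg = rng.normal(scale=1.5, size=(1000, 2))
        g = density_grid(_FakeSpace(RANGES), occ, bg, R=60)
        for z in (g.z_env, g.z_occ, g.z_cor):
            assert z.min() >= 0
            assert z.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g.z_cor[g.z_env == 0] == 0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        occ = rng.normal(size=(80, 2))
        bg = rng.normal(size=(500, 2))
        g1 = density_grid(_FakeSpace(RANGES), occ, bg, R=50)
        perm = rng.permutation(80)
        g2 = density_grid(_FakeSpace(RANGES), occ[perm], bg[::-1], R=50)
        np.testing.assert_allclose(g1.z_cor, g2.z_cor, atol=1e-15)

    def test_tight_cluster_mode_location(self):
        rng = np.random.default_rng(2)
        occ = np.array([1.5, -2.0]) + 0.05 * rng.standard_normal((50, 2))
        bg = rng.uniform(-4, 4, size=(2000, 2))
        g = density_grid(_FakeSpace(RANGES), occ, bg, R=80)
        iy, ix = np.unravel_index(np.argmax(g.z_occ), g.z_occ.shape)
        assert g.x_centers[ix] == pytest.approx(1.5, abs=0.2)
        assert g.y_centers[iy] == pytest.approx(-2.0, abs=0.2)

    def test_occurrences_equal_background_gives_uniform_occupancy(self):
        # same scores for both surfaces -> identical KDEs -> flat ratio
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5000, 2))
        g = density_grid(_FakeSpace(RANGES), pts, pts, R=60)
        support = g.z_cor > 0
        u = 1.0 / support.sum()
        assert np.abs(g.z_cor[support] - u).max() < 0.1 * u

    def test_identical_occurrence_sets_give_exact_unit_overlap(self):
        rng = np.random.default_rng(4)
        occ = rng.normal(size=(60, 2))
        bg = rng.normal(size=(400, 2))
        z_env = background_surface(_FakeSpace(RANGES), bg, R=50)
        g1 = density_grid(_FakeSpace(RANGES), occ, R=50, bg_surface=z_env)
        g2 = density_grid(_FakeSpace(RANGES), occ.copy(), R=50, bg_surface=z_env)
        assert schoener_d(g1, g2) == 1.0

    def test_resolution_stability_of_downstream_overlap(self):
        rng = np.random.default_rng(5)
        occ_a = rng.normal(loc=(-0.5, 0.0), size=(400, 2))
        occ_b = rng.normal(loc=(0.5, 0.0), size=(400, 2))
        bg = rng.normal(scale=1.5, size=(3000, 2))
        ds = {}
        for R in (50, 100):
            ga = density_grid(_FakeSpace(RANGES), occ_a, bg, R=R)
            gb = density_grid(_FakeSpace(RANGES), occ_b, bg, R=R)
            ds[R] = schoener_d(ga, gb)
        assert abs(ds[50] - ds[100]) < 0.05

    def test_degenerate_scores_signalled(self):
        occ = np.ones((10, 2))
        bg = np.random.default_rng(0).normal(size=(100, 2))
        with pytest.raises(ValueError, match="degenerate"):
            density_grid(_FakeSpace(RANGES), occ, bg, R=40)

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="at least 5"):
            density_grid(_FakeSpace(RANGES), rng.normal(size=(3, 2)),
                         rng.normal(size=(100, 2)), R=40)
        with pytest.raises(ValueError, match="at least 20"):
            density_grid(_FakeSpace(RANGES), rng.normal(size=(10, 2)),
                         rng.normal(size=(5, 2)), R=40)


class TestDensityGridContainer:
    def test_invalid_density_rejected(self):
        z = np.full((4, 4), 1 / 16.0)
        bad = z * 2  # sums to 2
        with pytest.raises(ValueError, match="summing to 1"):
            DensityGrid(np.arange(4.0), np.arange(4.0), z, bad, z, z > 0)

    def test_occupancy_outside_background_rejected(self):
        z_env = np.zeros((2, 2))
        z_env[0, 0] = 1.0
        z_cor = np.zeros((2, 2))
        z_cor[1, 1] = 1.0
        with pytest.raises(ValueError, match="background support"):
            DensityGrid(np.arange(2.0), np.arange(2.0), z_env, z_cor, z_cor,
                        z_cor > 0)

    def test_from_occupancy_normalizes(self):
        g = DensityGrid.from_occupancy([[2.0, 1.0, 1.0]])
        np.testing.assert_allclose(g.z_cor, [[0.5, 0.25, 0.25]])
        assert g.z_env.sum() == pytest.approx(1.0)
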