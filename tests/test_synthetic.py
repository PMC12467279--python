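"""Generator contracts: determinism, planted correlations, niche sampling,
and the quadrature overlap oracle."""

import numpy as np
import pytest
from scipy.stats import norm

from nicheshift import (NicheScenario, generate_climate_stack,
                        generate_occurrences, true_overlap)
from nicheshift.synthetic import latent_scores, region_masks


def _scenario(**kw):
    base = dict(grid_shape=(60, 60), n_native=50, n_invasive=50,
                nodata_fraction=0.0, seed=7)
    base.update(kw)
    return NicheScenario(**base)


class TestClimateStack:
    def test_deterministic_given_seed(self):
        s = _scenario(seed=11)
        a = generate_climate_stack(s)
        b = generate_climate_stack(_scenario(seed=11))
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.nodata_mask, b.nodata_mask)

    def test_different_seed_changes_fields(self):
        a = generate_climate_stack(_scenario(seed=1))
        b = generate_climate_stack(_scenario(seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_identical_mixing_rows_are_perfectly_correlated(self):
        s = _scenario(n_layers=2, layer_mixing=[[1.0, 0.5], [1.0, 0.5]],
                      noise_sd=0.0)
        stack = generate_climate_stack(s)
        land = ~stack.nodata_mask
        r = np.corrcoef(stack.data[0][land], stack.data[1][land])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_independent_latents_give_uncorrelated_layers(self):
        # identity mixing, no noise: layer correlation equals realized latent
        # correlation, which orthogonalization pins near zero
        rs = []
        for seed in range(20):
            s = _scenario(grid_shape=(100, 100), n_layers=2,
                          layer_mixing=np.eye(2), noise_sd=0.0, seed=seed)
            stack = generate_climate_stack(s)
            rs.append(np.corrcoef(stack.data[0].ravel(), stack.data[1].ravel())[0, 1])
        assert max(abs(r) for r in rs) < 0.2

    def test_mixing_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layer_mixing"):
            _scenario(n_layers=3, layer_mixing=np.eye(2))

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_shape"):
            _scenario(grid_shape=(5, 60))


class TestOccurrences:
    def test_exact_counts_on_valid_cells(self):
        s = _scenario(n_native=100, n_invasive=40, nodata_fraction=0.1)
        stack = generate_climate_stack(s)
        recs = generate_occurrences(s, stack)
        assert (recs.data["range"] == "native").sum() == 100
        assert (recs.data["range"] == "invasive").sum() == 40
        row, col = stack.transform.index_of(recs.data["lon"].to_numpy(),
                                            recs.data["lat"].to_numpy())
        assert not stack.nodata_mask[row, col].any()

    def test_native_left_invasive_right(self):
        s = _scenario()
        stack = generate_climate_stack(s)
        recs = generate_occurrences(s, stack)
        masks = region_masks(s)
        row, col = stack.transform.index_of(recs.data["lon"].to_numpy(),
                                            recs.data["lat"].to_numpy())
        nat = (recs.data["range"] == "native").to_numpy()
        assert masks["native"][row[nat], col[nat]].all()
        assert masks["invasive"][row[~nat], col[~nat]].all()

    def test_deterministic_given_seed(self):
        s = _scenario(seed=5)
        stack = generate_climate_stack(s)
        a = generate_occurrences(s, stack)
        b = generate_occurrences(_scenario(seed=5), stack)
        assert a.data.equals(b.data)

    def test_degenerate_decade_weights(self):
        s = _scenario(decade_weights=(1.0, 0.0, 0.0))
        stack = generate_climate_stack(s)
        recs = generate_occurrences(s, stack)
        years = recs.data.loc[recs.data["range"] == "invasive", "year"]
        assert years.between(2000, 2009).all()

    def test_without_replacement_count_exceeds_cells(self):
        s = _scenario(grid_shape=(12, 12), n_native=200,
                      sample_with_replacement=False)
        stack = generate_climate_stack(s)
        with pytest.raises(ValueError, match="valid cells"):
            generate_occurrences(s, stack)

    def test_identical_niches_have_matching_sample_means(self):
        # calibration: latent mean difference between ranges stays within
        # sampling error when the two niches coincide
        zs = []
        for seed in range(30):
            s = _scenario(native_centroid=(0.3, -0.2), invasive_centroid=(0.3, -0.2),
                          native_cov=0.25 * np.eye(2), invasive_cov=0.25 * np.eye(2),
                          n_native=60, n_invasive=60, seed=seed)
            stack = generate_climate_stack(s)
            recs = generate_occurrences(s, stack)
            ln = latent_scores(s, recs.by_range("native"))
            li = latent_scores(s, recs.by_range("invasive"))
            se = np.sqrt(ln.var(0, ddof=1) / len(ln) + li.var(0, ddof=1) / len(li))
            zs.append((ln.mean(0) - li.mean(0)) / se)
        zs = np.array(zs)
        # per-seed calibration plus no systematic bias across seeds
        assert np.mean(np.abs(zs) < 3.0) > 0.9
        assert np.all(np.abs(zs.mean(0)) < 3.0 / np.sqrt(len(zs)) * 2)

    def test_niche_recovery_at_large_n(self):
        # centroids close to the background center so availability tilt is
        # small; sample latent means land within 0.2 of the truth
        diffs = []
        for seed in range(5):
            s = _scenario(native_centroid=(-0.5, 0.0), invasive_centroid=(0.5, 0.0),
                          native_cov=0.25 * np.eye(2), invasive_cov=0.25 * np.eye(2),
                          grid_shape=(120, 120), n_native=600, n_invasive=600,
                          seed=seed)
            stack = generate_climate_stack(s)
            recs = generate_occurrences(s, stack)
            ln = latent_scores(s, recs.by_range("native")).mean(0)
            li = latent_scores(s, recs.by_range("invasive")).mean(0)
            diffs.append([np.abs(ln - [-0.5, 0.0]).max(), np.abs(li - [0.5, 0.0]).max()])
        assert np.mean(diffs) < 0.2


class TestTrueOverlap:
    def test_identical_niches_overlap_fully(self):
        s = _scenario()
        s.invasive_centroid = s.native_centroid.copy()
        s.invasive_cov = s.native_cov.copy()
        assert true_overlap(s) == pytest.approx(1.0, abs=1e-6)

    def test_distant_niches_do_not_overlap(self):
        s = _scenario(native_centroid=(-50.0, 0.0), invasive_centroid=(50.0, 0.0),
                      native_cov=np.eye(2), invasive_cov=np.eye(2))
        assert true_overlap(s) < 1e-6

    def test_against_closed_form_and_monte_carlo(self):
        # equal isotropic unit-variance niches a distance d apart have
        # D = 2 * Phi(-d/2); cross-check quadrature with both the closed form
        # and a Monte-Carlo integral of the positive part of (f - g)
        d = 2.0
        s = _scenario(native_centroid=(0.0, 0.0), invasive_centroid=(d, 0.0),
                      native_cov=np.eye(2), invasive_cov=np.eye(2))
        quad = true_overlap(s)
        closed = 2 * norm.cdf(-d / 2)
        assert quad == pytest.approx(closed, abs=1e-4)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1_000_000, 2))  # draws from f
        log_ratio = -0.5 * (((x - [d, 0.0]) ** 2).sum(1) - (x ** 2).sum(1))
        mc = 1.0 - np.mean(np.clip(1.0 - np.exp(log_ratio), 0.0, None))
        assert quad == pytest.approx(mc, abs=1e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        mu_a, mu_b = rng.normal(size=2), rng.normal(size=2)
        a_ = rng.normal(size=(2, 2))
        b_ = rng.normal(size=(2, 2))
        cov_a = a_ @ a_.T + 0.2 * np.eye(2)
        cov_b = b_ @ b_.T + 0.2 * np.eye(2)
        s1 = _scenario(native_centroid=tuple(mu_a), invasive_centroid=tuple(mu_b),
                       native_cov=cov_a, invasive_cov=cov_b)
        s2 = _scenario(native_centroid=tuple(mu_b), invasive_centroid=tuple(mu_a),
                       native_cov=cov_b, invasive_cov=cov_a)
        d1, d2 = true_overlap(s1), true_overlap(s2)
        assert d1 == pytest.approx(d2, abs=1e-6)
        assert 0.0 <= d1 <= 1.0


class TestScenarioValidation:
    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            _scenario(native_cov=[[1.0, 2.0], [2.0, 1.0]])

    def test_decade_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="decade_weights"):
            _scenario(decade_weights=(0.5, 0.2, 0.2))

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError, match="n_native"):
            _scenario(n_native=0)
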