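"""Dataset generators, splitters and sampling."""

import numpy as np
import pytest
from scipy import stats

import neurocca as nc
from neurocca.datasets import UniformSampler


class TestGaussian:
    def test_shapes_and_centering(self, gaussian_ds):
        assert gaussian_ds.X.shape == (10_000, 5)
        assert gaussian_ds.Y.shape == (10_000, 5)
        assert gaussian_ds.centered
        assert np.abs(gaussian_ds.X.mean(0)).max() < 1e-12
        assert np.abs(gaussian_ds.Y.mean(0)).max() < 1e-12

    def test_two_sample_centering_is_antisymmetric(self):
        ds = nc.make_gaussian(1, 1, 2, 100.0, seed=0)
        assert np.allclose(ds.X[0], -ds.X[1])
        assert np.allclose(ds.Y[0], -ds.Y[1])

    def test_sample_covariance_matches_construction(self):
        # regenerate the mixing matrix the generator draws first, so the
        # intended covariance G'G/100 is known exactly
        seed, T = 11, 200_000
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((10, 10))
        C = G.T @ G / 100.0
        ds = nc.make_gaussian(5, 5, T, 100.0, seed=seed)
        Z = np.concatenate([ds.X, ds.Y], axis=1)
        S = Z.T @ Z / T
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / T)
        assert np.all(np.abs(S - C) < 3.0 * se)

    @pytest.mark.parametrize("bad", [dict(n_x=0), dict(T=1), dict(scale_divisor=0)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(n_x=2, n_y=2, T=10, scale_divisor=100.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            nc.make_gaussian(**kwargs)

    def test_bit_reproducible(self):
        a = nc.make_gaussian(3, 4, 50, 100.0, seed=9)
        b = nc.make_gaussian(3, 4, 50, 100.0, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)


class TestPlanted:
    def test_population_correlations_recovered(self, planted_ds):
        sol = nc.solve_cca(planted_ds, d=2)
        assert abs(sol.rho[0] - 0.9) < 0.05
        assert abs(sol.rho[1] - 0.2) < 0.05

    def test_rejects_increasing_rhos(self):
        with pytest.raises(ValueError):
            nc.make_planted_gaussian(rhos=(0.2, 0.9), seed=0)


class TestSvdMax:
    def test_shapes(self, svdmax):
        ds, _ = svdmax
        assert ds.dims == (4, 5, 6)
        assert ds.T == 10_000

    def test_optimal_weights_reproduce_shared_direction(self, svdmax):
        ds, gt = svdmax
        for v, w in zip(ds.views, gt.optimal_weights):
            assert np.abs(v @ w - gt.shared_direction).max() < 1e-8

    def test_groundtruth_projections_maximally_correlated(self, svdmax):
        ds, gt = svdmax
        proj = [v @ w for v, w in zip(ds.views, gt.optimal_weights)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.corrcoef(proj[i], proj[j])[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_factors_are_valid(self, svdmax):
        _, gt = svdmax
        for U, s in zip(gt.U, gt.S):
            assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)
            assert np.all(np.diff(s) <= 0)
            assert np.all((s >= 0.1) & (s <= 1.0))

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_property_holds_for_any_seed(self, seed):
        ds, gt = nc.make_svdmax(dims=(3, 4), T=50, seed=seed)
        proj = [v @ w for v, w in zip(ds.views, gt.optimal_weights)]
        assert np.corrcoef(proj[0], proj[1])[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="orthonormal"):
            nc.make_svdmax(dims=(4, 5, 6), T=10, seed=0)


class TestCorrelatedImages:
    def test_tiny_length_scale_decorrelates_pixels(self):
        images = nc.make_correlated_images(4000, 4, 4, length_scale=0.01, seed=2)
        flat = images.reshape(4000, -1)
        corr = np.corrcoef(flat.T)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 0.08  # sampling noise only

    def test_empirical_correlation_matches_kernel(self):
        T, ls = 20_000, 3.0
        images = nc.make_correlated_images(T, 5, 5, length_scale=ls, seed=4)
        flat = images.reshape(T, -1)
        corr = np.corrcoef(flat.T)
        r, c = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        pos = np.stack([r.ravel(), c.ravel()], 1).astype(float)
        d2 = ((pos[:, None] - pos[None]) ** 2).sum(-1)
        expected = np.exp(-d2 / (2 * ls**2))
        se = (1 - expected**2) / np.sqrt(T)  # Fisher-style correlation SE
        assert np.all(np.abs(corr - expected) <= 3 * se + 1e-12)

    def test_adjacent_more_correlated_than_distant(self):
        images = nc.make_correlated_images(5000, 1, 7, length_scale=3.0, seed=0)
        flat = images[:, 0, :]
        corr = np.corrcoef(flat.T)
        assert corr[0, 1] > corr[0, 5]


class TestSplitters:
    def test_row_split_shapes(self):
        images = nc.make_correlated_images(100, 28, 28, 3.0, seed=1)
        ds = nc.split_image_rows(images, 14, (9, 14), (14, 19))
        assert ds.X.shape == (100, 5) and ds.Y.shape == (100, 5)
        assert ds.centered

    def test_constant_images_center_to_zero(self):
        images = np.full((10, 6, 6), 7.0)
        ds = nc.split_image_rows(images, 2, (0, 3), (3, 6))
        assert np.abs(ds.X).max() == 0 and np.abs(ds.Y).max() == 0

    def test_adjacent_columns_more_correlated(self):
        images = nc.make_correlated_images(5000, 8, 10, length_scale=3.0, seed=6)
        ds = nc.split_image_rows(images, 4, (0, 5), (5, 10))
        near = np.corrcoef(ds.X[:, 4], ds.Y[:, 0])[0, 1]
        far = np.corrcoef(ds.X[:, 0], ds.Y[:, 4])[0, 1]
        assert near > far

    def test_row_split_bounds(self):
        images = np.zeros((5, 4, 4))
        with pytest.raises(IndexError):
            nc.split_image_rows(images, 4, (0, 2), (2, 4))
        with pytest.raises(IndexError):
            nc.split_image_rows(images, 0, (0, 2), (2, 5))

    def test_quadrant_shapes_and_partition(self):
        images = nc.make_correlated_images(50, 6, 8, 2.0, seed=3)
        mv = nc.split_image_quadrants(images)
        assert mv.k == 4
        assert mv.dims == (12, 12, 12, 12)
        # adding back the removed column means must reassemble the images
        means = [q.reshape(50, -1).mean(0) for q in (
            images[:, :3, :4], images[:, :3, 4:], images[:, 3:, :4], images[:, 3:, 4:])]
        top = np.concatenate(
            [(mv.views[0] + means[0]).reshape(50, 3, 4),
             (mv.views[1] + means[1]).reshape(50, 3, 4)], axis=2)
        bottom = np.concatenate(
            [(mv.views[2] + means[2]).reshape(50, 3, 4),
             (mv.views[3] + means[3]).reshape(50, 3, 4)], axis=2)
        assert np.allclose(np.concatenate([top, bottom], axis=1), images)

    def test_single_pixel_quadrants(self):
        images = np.arange(2 * 2 * 2, dtype=float).reshape(2, 2, 2)
        mv = nc.split_image_quadrants(images)
        assert all(v.shape == (2, 1) for v in mv.views)

    def test_odd_dimensions_raise(self):
        with pytest.raises(ValueError, match="even"):
            nc.split_image_quadrants(np.zeros((3, 5, 4)))


class TestCenteringAndSampling:
    def test_center_idempotent(self, rng):
        ds = nc.PairedDataset(rng.normal(2, 1, (30, 3)), rng.normal(-1, 2, (30, 2)))
        once = ds.center()
        twice = once.center()
        assert np.allclose(once.X, twice.X) and np.allclose(once.Y, twice.Y)

    def test_center_preserves_covariances(self, rng):
        X = rng.normal(3, 1, (200, 4))
        ds = nc.PairedDataset(X, rng.normal(0, 1, (200, 2)))
        assert np.allclose(np.cov(ds.center().X.T), np.cov(X.T))

    def test_sampler_reproducible(self, gaussian_ds):
        s1 = UniformSampler(gaussian_ds, seed=4).indices(1000)
        s2 = UniformSampler(gaussian_ds, seed=4).indices(1000)
        assert np.array_equal(s1, s2)
        x, y = nc.sample_minibatch(gaussian_ds, seed=4, t=17)
        assert np.array_equal(x, gaussian_ds.X[s1[17]])
        assert np.array_equal(y, gaussian_ds.Y[s1[17]])

    def test_sampling_is_uniform(self):
        ds = nc.PairedDataset(np.zeros((50, 1)), np.zeros((50, 1)))
        idx = UniformSampler(ds, seed=8).indices(1_000_000)
        counts = np.bincount(idx, minlength=50)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_epoch_order_covers_all_samples(self, gaussian_ds):
        idx = UniformSampler(gaussian_ds, seed=0, order="epoch").indices(gaussian_ds.T)
        assert np.array_equal(np.sort(idx), np.arange(gaussian_ds.T))


class TestIO:
    def test_paired_roundtrip(self, tmp_path, rng):
        ds = nc.PairedDataset(rng.normal(size=(20, 3)), rng.normal(size=(20, 2))).center()
        nc.save_dataset(ds, tmp_path / "d")
        back = nc.load_dataset(tmp_path / "d")
        assert back.centered
        assert np.allclose(back.X, ds.X) and np.allclose(back.Y, ds.Y)

    def test_multiview_roundtrip(self, tmp_path, svdmax):
        ds, _ = svdmax
        small = nc.MultiviewDataset([v[:30] for v in ds.views])
        nc.save_dataset(small, tmp_path / "mv")
        back = nc.load_dataset(tmp_path / "mv")
        assert back.k == 3
        for a, b in zip(back.views, small.views):
            assert np.allclose(a, b)
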