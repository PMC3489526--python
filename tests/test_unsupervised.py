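"""PCA and the four segmentation variants: recovery, guards, memory."""

import tracemalloc

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from msipipe import synthgen
from msipipe.peaks import dataset_peaks
from msipipe.unsupervised import (
    denoise_then_cluster,
    hierarchical_segment,
    kmeans_segment,
    pca_components,
    peak_features,
    spatially_aware_segment,
)


def _features(cube):
    return peak_features(cube, dataset_peaks(cube))


class TestPCA:
    def test_collinear_data_first_component_explains_everything(self):
        rng = np.random.default_rng(0)
        t = rng.random(50)
        X = np.outer(t, [1.0, 2.0, -0.5]) + np.array([3.0, 1.0, 2.0])
        res = pca_components(X, n_components=3)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_noise_components_comparable(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 4))
        res = pca_components(X, n_components=4)
        ev = res.explained_variance_fraction
        # sampled-covariance eigenvalue spread oracle: all near 1/4
        assert ev.max() / ev.min() < 1.3

    def test_reconstruction_error_nonincreasing_and_exact_at_full_rank(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 6))
        errors = []
        for ncomp in range(1, 7):
            res = pca_components(X, n_components=ncomp)
            recon = res.scores @ res.loadings.T + res.mean
            errors.append(np.linalg.norm(recon - X))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-8

    def test_loading_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 5))
        a = pca_components(X, 3)
        b = pca_components(X[:], 3)
        np.testing.assert_allclose(a.loadings, b.loadings)
        for j in range(3):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_components(np.random.rand(5, 3), 4)

    def test_highest_loading_lookup_warns_about_colocalization(self):
        res = pca_components(np.random.default_rng(4).random((20, 5)), 2)
        with pytest.warns(UserWarning, match="co-localize"):
            res.highest_loading_channels(0)


class TestKmeans:
    def test_noise_free_two_regions_recovered_exactly(self, clean_two_region):
        cube, truth = clean_two_region
        seg = kmeans_segment(_features(cube), cube, 2, seed=0)
        assert adjusted_rand_score(truth.region_labels, seg.labels) == 1.0

    def test_k_one_rejected(self, clean_two_region):
        cube, _ = clean_two_region
        with pytest.raises(ValueError):
            kmeans_segment(_features(cube), cube, 1)

    def test_same_seed_identical_labels(self, noisy_two_region):
        cube, _ = noisy_two_region
        F = _features(cube)
        a = kmeans_segment(F, cube, 2, seed=3)
        b = kmeans_segment(F, cube, 2, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_pixel_order_equivariance_as_partition(self, clean_two_region):
        cube, _ = clean_two_region
        F = _features(cube)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cube.n_pixels)
        permuted = cube.copy_with(intensities=cube.intensities[perm])
        permuted.coords = cube.coords[perm]
        a = kmeans_segment(F, cube, 2, seed=0)
        b = kmeans_segment(F[perm], permuted, 2, seed=0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_all_measured_pixels_labeled(self, noisy_two_region):
        cube, _ = noisy_two_region
        seg = kmeans_segment(_features(cube), cube, 3, seed=0)
        assert seg.labels.shape == (cube.n_pixels,)
        assert set(np.unique(seg.labels)) <= set(range(1, 4))


class TestHierarchical:
    def test_separated_blobs_recovered(self, clean_two_region):
        cube, truth = clean_two_region
        seg = hierarchical_segment(_features(cube), cube, 2)
        assert adjusted_rand_score(truth.region_labels, seg.labels) == 1.0

    def test_variance_endpoint_keeps_all_nonzero_components(self, clean_two_region):
        cube, truth = clean_two_region
        seg = hierarchical_segment(_features(cube), cube, 2, pca_variance=1.0)
        assert adjusted_rand_score(truth.region_labels, seg.labels) == 1.0

    def test_memory_guard_refusal_names_quadratic_cost(self, noisy_two_region):
        cube, _ = noisy_two_region
        F = _features(cube)
        with pytest.raises(MemoryError, match="n x n"):
            hierarchical_segment(F, cube, 2, memory_guard=100)


class TestDenoiseThenCluster:
    def test_zero_strength_equals_plain_kmeans(self, noisy_two_region):
        cube, _ = noisy_two_region
        F = _features(cube)
        a = denoise_then_cluster(F, cube, 2, denoise_strength=0, seed=0)
        b = kmeans_segment(F, cube, 2, seed=0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_noise_free_matches_plain_kmeans_partition(self, clean_two_region):
        cube, truth = clean_two_region
        F = _features(cube)
        a = denoise_then_cluster(F, cube, 2, seed=0)
        assert adjusted_rand_score(truth.region_labels, a.labels) == 1.0

    def test_beats_plain_kmeans_under_multiplicative_noise(self):
        wins = 0
        for seed in range(10):
            spec = synthgen.two_region_spec(30, 30, noise_cv=0.3, seed=seed)
            cube, truth = synthgen.generate_datacube(spec)
            F = _features(cube)
            plain = adjusted_rand_score(
                truth.region_labels, kmeans_segment(F, cube, 2, seed=seed).labels)
            den = adjusted_rand_score(
                truth.region_labels,
                denoise_then_cluster(F, cube, 2, seed=seed).labels)
            wins += den > plain
        assert wins >= 8


class TestSpatiallyAware:
    def test_radius_zero_equals_plain_kmeans(self, noisy_two_region):
        cube, _ = noisy_two_region
        F = _features(cube)
        a = spatially_aware_segment(F, cube, 2, radius=0, seed=0)
        b = kmeans_segment(F, cube, 2, seed=0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_fewer_isolated_singletons_than_plain(self):
        def singletons(seg):
            grid = seg.label_grid()
            count = 0
            h, w = grid.shape
            for r in range(h):
                for c in range(w):
                    if grid[r, c] == 0:
                        continue
                    neigh = [grid[rr, cc]
                             for rr in range(max(r - 1, 0), min(r + 2, h))
                             for cc in range(max(c - 1, 0), min(c + 2, w))
                             if (rr, cc) != (r, c) and grid[rr, cc] != 0]
                    if neigh and all(n != grid[r, c] for n in neigh):
                        count += 1
            return count

        total_plain = total_spatial = 0
        for seed in (0, 1, 2):
            spec = synthgen.two_region_spec(30, 30, noise_cv=0.3, seed=seed)
            cube, _ = synthgen.generate_datacube(spec)
            F = _features(cube)
            total_plain += singletons(kmeans_segment(F, cube, 2, seed=seed))
            total_spatial += singletons(
                spatially_aware_segment(F, cube, 2, radius=2, seed=seed))
        assert total_spatial < total_plain

    def test_adaptive_preserves_thin_structure_better_than_large_nonadaptive(self):
        adaptive_better = 0
        for seed in range(5):
            spec = synthgen.thin_structure_spec(seed=seed)
            cube, truth = synthgen.generate_datacube(spec)
            F = _features(cube)
            a = adjusted_rand_score(
                truth.region_labels,
                spatially_aware_segment(F, cube, 2, radius=2, adaptive=True,
                                        seed=seed).labels)
            n = adjusted_rand_score(
                truth.region_labels,
                spatially_aware_segment(F, cube, 2, radius=6, adaptive=False,
                                        seed=seed).labels)
            adaptive_better += a > n
        assert adaptive_better >= 4

    def test_beats_plain_kmeans_under_multiplicative_noise(self):
        wins = 0
        for seed in range(10):
            spec = synthgen.two_region_spec(30, 30, noise_cv=0.3, seed=seed)
            cube, truth = synthgen.generate_datacube(spec)
            F = _features(cube)
            plain = adjusted_rand_score(
                truth.region_labels, kmeans_segment(F, cube, 2, seed=seed).labels)
            spatial = adjusted_rand_score(
                truth.region_labels,
                spatially_aware_segment(F, cube, 2, radius=2, seed=seed).labels)
            wins += spatial > plain
        assert wins >= 8


class TestMemoryContract:
    def test_segmenters_never_materialize_pixel_pair_matrix(self):
        spec = synthgen.two_region_spec(50, 50, noise_cv=0.2, seed=0)
        cube, _ = synthgen.generate_datacube(spec)
        F = _features(cube)
        n = cube.n_pixels
        quadratic = n * n * 8          # bytes an n x n float matrix would need
        for fn in (lambda: kmeans_segment(F, cube, 2, seed=0),
                   lambda: spatially_aware_segment(F, cube, 2, radius=2, seed=0)):
            tracemalloc.start()
            fn()
            _, peak = tracemalloc.get_traced_memory()
            tracemalloc.stop()
            assert peak < quadratic / 4
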