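"""Unsupervised mining: PCA score images and spatial segmentation.

Segmentation groups pixels by spectral similarity and renders the cluster
assignment as one pseudo-colored map.  Four variants are provided:

* plain k-means on the peak-intensity features;
* hierarchical (Ward) clustering after PCA reduction — note the n x n
  distance matrix, guarded by an explicit memory limit;
* k-means after edge-preserving denoising of every peak image;
* spatially-aware k-means, where each pixel's features are augmented with
  a Gaussian-weighted neighborhood average (optionally adaptive, i.e.
  down-weighting spectrally dissimilar neighbors to preserve edges).

The last two suppress the strong pixel-to-pixel variability of
MALDI-imaging and give markedly smoother maps on noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

from .containers import Datacube, MzImage
from .peaks import ConsensusPeakList
from . import viz

__all__ = [
    "ComponentResult",
    "SegmentationMap",
    "peak_features",
    "pca_components",
    "kmeans_segment",
    "hierarchical_segment",
    "denoise_then_cluster",
    "spatially_aware_segment",
]

#: categorical palette for cluster pseudo-coloring (RGB, 0-1)
PALETTE = (
    (0.894, 0.102, 0.110), (0.216, 0.494, 0.722), (0.302, 0.686, 0.290),
    (0.596, 0.306, 0.639), (1.000, 0.498, 0.000), (1.000, 1.000, 0.200),
    (0.651, 0.337, 0.157), (0.969, 0.506, 0.749), (0.600, 0.600, 0.600),
)

HIERARCHICAL_MEMORY_GUARD = 20000   # max pixels for the n x n distance matrix


@dataclass
class ComponentResult:
    """PCA decomposition: per-pixel scores, per-channel loadings."""

    scores: np.ndarray                       # n_pixels x n_components
    loadings: np.ndarray                     # n_channels x n_components
    explained_variance_fraction: np.ndarray
    mean: np.ndarray                         # channel means removed before PCA

    def highest_loading_channels(self, component: int, top_n: int = 1) -> np.ndarray:
        """Channel indices of the largest loadings of one component.

        Caution: picking m/z-images by highest loading sometimes fails to
        return images co-localized with the score image — inspect both.
        """
        warnings.warn(
            "highest-loading m/z-images are not guaranteed to co-localize "
            "with the score image; inspect them visually",
            UserWarning,
        )
        order = np.argsort(np.abs(self.loadings[:, component]))[::-1]
        return order[:top_n]


@dataclass
class SegmentationMap:
    """Per-pixel cluster labels (1..k) over a cube's measured pixels."""

    labels: np.ndarray            # per measured pixel, values in 1..k
    k: int
    coords: np.ndarray            # (n, 2) pixel coords matching labels
    grid_shape: tuple[int, int]
    palette: tuple = field(default=PALETTE)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        if used.min() < 1 or used.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if used.size < self.k:
            warnings.warn(f"only {used.size} of {self.k} clusters are non-empty",
                          UserWarning)

    def label_grid(self) -> np.ndarray:
        """Labels on the bounding-box grid; 0 marks unmeasured pixels."""
        x0 = self.coords[:, 0].min()
        y0 = self.coords[:, 1].min()
        grid = np.zeros(self.grid_shape, dtype=int)
        grid[self.coords[:, 1] - y0, self.coords[:, 0] - x0] = self.labels
        return grid

    def cluster_sizes(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in range(1, self.k + 1)}


# ---- features -----------------------------------------------------------

def peak_features(cube: Datacube, consensus: ConsensusPeakList,
                  tol: float = 0.5) -> np.ndarray:
    """Pixel x peak intensity matrix: each consensus peak's m/z window summed."""
    cols = []
    for mz in consensus.mzs:
        window = cube.axis.index_window(mz, tol)
        cols.append(cube.intensities[:, window].sum(axis=1))
    return np.column_stack(cols) if cols else np.empty((cube.n_pixels, 0))


# ---- PCA ----------------------------------------------------------------

def pca_components(features: np.ndarray, n_components: int) -> ComponentResult:
    """Centered PCA with a deterministic sign convention.

    Each loading column is flipped so its largest-magnitude entry is
    positive, making score images reproducible across runs and platforms.
    """
    features = np.asarray(features, dtype=float)
    n, d = features.shape
    if n_components > min(n, d):
        raise ValueError("n_components exceeds min(n_pixels, n_features)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features)
    loadings = pca.components_.T
    for j in range(loadings.shape[1]):
        flip = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if flip < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return ComponentResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


# ---- segmentation -------------------------------------------------------

def _as_map(labels0: np.ndarray, k: int, cube: Datacube) -> SegmentationMap:
    return SegmentationMap(labels=labels0 + 1, k=k, coords=cube.coords,
                           grid_shape=cube.grid_shape)


def kmeans_segment(features: np.ndarray, cube: Datacube, k: int,
                   seed: int = 0, n_restarts: int = 10) -> SegmentationMap:
    """Plain k-means (k-means++ init, best of ``n_restarts`` by inertia)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > features.shape[0]:
        raise ValueError("k exceeds the number of pixels")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels0 = km.fit_predict(np.asarray(features, dtype=float))
    return _as_map(labels0, k, cube)


def hierarchical_segment(features: np.ndarray, cube: Datacube, k: int,
                         linkage: str = "ward", pca_variance: float = 0.70,
                         memory_guard: int = HIERARCHICAL_MEMORY_GUARD
                         ) -> SegmentationMap:
    """Agglomerative clustering after PCA reduction.

    Features are first reduced to the smallest number of principal
    components reaching ``pca_variance`` explained variance, then
    agglomerated (Euclidean distance, Ward linkage by default) and cut at
    ``k`` clusters.  Because agglomeration materializes an n x n distance
    matrix, cubes larger than ``memory_guard`` pixels are refused.
    """
    n = features.shape[0]
    if n > memory_guard:
        raise MemoryError(
            f"hierarchical clustering needs an n x n = {n}x{n} distance "
            f"matrix; above the guard of {memory_guard} pixels use "
            "kmeans/spatial segmentation instead"
        )
    if k < 2:
        raise ValueError("k must be >= 2")
    features = np.asarray(features, dtype=float)
    max_comp = min(n, features.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(features)
    ratios = pca.explained_variance_ratio_
    nonzero = ratios > 1e-12
    if pca_variance >= 1.0:
        ncomp = int(nonzero.sum()) or 1
    else:
        ncomp = int(np.searchsorted(np.cumsum(ratios), pca_variance) + 1)
        ncomp = min(max(ncomp, 1), max_comp)
    agg = AgglomerativeClustering(n_clusters=k, linkage=linkage)
    labels0 = agg.fit_predict(scores[:, :ncomp])
    return _as_map(labels0, k, cube)


def _feature_images(features: np.ndarray, cube: Datacube) -> list[MzImage]:
    mask = cube.measured_mask()
    return [MzImage(grid=cube.to_grid(features[:, j]), mask=mask, mz=float(j))
            for j in range(features.shape[1])]


def denoise_then_cluster(features: np.ndarray, cube: Datacube, k: int,
                         denoise_strength: float = 1.0, seed: int = 0
                         ) -> SegmentationMap:
    """Edge-preserving denoising of every feature image, then k-means.

    ``denoise_strength`` scales the bilateral range sigma in units of each
    image's intensity spread; 0 disables denoising entirely and reduces to
    plain k-means.
    """
    if denoise_strength == 0:
        return kmeans_segment(features, cube, k, seed=seed)
    denoised = np.empty_like(np.asarray(features, dtype=float))
    for j, img in enumerate(_feature_images(features, cube)):
        spread = np.std(img.measured_values)
        if spread == 0:
            denoised[:, j] = features[:, j]
            continue
        out = viz.denoise_image(img, spatial_sigma=1.5,
                                range_sigma=denoise_strength * spread)
        denoised[:, j] = cube.from_grid(out.grid)
    return kmeans_segment(denoised, cube, k, seed=seed)


def _neighbor_average(features: np.ndarray, cube: Datacube, radius: float,
                      adaptive: bool) -> np.ndarray:
    """Gaussian-weighted neighborhood mean of each pixel's feature vector.

    Weights are ``exp(-d^2 / (2 sigma^2))`` with ``sigma = radius / 2`` over
    pixel distance d <= radius.  In adaptive mode each neighbor is further
    down-weighted by ``exp(-||f_i - f_j||^2 / h^2)`` with ``h`` the median
    neighbor spectral distance, so averages do not leak across tissue
    edges.  Implemented with shifted-grid accumulation: O(n * radius^2)
    time, O(n) memory, no pairwise pixel matrix.
    """
    n, d = features.shape
    grid_feat = np.stack([cube.to_grid(features[:, j], fill=0.0) for j in range(d)],
                         axis=-1)
    mask = cube.measured_mask().astype(float)
    sigma = radius / 2.0
    r_int = int(np.floor(radius))

    offsets = [(dy, dx) for dy in range(-r_int, r_int + 1)
               for dx in range(-r_int, r_int + 1)
               if 0 < dy * dy + dx * dx <= radius * radius]

    h2 = None
    if adaptive:
        # median squared spectral distance to immediate neighbors
        sq = []
        for dy, dx in ((0, 1), (1, 0)):
            a = grid_feat[max(dy, 0):grid_feat.shape[0] - max(-dy, 0),
                          max(dx, 0):grid_feat.shape[1] - max(-dx, 0)]
            b = grid_feat[max(-dy, 0):grid_feat.shape[0] - max(dy, 0),
                          max(-dx, 0):grid_feat.shape[1] - max(dx, 0)]
            ma = mask[max(dy, 0):mask.shape[0] - max(-dy, 0),
                      max(dx, 0):mask.shape[1] - max(-dx, 0)]
            mb = mask[max(-dy, 0):mask.shape[0] - max(dy, 0),
                      max(-dx, 0):mask.shape[1] - max(dx, 0)]
            both = (ma * mb) > 0
            diff = ((a - b) ** 2).sum(axis=-1)[both]
            sq.append(diff)
        all_sq = np.concatenate(sq) if sq else np.empty(0)
        med = float(np.median(all_sq)) if all_sq.size else 1.0
        h2 = med if med > 0 else 1.0

    acc = np.zeros_like(grid_feat)
    wsum = np.zeros(mask.shape)
    for dy, dx in offsets:
        w_spatial = np.exp(-(dy * dy + dx * dx) / (2.0 * sigma * sigma))
        shifted = np.zeros_like(grid_feat)
        shifted_mask = np.zeros_like(mask)
        src_r = slice(max(-dy, 0), grid_feat.shape[0] - max(dy, 0))
        dst_r = slice(max(dy, 0), grid_feat.shape[0] - max(-dy, 0))
        src_c = slice(max(-dx, 0), grid_feat.shape[1] - max(dx, 0))
        dst_c = slice(max(dx, 0), grid_feat.shape[1] - max(-dx, 0))
        shifted[dst_r, dst_c] = grid_feat[src_r, src_c]
        shifted_mask[dst_r, dst_c] = mask[src_r, src_c]
        w = w_spatial * shifted_mask
        if adaptive:
            spectral = ((shifted - grid_feat) ** 2).sum(axis=-1)
            w = w * np.exp(-spectral / h2)
        acc += shifted * w[..., None]
        wsum += w
    wsum = np.maximum(wsum, 1e-30)
    averaged = acc / wsum[..., None]
    # pixels with no in-radius neighbor fall back to their own features
    lonely = wsum < 1e-20
    averaged[lonely] = grid_feat[lonely]
    return np.column_stack([cube.from_grid(averaged[..., j]) for j in range(d)])


def spatially_aware_segment(features: np.ndarray, cube: Datacube, k: int,
                            radius: float = 2.0, adaptive: bool = True,
                            seed: int = 0) -> SegmentationMap:
    """Spatially-aware k-means: features augmented with neighborhood context.

    Each pixel's feature vector is concatenated with the Gaussian-weighted
    average of its neighbors within ``radius`` (see
    :func:`_neighbor_average`); the clustering then sees both the pixel's
    own spectrum and its local context, which suppresses pixel-to-pixel
    noise.  Non-adaptive mode with a large radius blurs thin structures;
    adaptive mode preserves them.  ``radius = 0`` is exactly plain k-means.
    All neighborhood sums are computed on the fly; memory stays O(n).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    features = np.asarray(features, dtype=float)
    if radius == 0:
        return kmeans_segment(features, cube, k, seed=seed)
    context = _neighbor_average(features, cube, radius, adaptive)
    augmented = np.hstack([features, context])
    return kmeans_segment(augmented, cube, k, seed=seed)
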