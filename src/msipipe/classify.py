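"""Supervised two-group classification of spectra for biomarker discovery.

Two groups of pixels (e.g. tumor vs control ROIs) are compared with a
regularized linear margin classifier on consensus-peak intensities;
linear weights make the discriminative m/z-values directly readable.
Moderate group imbalance (up to ten-fold) is handled by decimation:
keeping every k-th spectrum of the larger group, k chosen to balance the
sizes.  Stronger imbalance is refused — it needs sampling or
cost-sensitive learning, which is out of scope here.

Accuracy interpretation: for balanced groups, accuracy near 50% means the
classifier learned nothing and the discriminative m/z-values are
meaningless; values above 80% are good.  100% should not be expected from
MALDI-imaging spectra (annotation noise, tissue mixing, ion diffusion).
The discriminative m/z-values must always be rendered as m/z-images and
examined visually before any identification effort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .containers import Datacube
from . import io as msio
from . import viz

__all__ = [
    "ClassificationResult",
    "extract_groups",
    "decimate_balance",
    "crossval_classify",
    "discriminative_mzs",
    "ImbalanceError",
]

MIN_GROUP_SIZE = 3
MAX_IMBALANCE = 10.0

GOOD_ACCURACY = 0.80
CHANCE_BAND = (0.45, 0.55)


class ImbalanceError(ValueError):
    """Group-size ratio beyond what decimation can responsibly fix."""


@dataclass
class ClassificationResult:
    accuracy: float
    per_class_accuracy: tuple[float, float]
    group_sizes_before: tuple[int, int]
    group_sizes_after: tuple[int, int]
    decimation_step: int
    weights: np.ndarray                    # per-feature linear weights
    feature_mzs: np.ndarray
    folds: int
    seed: int
    discriminative: list[tuple[float, float]] = field(default_factory=list)

    def interpretation(self) -> str:
        """Plain-language reading of the accuracy value."""
        if self.accuracy >= GOOD_ACCURACY:
            band = "good: the groups are clearly discriminable"
        elif CHANCE_BAND[0] <= self.accuracy <= CHANCE_BAND[1]:
            band = ("problematic: chance level for balanced groups — treat "
                    "the discriminative m/z-values with caution")
        else:
            band = "intermediate: inspect discriminative m/z-images carefully"
        return f"cross-validated accuracy {self.accuracy:.1%} ({band})"


def extract_groups(features: np.ndarray, cube: Datacube, roi_labels: np.ndarray,
                   group_a: int, group_b: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Partition pixel features by an ROI label image (or per-pixel vector).

    Pixels carrying neither label are excluded.  Returns the two feature
    blocks and the corresponding pixel indices (row-major pixel order of
    the cube, which decimation relies on).
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.shape == cube.grid_shape:
        per_pixel = cube.from_grid(roi_labels.astype(float)).astype(int)
    elif roi_labels.shape == (cube.n_pixels,):
        per_pixel = roi_labels.astype(int)
    else:
        raise ValueError("roi_labels must match the cube grid or pixel vector")
    idx_a = np.flatnonzero(per_pixel == group_a)
    idx_b = np.flatnonzero(per_pixel == group_b)
    for name, idx in (("first", idx_a), ("second", idx_b)):
        if idx.size < MIN_GROUP_SIZE:
            raise ValueError(f"{name} ROI has {idx.size} pixels; "
                             f"need >= {MIN_GROUP_SIZE}")
    return features[idx_a], features[idx_b], idx_a, idx_b


def decimate_balance(larger: np.ndarray, smaller: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Balance two groups by keeping every k-th spectrum of the larger one.

    ``k = round(n_larger / n_smaller)``; spectra are taken in their stored
    (row-major pixel) order, so the subsample is deterministic and
    spatially spread.  Imbalance beyond ten-fold raises
    :class:`ImbalanceError` — use sampling or cost-sensitive methods then.
    """
    n_l, n_s = larger.shape[0], smaller.shape[0]
    if n_l < n_s:
        raise ValueError("first argument must be the larger group")
    ratio = n_l / n_s
    if ratio > MAX_IMBALANCE:
        raise ImbalanceError(
            f"imbalance {ratio:.1f}x exceeds {MAX_IMBALANCE:.0f}x; decimation "
            "would discard too much — use sampling or cost-sensitive learning"
        )
    k = max(1, round(ratio))
    decimated = larger[::k]
    return decimated, smaller, k


def crossval_classify(group_a: np.ndarray, group_b: np.ndarray,
                      feature_mzs: np.ndarray, folds: int = 5, seed: int = 0,
                      balance: bool = True, C: float = 1.0
                      ) -> ClassificationResult:
    """Stratified cross-validation of a linear SVM on peak intensities.

    Groups are decimation-balanced first (unless ``balance=False``), the
    classifier is an L2-regularized linear SVM behind per-feature
    standardization, and accuracy is the mean correct rate over
    ``folds`` stratified folds.  The final weights come from a refit on
    all (balanced) spectra.
    """
    before = (group_a.shape[0], group_b.shape[0])
    k = 1
    if balance:
        if group_a.shape[0] >= group_b.shape[0]:
            group_a, group_b, k = decimate_balance(group_a, group_b)
        else:
            group_b, group_a, k = decimate_balance(group_b, group_a)
    after = (group_a.shape[0], group_b.shape[0])
    if min(after) < folds:
        raise ValueError("each group must have at least `folds` spectra")

    X = np.vstack([group_a, group_b])
    y = np.concatenate([np.zeros(after[0], dtype=int), np.ones(after[1], dtype=int)])
    if np.all(X.std(axis=0) == 0):
        warnings.warn("all features are constant; classification is degenerate",
                      UserWarning)

    model = make_pipeline(StandardScaler(),
                          LinearSVC(C=C, dual=True, max_iter=20000,
                                    random_state=seed))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, X, y, cv=cv)
    accuracy = float((pred == y).mean())
    per_class = (float((pred[y == 0] == 0).mean()), float((pred[y == 1] == 1).mean()))

    model.fit(X, y)
    weights = np.ravel(model.named_steps["linearsvc"].coef_).copy()
    order = np.argsort(np.abs(weights))[::-1]
    discriminative = [(float(feature_mzs[j]), float(weights[j])) for j in order]

    return ClassificationResult(
        accuracy=accuracy,
        per_class_accuracy=per_class,
        group_sizes_before=before,
        group_sizes_after=after,
        decimation_step=k,
        weights=weights,
        feature_mzs=np.asarray(feature_mzs, dtype=float),
        folds=folds,
        seed=seed,
        discriminative=discriminative,
    )


def discriminative_mzs(result: ClassificationResult, top_n: int,
                       cube: Datacube | None = None,
                       output_dir: str | Path | None = None
                       ) -> list[tuple[float, float]]:
    """Top discriminative (m/z, weight) pairs, with mandatory image export.

    When a cube and output directory are given, each returned m/z is also
    rendered as a conditioned m/z-image for the visual sanity check that
    must precede any identification work; the report stage always calls
    it this way.
    """
    if top_n > len(result.discriminative):
        warnings.warn(f"top_n={top_n} exceeds {len(result.discriminative)} "
                      "features; clipping", UserWarning)
        top_n = len(result.discriminative)
    top = result.discriminative[:max(top_n, 0)]
    if cube is not None and output_dir is not None and top:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mz, weight in top:
            img = msio.get_mz_image(cube, mz, tol=0.5)
            img = viz.condition_image(img)
            viz.render(img, outdir / f"discriminative_mz_{mz:.3f}.png",
                       viz.RenderSettings(title=f"m/z {mz:.3f}  w={weight:+.3f}"))
    return top
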