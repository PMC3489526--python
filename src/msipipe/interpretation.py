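"""Interpretation of a segmentation map: colocalized ions and reports.

Once a segmentation map shows a region of interest, the ions specific to
that region are found by correlation: for *every* channel of the cube
(all m/z values, not only picked peaks) the Pearson correlation r between
the channel's image and the binary cluster mask is computed, with a
two-sided p-value from the t transform.  Channels with high positive and
significant correlation (p < 0.05 by default) are the cluster's
colocalized ions.  Because tens of thousands of channels are tested, a
Benjamini-Hochberg adjusted q-value is reported alongside; the default
selection rule remains the raw-p threshold, with ``use_q`` to switch.

A related-ion annotation step flags m/z pairs separated by known mass
differences (isotope +1, oxidation +16, ammonia loss +17, water loss
+18 Da), which raises confidence that a hit list is biologically real.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Datacube, MzImage
from .unsupervised import SegmentationMap
from . import io as msio
from . import viz

__all__ = [
    "ColocalizationRecord",
    "RelatedIonTable",
    "cluster_mask",
    "colocalization",
    "annotate_related_ions",
    "build_report",
]

DEFAULT_ALPHA = 0.05


@dataclass
class ColocalizationRecord:
    """Correlation of one m/z-image with a cluster mask."""

    mz: float
    r: float
    p: float
    q: float
    selected: bool
    q90_intensity: float
    degenerate: bool = False    # constant channel: r undefined, never selected


@dataclass
class RelatedIonTable:
    """Known mass differences between related ions, in Daltons."""

    deltas: dict[float, str] = field(default_factory=lambda: {
        1.0: "isotope",
        16.0: "oxidation",
        17.0: "ammonia loss",
        18.0: "water loss",
    })
    tol: float = 0.2

    def __post_init__(self) -> None:
        if self.tol <= 0 or any(d <= 0 for d in self.deltas):
            raise ValueError("deltas and tol must be positive")


def cluster_mask(segmap: SegmentationMap, cluster_id: int) -> MzImage:
    """Binary spatial mask of one cluster (1 inside, 0 elsewhere).

    Returned as an image over the bounding-box grid with unmeasured pixels
    masked out, ready for correlation against m/z-images.
    """
    if not 1 <= cluster_id <= segmap.k:
        raise KeyError(f"cluster {cluster_id} not in 1..{segmap.k}")
    grid = segmap.label_grid()
    x0 = segmap.coords[:, 0].min()
    y0 = segmap.coords[:, 1].min()
    measured = np.zeros(segmap.grid_shape, dtype=bool)
    measured[segmap.coords[:, 1] - y0, segmap.coords[:, 0] - x0] = True
    mask = np.where(measured, (grid == cluster_id).astype(float), np.nan)
    return MzImage(grid=mask, mask=measured, mz=float(cluster_id), tol=0.0)


def colocalization(cube: Datacube, mask: MzImage | np.ndarray,
                   alpha: float = DEFAULT_ALPHA, use_q: bool = False,
                   intensity_floor: float = 1e-12
                   ) -> list[ColocalizationRecord]:
    """Pearson correlation of every channel image with a binary mask.

    Returns one record per channel, sorted by r descending; ``selected``
    is true when the correlation is positive and significant (raw p <
    ``alpha``, or adjusted q < ``alpha`` with ``use_q``).  Channels that
    are constant over the measured pixels — or numerically silent, i.e.
    whose maximum is below ``intensity_floor`` times the cube maximum —
    have no meaningful correlation; they are flagged ``degenerate`` with
    r = 0, p = 1, never NaN.
    """
    if isinstance(mask, MzImage):
        mask_grid = mask.grid
    else:
        mask_grid = np.asarray(mask, dtype=float)
    m = _mask_vector(cube, mask_grid)
    n = m.size
    ones, zeros = int(m.sum()), int(n - m.sum())
    if ones < 3 or zeros < 3:
        raise ValueError("mask must contain >= 3 ones and >= 3 zeros over measured pixels")

    X = cube.intensities
    mc = m - m.mean()
    sm = np.sqrt((mc ** 2).sum())
    Xc = X - X.mean(axis=0, keepdims=True)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    degenerate = (sx <= 0) | (X.max(axis=0) < intensity_floor * X.max())
    sx_safe = np.where(degenerate, 1.0, sx)
    r = (Xc.T @ mc) / (sx_safe * sm)
    r = np.clip(np.where(degenerate, 0.0, r), -1.0, 1.0)

    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    crit = q if use_q else p
    selected = (crit < alpha) & (r > 0) & ~degenerate
    q90 = np.quantile(X, 0.90, axis=0)

    records = [
        ColocalizationRecord(
            mz=float(cube.axis.values[j]), r=float(r[j]), p=float(p[j]),
            q=float(q[j]), selected=bool(selected[j]),
            q90_intensity=float(q90[j]), degenerate=bool(degenerate[j]),
        )
        for j in range(cube.n_channels)
    ]
    # near-ties in r (e.g. flank channels of one peak) break toward intensity
    records.sort(key=lambda rec: (-round(rec.r, 6), -rec.q90_intensity))
    return records


def _mask_vector(cube: Datacube, mask_grid: np.ndarray) -> np.ndarray:
    if mask_grid.shape == cube.grid_shape:
        vec = cube.from_grid(mask_grid)
    elif mask_grid.shape == (cube.n_pixels,):
        vec = mask_grid.astype(float)
    else:
        raise ValueError("mask must match the cube grid or the pixel vector")
    if np.any(np.isnan(vec)):
        raise ValueError("mask has NaN at measured pixels")
    return (vec > 0.5).astype(float)


def annotate_related_ions(mzs: np.ndarray,
                          table: RelatedIonTable | None = None
                          ) -> list[tuple[float, float, str]]:
    """All pairs of m/z values separated by a known mass difference.

    Input must be sorted ascending; each matching pair is returned as
    ``(mz_low, mz_high, relation)``.
    """
    table = table or RelatedIonTable()
    mzs = np.asarray(mzs, dtype=float)
    if np.any(np.diff(mzs) < 0):
        raise ValueError("mzs must be sorted ascending")
    hits = []
    for i in range(mzs.size):
        for j in range(i + 1, mzs.size):
            gap = mzs[j] - mzs[i]
            if gap > max(table.deltas) + table.tol:
                break
            for delta, relation in table.deltas.items():
                if abs(gap - delta) <= table.tol:
                    hits.append((float(mzs[i]), float(mzs[j]), relation))
    return hits


def build_report(segmap: SegmentationMap, cube: Datacube, output_dir: str | os.PathLike,
                 alpha: float = DEFAULT_ALPHA, top_n: int = 6,
                 use_q: bool = False) -> dict[int, Path]:
    """One overview page + CSV per cluster: mask, mean spectrum, top ions.

    For each cluster the page shows the segmentation overlay, the mean
    spectrum of the cluster's pixels, and the ``top_n`` selected
    m/z-images titled with (m/z, r, q90).  Clusters with no significant
    ion get a page saying so rather than being dropped.  File naming is
    deterministic (``cluster_<id>.png`` / ``.csv``).
    """
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pages: dict[int, Path] = {}
    for cid in range(1, segmap.k + 1):
        mask = cluster_mask(segmap, cid)
        records = colocalization(cube, mask, alpha=alpha, use_q=use_q)
        msio.export_table(records, outdir / f"cluster_{cid}.csv")
        chosen = [rec for rec in records if rec.selected][:top_n]

        in_cluster = segmap.labels == cid
        cluster_mean = cube.intensities[in_cluster].mean(axis=0)

        ncols = max(3, len(chosen))
        fig, axes = plt.subplots(2, ncols, figsize=(3 * ncols, 6))
        axes = np.atleast_2d(axes)
        ax = axes[0, 0]
        ax.imshow(mask.grid, interpolation="nearest", cmap="gray")
        ax.set_title(f"cluster {cid} mask")
        ax.axis("off")
        ax = axes[0, 1]
        ax.plot(cube.axis.values, cluster_mean, lw=0.7)
        ax.set_title("cluster mean spectrum")
        ax.set_xlabel("m/z")
        for extra in range(2, ncols):
            axes[0, extra].axis("off")
        if chosen:
            for slot in range(ncols):
                ax = axes[1, slot]
                if slot < len(chosen):
                    rec = chosen[slot]
                    img = msio.get_mz_image(cube, rec.mz, tol=0.0)
                    img = viz.condition_image(img)
                    ax.imshow(img.grid, interpolation="nearest", cmap="jet")
                    ax.set_title(f"m/z {rec.mz:.3f}  r={rec.r:.3f}  "
                                 f"q90={rec.q90_intensity:.3f}", fontsize=8)
                ax.axis("off")
        else:
            axes[1, 0].text(0.5, 0.5, "no significant ions",
                            ha="center", va="center")
            for slot in range(ncols):
                axes[1, slot].axis("off")
        fig.suptitle(f"Cluster {cid}: {int(in_cluster.sum())} pixels")
        page = outdir / f"cluster_{cid}.png"
        fig.savefig(page, dpi=100)
        plt.close(fig)
        pages[cid] = page
    return pages
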