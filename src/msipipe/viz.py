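"""Conditioning and rendering of m/z-images.

Raw ion images are hard to read: isolated hotspot pixels stretch the
pseudo-color scale, and the multiplicative pixel-to-pixel noise obscures
region boundaries.  The standard conditioning sequence used by the report
stage is hotspot suppression -> histogram equalization -> edge-preserving
(bilateral) denoising, after which the image is rendered with a pseudo-
color map (jet by default, blue = lowest to red = highest intensity).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import exposure

from .containers import MzImage

__all__ = [
    "RenderSettings",
    "suppress_hotspots",
    "hist_equalize",
    "denoise_image",
    "render",
    "condition_image",
]

#: pixels outside the measured region are drawn in this color
BACKGROUND_RGB = (0.85, 0.85, 0.85)


@dataclass
class RenderSettings:
    colormap: str = "jet"       # "viridis" for a perceptually-uniform scale
    dpi: int = 100
    title: str | None = None
    scale: int = 4              # nearest-neighbor upscaling factor


def suppress_hotspots(img: MzImage, quantile: float = 0.95) -> MzImage:
    """Clip intensities above the given quantile of the measured pixels.

    With the default quantile 0.95 exactly the brightest 5% of
    distinct-valued pixels are altered.  Clipping (rather than deleting
    pixels) keeps the grid complete for downstream correlation.  The remap
    is monotone: the rank order of unclipped pixels is preserved.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    values = img.measured_values
    cutoff = float(np.quantile(values, quantile))
    return img.replace_values(np.minimum(values, cutoff))


def hist_equalize(img: MzImage, bins: int = 256) -> MzImage:
    """Histogram equalization over the measured pixels only.

    A monotone remap of intensities whose output empirical CDF is uniform
    on [0, 1] — the contrast-enhancing alternative to hotspot clipping.
    """
    values = img.measured_values
    if values.size < 2:
        raise ValueError("need at least 2 measured pixels")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return img.replace_values(np.zeros_like(values))
    scaled = (values - lo) / (hi - lo)
    equalized = exposure.equalize_hist(scaled, nbins=bins)
    return img.replace_values(equalized)


def denoise_image(img: MzImage, spatial_sigma: float = 1.5,
                  range_sigma: float = 1.0) -> MzImage:
    """Bilateral (edge-preserving) filtering that respects the pixel mask.

    Each pixel is replaced by a weighted mean of its neighbors, weights
    being the product of a spatial Gaussian (``spatial_sigma``, pixels)
    and an intensity-range Gaussian (``range_sigma``, intensity units).
    Neighbors across a step larger than ``range_sigma`` get negligible
    weight, so edges survive while within-region noise is averaged out.
    Unmeasured pixels never contribute to any window.
    """
    if spatial_sigma <= 0 or range_sigma <= 0:
        raise ValueError("sigmas must be positive")
    grid = np.nan_to_num(img.grid, nan=0.0)
    mask = img.mask.astype(float)
    r = max(1, int(np.ceil(2.5 * spatial_sigma)))

    acc = np.zeros_like(grid)
    wsum = np.zeros_like(grid)
    h, w = grid.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            w_spatial = np.exp(-(dy * dy + dx * dx) / (2.0 * spatial_sigma ** 2))
            if w_spatial < 1e-6:
                continue
            shifted = np.zeros_like(grid)
            shifted_mask = np.zeros_like(mask)
            src_r = slice(max(-dy, 0), h - max(dy, 0))
            dst_r = slice(max(dy, 0), h - max(-dy, 0))
            src_c = slice(max(-dx, 0), w - max(dx, 0))
            dst_c = slice(max(dx, 0), w - max(-dx, 0))
            shifted[dst_r, dst_c] = grid[src_r, src_c]
            shifted_mask[dst_r, dst_c] = mask[src_r, src_c]
            w_range = np.exp(-((shifted - grid) ** 2) / (2.0 * range_sigma ** 2))
            weight = w_spatial * w_range * shifted_mask
            acc += shifted * weight
            wsum += weight
    out = np.where(wsum > 0, acc / np.maximum(wsum, 1e-30), grid)
    out[~img.mask] = np.nan
    return MzImage(grid=out, mask=img.mask.copy(), mz=img.mz, tol=img.tol)


def condition_image(img: MzImage, quantile: float = 0.95, bins: int = 256,
                    spatial_sigma: float = 1.5, range_sigma: float = 0.1
                    ) -> MzImage:
    """The report-stage conditioning chain: hotspot -> equalize -> denoise."""
    out = suppress_hotspots(img, quantile)
    out = hist_equalize(out, bins)
    return denoise_image(out, spatial_sigma, range_sigma)


def _to_rgb(img: MzImage, colormap: str) -> np.ndarray:
    values = img.grid.copy()
    measured = img.measured_values
    if measured.size and measured.max() > measured.min():
        values = (values - measured.min()) / (measured.max() - measured.min())
    else:
        values = np.zeros_like(values)
    cmap = matplotlib.colormaps[colormap]
    rgb = cmap(np.nan_to_num(values, nan=0.0))[..., :3]
    rgb[~img.mask] = BACKGROUND_RGB
    return rgb


def render(img: MzImage, path: str | os.PathLike,
           settings: RenderSettings | None = None) -> None:
    """Write a pseudo-colored PNG of an m/z-image.

    The lowest measured intensity maps to the blue end of the colormap and
    the highest to the red end (jet); unmeasured pixels are drawn in a
    reserved background gray.  Output is deterministic: identical image +
    settings give byte-identical files.
    """
    settings = settings or RenderSettings()
    rgb = _to_rgb(img, settings.colormap)
    if settings.scale > 1:
        rgb = np.repeat(np.repeat(rgb, settings.scale, axis=0), settings.scale, axis=1)
    if settings.title:
        fig, ax = plt.subplots(figsize=(4, 4), dpi=settings.dpi)
        ax.imshow(rgb, interpolation="nearest")
        ax.set_title(settings.title, fontsize=9)
        ax.axis("off")
        fig.savefig(path, dpi=settings.dpi, metadata={"Software": None})
        plt.close(fig)
    else:
        plt.imsave(path, rgb, metadata={"Software": None})
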