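"""Spectrum pre-processing: normalization, baseline correction, smoothing.

Normalization scales each spectrum so intensities are comparable between
pixels; total-ion-count (TIC) normalization divides a spectrum by the sum
of its intensities, median normalization by the median of its positive
intensities.  Both are per-spectrum scalings and agree up to a constant
factor per spectrum.  By default the normalized cube is rescaled by the
dataset median divisor so intensities stay on an interpretable scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import grey_closing, grey_opening, uniform_filter1d

from .containers import Datacube, Spectrum

__all__ = [
    "tic_normalize",
    "median_normalize",
    "correct_baseline",
    "smooth_spectrum",
    "NormalizationWarning",
]


class NormalizationWarning(UserWarning):
    """Emitted when normalization is requested on an already-normalized cube."""


def _normalize(cube: Datacube, divisors: np.ndarray, method: str,
               target_scale: float | None) -> tuple[Datacube, np.ndarray]:
    state = cube.meta.get("normalization", "none")
    if state not in ("none", None):
        warnings.warn(
            f"cube already normalized ({state}); leaving intensities unchanged",
            NormalizationWarning,
        )
        out = cube.copy_with()
        out.meta["normalization_skipped"] = method
        return out, np.zeros(cube.n_pixels, dtype=bool)

    flagged = ~(divisors > 0)
    safe = np.where(flagged, 1.0, divisors)
    if target_scale is None:
        ok = divisors[~flagged]
        target = float(np.median(ok)) if ok.size else 1.0
    else:
        target = float(target_scale)
    scale = np.where(flagged, 1.0, target / safe)
    out = cube.copy_with(intensities=cube.intensities * scale[:, None])
    out.meta["normalization"] = method
    out.meta["normalization_target"] = target
    out.meta["normalization_flagged"] = int(flagged.sum())
    return out, flagged


def tic_normalize(cube: Datacube, target_scale: float | None = None
                  ) -> tuple[Datacube, np.ndarray]:
    """Divide every spectrum by its TIC, then rescale to a common level.

    ``target_scale=None`` (default) rescales by the dataset median TIC so
    absolute intensities remain interpretable; pass ``1.0`` for unit-TIC
    spectra.  Zero-TIC spectra (empty, off-tissue pixels) are left
    unchanged and flagged in the returned boolean vector.  Re-normalizing
    an already-normalized cube warns and is a no-op.
    """
    tics = cube.intensities.sum(axis=1)
    return _normalize(cube, tics, "tic", target_scale)


def median_normalize(cube: Datacube, target_scale: float | None = None
                     ) -> tuple[Datacube, np.ndarray]:
    """Like :func:`tic_normalize` with the per-spectrum median of positive
    intensities as divisor; spectra with no positive intensity are flagged."""
    inten = cube.intensities
    divisors = np.zeros(cube.n_pixels)
    for i in range(cube.n_pixels):
        pos = inten[i][inten[i] > 0]
        divisors[i] = np.median(pos) if pos.size else 0.0
    return _normalize(cube, divisors, "median", target_scale)


def correct_baseline(spectrum: Spectrum, window: int = 101) -> Spectrum:
    """Subtract a morphological-opening baseline estimate.

    The baseline is estimated by a rolling minimum followed by a rolling
    maximum (grey opening) over *window* channels — a parameter-light
    standard for MALDI spectra; *window* must be odd, >= 3 and wider than
    the peaks to be preserved.  The residual is clipped at zero.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("baseline window must be odd and >= 3")
    y = spectrum.intensities
    if window > y.size:
        raise ValueError("baseline window exceeds spectrum length")
    baseline = grey_opening(y, size=window, mode="reflect")
    # light smoothing of the staircase the opening produces
    baseline = uniform_filter1d(baseline, size=window, mode="reflect")
    baseline = np.minimum(baseline, y)
    return Spectrum(spectrum.axis, np.maximum(y - baseline, 0.0))


def smooth_spectrum(spectrum: Spectrum, window: int = 5) -> Spectrum:
    """Moving-average smoothing with reflective edge handling.

    *window* must be odd (>= 1); window 1 is the identity.  Reflection at
    the edges keeps the TIC conserved to well within 0.1%.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return Spectrum(spectrum.axis, spectrum.intensities.copy())
    smoothed = uniform_filter1d(spectrum.intensities, size=window, mode="reflect")
    return Spectrum(spectrum.axis, np.maximum(smoothed, 0.0))


def smooth_cube(cube: Datacube, window: int = 5) -> Datacube:
    """Apply :func:`smooth_spectrum` to every pixel of a cube."""
    if window == 1:
        return cube.copy_with()
    smoothed = uniform_filter1d(cube.intensities, size=window, mode="reflect", axis=1)
    out = cube.copy_with(intensities=np.maximum(smoothed, 0.0))
    out.meta["smoothed_window"] = window
    return out


def correct_baseline_cube(cube: Datacube, window: int = 101) -> Datacube:
    """Apply :func:`correct_baseline` to every pixel of a cube."""
    out = np.empty_like(cube.intensities)
    for i in range(cube.n_pixels):
        out[i] = correct_baseline(cube.spectrum(i), window).intensities
    res = cube.copy_with(intensities=out)
    res.meta["baseline_window"] = window
    return res
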