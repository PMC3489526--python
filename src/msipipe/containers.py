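"""Core in-memory containers for MALDI-imaging data.

A MALDI-imaging dataset is a *datacube*: a mass spectrum measured at every
pixel of a (possibly irregular) spatial grid.  The containers here hold the
cube as an ``n_pixels x n_channels`` intensity matrix on a shared m/z axis,
plus the derived per-channel spatial views (m/z-images) and per-pixel views
(spectra) the rest of the pipeline operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MzAxis",
    "Datacube",
    "Spectrum",
    "MzImage",
    "MissingIbdError",
    "DuplicateCoordinateError",
    "ChecksumMismatchError",
]


class MissingIbdError(FileNotFoundError):
    """The binary .ibd companion of an .imzML file is absent."""


class DuplicateCoordinateError(ValueError):
    """Two spectra in a file or cube claim the same (x, y) pixel."""


class ChecksumMismatchError(IOError):
    """The .ibd file content does not match the checksum stored in the .imzML."""


@dataclass(frozen=True)
class MzAxis:
    """Shared m/z axis (Daltons) of all spectra in a datacube.

    Values must be finite, strictly increasing and of length >= 2.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("m/z axis must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("m/z axis contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mz_min(self) -> float:
        return float(self.values[0])

    @property
    def mz_max(self) -> float:
        return float(self.values[-1])

    def index_window(self, mz: float, tol: float) -> slice:
        """Channel slice covering the closed window [mz - tol, mz + tol]."""
        lo = int(np.searchsorted(self.values, mz - tol, side="left"))
        hi = int(np.searchsorted(self.values, mz + tol, side="right"))
        if lo >= hi:
            raise ValueError(
                f"window [{mz - tol}, {mz + tol}] Da covers no channel of the "
                f"axis [{self.mz_min}, {self.mz_max}] Da"
            )
        return slice(lo, hi)

    def nearest_channel(self, mz: float) -> int:
        """Index of the axis channel closest to *mz*."""
        i = int(np.searchsorted(self.values, mz))
        if i == 0:
            return 0
        if i >= len(self):
            return len(self) - 1
        return i if self.values[i] - mz < mz - self.values[i - 1] else i - 1


@dataclass
class Spectrum:
    """One mass spectrum: non-negative intensities on an m/z axis."""

    axis: MzAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.axis),) :
            raise ValueError("intensity length must equal axis length")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite and non-negative")
        self.intensities = y

    @property
    def tic(self) -> float:
        """Total ion count: the sum of all intensities."""
        return float(self.intensities.sum())


@dataclass
class Datacube:
    """A hyperspectral MALDI image: one spectrum per pixel.

    Parameters
    ----------
    coords
        ``(n_pixels, 2)`` integer array of (x, y) pixel positions, 1-based
        as stored in imzML.  The grid may have holes (unmeasured pixels).
    intensities
        ``(n_pixels, n_channels)`` non-negative matrix; row *i* is the
        spectrum at ``coords[i]``.
    axis
        The shared m/z axis.
    meta
        Free-form provenance: spatial resolution (um), normalization state,
        acquisition mode (profile / centroid), ...
    """

    coords: np.ndarray
    intensities: np.ndarray
    axis: MzAxis
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=int)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be an (n_pixels, 2) integer array")
        if c.shape[0] == 0:
            raise ValueError("cube must contain at least one pixel")
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 2 or y.shape[0] != c.shape[0]:
            raise ValueError("intensities rows must match number of coords")
        if y.shape[1] != len(self.axis):
            raise ValueError("intensity columns must match axis length")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        uniq = {tuple(p) for p in c}
        if len(uniq) != c.shape[0]:
            raise DuplicateCoordinateError("duplicate pixel coordinates in cube")
        self.coords = c
        self.intensities = y

    @property
    def n_pixels(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.intensities.shape[1])

    # ---- spatial layout -------------------------------------------------

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(x_min, x_max, y_min, y_max) of the measured pixels."""
        x, y = self.coords[:, 0], self.coords[:, 1]
        return int(x.min()), int(x.max()), int(y.min()), int(y.max())

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding-box grid; y runs downward."""
        x0, x1, y0, y1 = self.bounding_box
        return y1 - y0 + 1, x1 - x0 + 1

    def grid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) grid indices of every measured pixel."""
        x0, _, y0, _ = self.bounding_box
        return self.coords[:, 1] - y0, self.coords[:, 0] - x0

    def measured_mask(self) -> np.ndarray:
        """Boolean grid marking pixels that carry a spectrum."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        r, c = self.grid_indices()
        mask[r, c] = True
        return mask

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector onto the bounding-box grid."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_pixels,):
            raise ValueError("need one value per measured pixel")
        grid = np.full(self.grid_shape, fill, dtype=float)
        r, c = self.grid_indices()
        grid[r, c] = values
        return grid

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        """Gather per-pixel values back from a bounding-box grid."""
        grid = np.asarray(grid)
        if grid.shape != self.grid_shape:
            raise ValueError("grid shape must equal the cube bounding box")
        r, c = self.grid_indices()
        return grid[r, c]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i])

    def copy_with(self, intensities: np.ndarray | None = None,
                  meta: dict[str, Any] | None = None) -> "Datacube":
        return Datacube(
            coords=self.coords.copy(),
            intensities=self.intensities.copy() if intensities is None else intensities,
            axis=self.axis,
            meta=dict(self.meta) if meta is None else meta,
        )


@dataclass
class MzImage:
    """One m/z channel (or window) rendered over the pixel grid.

    Unmeasured pixels are NaN in ``grid`` and False in ``mask`` — never a
    silent zero, which would bias correlations and contrast scaling.
    """

    grid: np.ndarray
    mask: np.ndarray
    mz: float
    tol: float = 0.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if g.shape != m.shape or g.ndim != 2:
            raise ValueError("grid and mask must be 2-D arrays of equal shape")
        g = g.copy()
        g[~m] = np.nan
        self.grid = g
        self.mask = m

    @property
    def measured_values(self) -> np.ndarray:
        return self.grid[self.mask]

    def replace_values(self, values: np.ndarray) -> "MzImage":
        """New image with the measured pixels replaced by *values*."""
        grid = np.full_like(self.grid, np.nan)
        grid[self.mask] = np.asarray(values, dtype=float)
        return MzImage(grid=grid, mask=self.mask.copy(), mz=self.mz, tol=self.tol)
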