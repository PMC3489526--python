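"""Reading and writing MALDI-imaging data.

Supports the imzML exchange standard (continuous and processed dialects,
via pyimzml), a single-file HDF5 container used between pipeline stages,
m/z-image extraction, and CSV export of tabular results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from pathlib import Path
from typing import Any, Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .containers import (
    ChecksumMismatchError,
    Datacube,
    DuplicateCoordinateError,
    MissingIbdError,
    MzAxis,
    MzImage,
)

__all__ = [
    "read_imzml",
    "write_imzml",
    "get_mz_image",
    "export_table",
    "save_container",
    "load_container",
]


def _ibd_path(imzml_path: Path) -> Path:
    for ext in (".ibd", ".IBD"):
        cand = imzml_path.with_suffix(ext)
        if cand.exists():
            return cand
    raise MissingIbdError(f"no .ibd companion found for {imzml_path}")


def _verify_checksum(parser: ImzMLParser, ibd: Path) -> None:
    stored = parser.metadata.file_description.param_by_name.get("ibd SHA-1")
    if stored is None:
        return
    digest = hashlib.sha1(ibd.read_bytes()).hexdigest()
    if digest.lower() != str(stored).lower():
        raise ChecksumMismatchError(
            f"ibd SHA-1 mismatch for {ibd}: stored {stored}, computed {digest}"
        )


def read_imzml(path: str | os.PathLike) -> Datacube:
    """Read an imzML/ibd pair into a :class:`Datacube`.

    Continuous-dialect files are loaded spectrum-by-spectrum onto their
    shared axis.  Processed-dialect files (per-spectrum axes) are resampled
    onto a common axis: the union of all axes binned at the median channel
    spacing, linear interpolation, and a per-spectrum rescale that conserves
    each spectrum's trapezoid integral over m/z.

    Raises
    ------
    MissingIbdError, DuplicateCoordinateError, ChecksumMismatchError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = _ibd_path(path)
    parser = ImzMLParser(str(path))
    _verify_checksum(parser, ibd)

    coords = np.asarray([(x, y) for x, y, _z in parser.coordinates], dtype=int)
    seen: set[tuple[int, int]] = set()
    for xy in map(tuple, coords):
        if xy in seen:
            raise DuplicateCoordinateError(f"pixel {xy} appears twice in {path}")
        seen.add(xy)

    n = len(parser.coordinates)
    first_mz, _ = parser.getspectrum(0)
    continuous = parser.metadata.file_description.param_by_name.get("continuous", False)
    if not continuous:
        # verify: processed files may still share one axis in practice
        continuous = all(
            np.array_equal(parser.getspectrum(i)[0], first_mz) for i in range(1, n)
        )

    if continuous:
        axis = MzAxis(np.asarray(first_mz, dtype=float))
        inten = np.empty((n, len(axis)), dtype=float)
        for i in range(n):
            _, ys = parser.getspectrum(i)
            inten[i] = ys
        mode = "continuous"
    else:
        axis, inten = _resample_processed(parser, n)
        mode = "processed-resampled"

    meta: dict[str, Any] = {"source": str(path), "dialect": mode}
    return Datacube(coords=coords, intensities=np.maximum(inten, 0.0), axis=axis, meta=meta)


def _resample_processed(parser: ImzMLParser, n: int) -> tuple[MzAxis, np.ndarray]:
    """Common-axis resampling for processed-dialect files."""
    all_mz = [np.asarray(parser.getspectrum(i)[0], dtype=float) for i in range(n)]
    union = np.unique(np.concatenate(all_mz))
    spacing = float(np.median(np.diff(union))) if union.size > 1 else 1.0
    axis_values = np.arange(union[0], union[-1] + spacing / 2, spacing)
    if axis_values.size < 2:
        axis_values = union
    axis = MzAxis(axis_values)

    inten = np.zeros((n, len(axis)), dtype=float)
    for i, mzs in enumerate(all_mz):
        _, ys = parser.getspectrum(i)
        ys = np.asarray(ys, dtype=float)
        resampled = np.interp(axis.values, mzs, ys, left=0.0, right=0.0)
        # conserve the spectrum's integral over m/z under the axis change
        orig = np.trapezoid(ys, mzs)
        new = np.trapezoid(resampled, axis.values)
        if new > 0 and orig > 0:
            resampled *= orig / new
        inten[i] = resampled
    return axis, inten


def write_imzml(cube: Datacube, path: str | os.PathLike) -> None:
    """Write a cube as a continuous-dialect imzML/ibd pair (64-bit floats)."""
    path = Path(path)
    mode = cube.meta.get("acquisition_mode", "profile")
    spec_type = "centroid" if mode == "centroid" else "profile"
    with ImzMLWriter(
        str(path),
        mode="continuous",
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        spec_type=spec_type,
    ) as writer:
        for i in range(cube.n_pixels):
            x, y = cube.coords[i]
            writer.addSpectrum(cube.axis.values, cube.intensities[i], (int(x), int(y), 1))


def get_mz_image(cube: Datacube, mz: float, tol: float) -> MzImage:
    """Render one m/z window as a spatial image.

    The per-pixel value is the *sum* of channel intensities whose m/z lies
    in the closed window ``[mz - tol, mz + tol]``; summation (rather than a
    maximum) keeps the image proportional to ion abundance, which the
    normalization and correlation stages rely on.  Pixels absent from the
    grid are masked, never zero-filled.
    """
    window = cube.axis.index_window(mz, tol)
    values = cube.intensities[:, window].sum(axis=1)
    grid = cube.to_grid(values)
    return MzImage(grid=grid, mask=cube.measured_mask(), mz=float(mz), tol=float(tol))


def export_table(records: Iterable[Any], path: str | os.PathLike,
                 columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write tabular results (dataclasses, dicts or tuples) to CSV.

    The header row is taken from dataclass fields / dict keys, or from
    *columns* for plain tuples.  An empty record list still produces a
    header-only file when *columns* is given.
    """
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    elif records and isinstance(records[0], dict):
        frame = pd.DataFrame(records)
    else:
        frame = pd.DataFrame(records, columns=columns)
    if frame.empty and columns is not None:
        frame = pd.DataFrame(columns=list(columns))
    frame.to_csv(path, index=False, float_format="%.6g")
    return frame


# ---- internal container (fast re-entry between CLI stages) --------------

def save_container(cube: Datacube, path: str | os.PathLike) -> None:
    """Persist a cube as a single HDF5 file mirroring the Datacube fields."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=cube.coords)
        f.create_dataset("intensities", data=cube.intensities)
        f.create_dataset("mz", data=cube.axis.values)
        meta = f.create_group("meta")
        for key, value in cube.meta.items():
            meta.attrs[key] = value if not isinstance(value, (list, tuple)) else list(value)


def load_container(path: str | os.PathLike) -> Datacube:
    with h5py.File(path, "r") as f:
        coords = f["coords"][()]
        inten = f["intensities"][()]
        axis = MzAxis(f["mz"][()])
        meta = {k: _h5attr(v) for k, v in f["meta"].attrs.items()}
    return Datacube(coords=coords, intensities=inten, axis=axis, meta=meta)


def _h5attr(value: Any) -> Any:
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value
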