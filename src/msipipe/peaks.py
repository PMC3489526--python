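"""Peak picking and peak-list handling.

MALDI-imaging produces thousands of spectra; dataset-level peak lists are
built in two stages.  Picking on the dataset *mean spectrum* is fast but
insensitive: a peak confined to 1% of the pixels contributes 100x less to
the mean than an equally intense ubiquitous (e.g. matrix) peak.  The
*consensus* approach therefore picks peaks in every spectrum, aligns them
against the mean spectrum and keeps those found in at least a minimum
fraction (default 1%) of the spectra.

The spectrum-wise picker is a prominence-based local-maxima detector with
a robust (MAD) noise estimate — a shape-aware, O(n log n) method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .containers import Datacube, Spectrum

__all__ = [
    "PeakList",
    "ConsensusPeakList",
    "mean_spectrum",
    "pick_peaks",
    "align_to_mean",
    "consensus_filter",
    "align_masses_uphill",
    "dataset_peaks",
]

DEFAULT_TOL = 0.5          # Da; protein-range TOF matching tolerance
DEFAULT_MIN_FRACTION = 0.01
TARGET_PEAK_RANGE = (50, 200)


@dataclass
class PeakList:
    """Peaks of one spectrum: (m/z, intensity) pairs on the cube axis."""

    mzs: np.ndarray
    intensities: np.ndarray
    unaligned: np.ndarray = field(default=None)  # set by align_to_mean

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mzs.shape != self.intensities.shape:
            raise ValueError("mzs and intensities must have equal length")
        if np.any(self.intensities <= 0):
            raise ValueError("peak intensities must be positive")
        if self.unaligned is None:
            self.unaligned = np.zeros(self.mzs.shape, dtype=bool)

    def __len__(self) -> int:
        return int(self.mzs.size)


@dataclass
class ConsensusPeakList:
    """Dataset-level peaks with the fraction of spectra they appear in."""

    mzs: np.ndarray
    presence_fractions: np.ndarray
    mean_intensities: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.mzs)
        self.mzs = np.asarray(self.mzs, dtype=float)[order]
        self.presence_fractions = np.asarray(self.presence_fractions, dtype=float)[order]
        self.mean_intensities = np.asarray(self.mean_intensities, dtype=float)[order]
        if np.any(self.presence_fractions <= 0) or np.any(self.presence_fractions > 1):
            raise ValueError("presence fractions must lie in (0, 1]")

    def __len__(self) -> int:
        return int(self.mzs.size)


def mean_spectrum(cube: Datacube, chunk: int = 1024) -> Spectrum:
    """Channel-wise mean over all pixels, accumulated in O(n_channels).

    Spectra are streamed in chunks so the running state is a single
    channel-length accumulator regardless of dataset size.
    """
    if cube.n_pixels == 0:
        raise ValueError("cube has no pixels")
    acc = np.zeros(cube.n_channels)
    for start in range(0, cube.n_pixels, chunk):
        acc += cube.intensities[start:start + chunk].sum(axis=0)
    return Spectrum(cube.axis, acc / cube.n_pixels)


def _noise_sigma(y: np.ndarray, detail_window: int = 5) -> float:
    """Robust noise scale: 1.4826 * MAD of the detail residual."""
    kernel = np.ones(detail_window) / detail_window
    smooth = np.convolve(y, kernel, mode="same")
    resid = y - smooth
    mad = np.median(np.abs(resid - np.median(resid)))
    return 1.4826 * float(mad)


def pick_peaks(spectrum: Spectrum, snr: float = 3.0,
               max_peaks: int | None = None) -> PeakList:
    """Local maxima whose prominence exceeds ``snr`` x the noise estimate.

    The noise estimate is the MAD of the detail residual (spectrum minus a
    short moving average), so broad structure does not inflate it.  For a
    noiseless spectrum the threshold degenerates to a tiny floor and every
    genuine apex is returned.  At most ``max_peaks`` highest-intensity
    peaks are kept.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    y = spectrum.intensities
    sigma = _noise_sigma(y)
    floor = 1e-9 * (float(y.max()) if y.size else 1.0)
    threshold = max(snr * sigma, floor)
    idx, _props = find_peaks(y, prominence=threshold)
    if idx.size == 0:
        return PeakList(np.empty(0), np.empty(0))
    if max_peaks is not None and idx.size > max_peaks:
        keep = np.argsort(y[idx])[::-1][:max_peaks]
        idx = np.sort(idx[keep])
    return PeakList(spectrum.axis.values[idx], y[idx])


def _mean_maxima(mean: Spectrum) -> np.ndarray:
    """m/z of local maxima of the mean spectrum (plateaus -> one apex)."""
    idx, _ = find_peaks(mean.intensities, prominence=0.0)
    # find_peaks skips boundary maxima; keep them for completeness
    y = mean.intensities
    extra = []
    if y.size >= 2 and y[0] > y[1]:
        extra.append(0)
    if y.size >= 2 and y[-1] > y[-2]:
        extra.append(y.size - 1)
    idx = np.unique(np.concatenate([idx, np.asarray(extra, dtype=int)]))
    return mean.axis.values[idx]


def align_to_mean(peaklists: list[PeakList], mean: Spectrum,
                  tol: float = DEFAULT_TOL) -> list[PeakList]:
    """Snap spectrum-level peak positions to the mean spectrum's maxima.

    Instrumental jitter moves an ion's apex between spectra; snapping each
    picked m/z to the nearest local maximum of the mean spectrum within
    ``tol`` makes the per-spectrum lists comparable.  Peaks with no mean
    maximum within ``tol`` are kept unmoved and flagged in ``unaligned``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    apexes = _mean_maxima(mean)
    out = []
    for pl in peaklists:
        if len(pl) == 0 or apexes.size == 0:
            out.append(PeakList(pl.mzs.copy(), pl.intensities.copy(),
                                np.ones(len(pl), dtype=bool)))
            continue
        pos = np.searchsorted(apexes, pl.mzs)
        left = np.clip(pos - 1, 0, apexes.size - 1)
        right = np.clip(pos, 0, apexes.size - 1)
        d_left = np.abs(pl.mzs - apexes[left])
        d_right = np.abs(pl.mzs - apexes[right])
        nearest = np.where(d_left <= d_right, apexes[left], apexes[right])
        dist = np.minimum(d_left, d_right)
        unaligned = dist > tol
        snapped = np.where(unaligned, pl.mzs, nearest)
        out.append(PeakList(snapped, pl.intensities.copy(), unaligned))
    return out


def consensus_filter(peaklists: list[PeakList],
                     min_fraction: float = DEFAULT_MIN_FRACTION,
                     tol: float = DEFAULT_TOL) -> ConsensusPeakList:
    """Merge per-spectrum peak lists into a dataset consensus list.

    Peaks from different spectra are matched within ``tol`` (sorted m/z,
    a gap larger than ``tol`` starts a new group) and a group is retained
    iff it occurs in at least ``min_fraction`` of the spectra.  Raising
    ``min_fraction`` can only remove peaks (monotone filter).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_spectra = len(peaklists)
    all_mz, all_int, all_src = [], [], []
    for s, pl in enumerate(peaklists):
        all_mz.append(pl.mzs)
        all_int.append(pl.intensities)
        all_src.append(np.full(len(pl), s))
    if not all_mz or sum(len(a) for a in all_mz) == 0:
        e = np.empty(0)
        return ConsensusPeakList(e, e.copy(), e.copy())
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    src = np.concatenate(all_src)
    order = np.argsort(mz)
    mz, inten, src = mz[order], inten[order], src[order]

    group_start = np.concatenate([[True], np.diff(mz) > tol])
    group_id = np.cumsum(group_start) - 1
    n_groups = group_id[-1] + 1

    out_mz, out_frac, out_int = [], [], []
    for g in range(n_groups):
        sel = group_id == g
        spectra = np.unique(src[sel])
        frac = spectra.size / n_spectra
        if frac >= min_fraction and frac > 0:
            weights = inten[sel]
            out_mz.append(float(np.average(mz[sel], weights=weights)))
            out_frac.append(min(frac, 1.0))
            out_int.append(float(inten[sel].sum() / n_spectra))
    return ConsensusPeakList(np.asarray(out_mz), np.asarray(out_frac),
                             np.asarray(out_int))


def align_masses_uphill(mzs: np.ndarray, mean: Spectrum) -> np.ndarray:
    """Move m/z values uphill along the mean spectrum into local maxima.

    Each input m/z starts at its nearest axis channel and repeatedly steps
    to a strictly higher neighboring channel until none exists; values on
    a plateau drift to the plateau's lowest-m/z channel (deterministic
    tie-break).  Several inputs on the flanks of one peak merge into its
    single apex, so the output (sorted, deduplicated) is never longer than
    the input.  The operation is idempotent.
    """
    y = mean.intensities
    axis = mean.axis
    result = set()
    for mz in np.atleast_1d(np.asarray(mzs, dtype=float)):
        if not axis.mz_min <= mz <= axis.mz_max:
            raise ValueError(f"m/z {mz} outside axis range")
        i = axis.nearest_channel(mz)
        while True:
            left = y[i - 1] if i > 0 else -np.inf
            right = y[i + 1] if i < y.size - 1 else -np.inf
            if left > y[i] or right > y[i]:
                # climb toward the higher neighbor; ties go to lower m/z
                i = i - 1 if left >= right else i + 1
            elif left == y[i] and i > 0:
                i -= 1          # plateau: drift to its lowest-m/z channel
            else:
                break
        result.add(float(axis.values[i]))
    return np.asarray(sorted(result))


def dataset_peaks(cube: Datacube, snr: float = 3.0,
                  min_fraction: float = DEFAULT_MIN_FRACTION,
                  tol: float = DEFAULT_TOL,
                  max_peaks_per_spectrum: int | None = 60,
                  target_range: tuple[int, int] | None = TARGET_PEAK_RANGE
                  ) -> ConsensusPeakList:
    """Full consensus pipeline: pick per spectrum, align, filter.

    If the consensus list exceeds ``target_range[1]`` peaks (for modeling,
    50-200 dataset peaks is a practical sweet spot), the spectrum-wise SNR
    threshold is raised until the list fits; presence-qualified peaks are
    never dropped silently by other means.
    """
    mean = mean_spectrum(cube)
    current_snr = snr
    for _ in range(12):
        lists = [pick_peaks(cube.spectrum(i), current_snr, max_peaks_per_spectrum)
                 for i in range(cube.n_pixels)]
        aligned = align_to_mean(lists, mean, tol)
        consensus = consensus_filter(aligned, min_fraction, tol)
        if target_range is None or len(consensus) <= target_range[1]:
            return consensus
        current_snr *= 1.5
    return consensus
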