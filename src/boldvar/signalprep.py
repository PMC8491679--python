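"""Conditioning of voxel time series and voxel-wise BOLD signal variability.

The resting-state variability measure used throughout this package is
``SD_BOLD``: the per-voxel standard deviation of a conditioned BOLD time
series.  Conditioning follows the conventional resting-state recipe for
variability analyses:

1. discard initial volumes (scanner equilibration),
2. remove a low-order polynomial trend per voxel,
3. zero-phase Butterworth band-pass filtering (default 0.01-0.10 Hz).

With the population (divide-by-N) standard deviation, ``SD_BOLD**2`` equals
the mean power of the demeaned series, so SD_BOLD is the square root of the
total (non-DC) spectral power of the same series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class VoxelTimeSeries:
    """One subject-occasion's voxels x timepoints matrix.

    Parameters
    ----------
    values : ndarray, shape (n_voxels, n_timepoints)
        BOLD signal in arbitrary units.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    voxel_ids : ndarray of int
        Ordered indices into the analysis mask; must be unique.
    subject_id : str
    occasion : int
        Measurement occasion, 1 or 2.
    """

    values: np.ndarray
    tr_seconds: float
    voxel_ids: np.ndarray = field(default=None)
    subject_id: str = ""
    occasion: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (voxels x timepoints) array")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("series must have at least one voxel and one timepoint")
        if not np.isfinite(self.tr_seconds) or self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be a positive finite number")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.values.shape[0])
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.voxel_ids.shape[0] != self.values.shape[0]:
            raise ValueError("voxel_ids length must match number of voxels")
        if np.unique(self.voxel_ids).size != self.voxel_ids.size:
            raise ValueError("voxel_ids must be unique")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def replace(self, values: np.ndarray) -> "VoxelTimeSeries":
        return dataclasses.replace(self, values=values)


@dataclass
class SDMap:
    """Per-voxel SD_BOLD for one subject-occasion."""

    values: np.ndarray
    voxel_ids: np.ndarray
    subject_id: str = ""
    occasion: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.values.shape != self.voxel_ids.shape:
            raise ValueError("values and voxel_ids must have equal length")
        if np.any(self.values < 0):
            raise ValueError("SD values must be nonnegative")


def discard_initial_volumes(ts: VoxelTimeSeries, n_discard: int = 4) -> VoxelTimeSeries:
    """Drop the first ``n_discard`` volumes (default 4, i.e. 10 s at TR 2.5 s)."""
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} timepoints"
        )
    return ts.replace(ts.values[:, n_discard:])


def detrend_poly(ts: VoxelTimeSeries, order: int = 2) -> VoxelTimeSeries:
    """Remove a least-squares polynomial trend of given order (0, 1 or 2).

    The residual is orthogonal to the polynomial basis by construction
    (normal equations).  ``order=0`` removes the mean.
    """
    if order not in (0, 1, 2):
        raise ValueError("detrend order must be 0, 1 or 2")
    t = ts.n_timepoints
    if t <= order + 1:
        raise ValueError("series too short for requested detrend order")
    # Scaled time axis keeps the Vandermonde basis well conditioned.
    x = np.linspace(-1.0, 1.0, t)
    basis = np.vander(x, order + 1, increasing=True)  # (T, order+1)
    coef, *_ = np.linalg.lstsq(basis, ts.values.T, rcond=None)
    residual = ts.values - (basis @ coef).T
    return ts.replace(residual)


def _bandpass_sos(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, Nyquist={fs / 2.0}) Hz"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    order: int = 8,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis of ``values``.

    Forward-backward application (``sosfiltfilt``) gives zero phase delay at
    the cost of doubling the effective attenuation order.  Edges are handled
    by reflect padding (scipy's ``padtype='even'``); the series must be longer
    than the pad length, which for the default order-8 design is 49 samples.
    """
    values = np.asarray(values, dtype=float)
    sos = _bandpass_sos(low_hz, high_hz, order, 1.0 / tr_seconds)
    n_sections = sos.shape[0]
    padlen = 3 * (2 * n_sections + 1)
    if values.shape[-1] <= padlen:
        raise ValueError(
            f"series of length {values.shape[-1]} too short for order-{order} "
            f"zero-phase filtering (needs > {padlen} samples)"
        )
    return sps.sosfiltfilt(sos, values, axis=-1, padtype="even")


def butterworth_bandpass(
    ts: VoxelTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    order: int = 8,
) -> VoxelTimeSeries:
    """Zero-phase band-pass of every voxel series; output length equals input."""
    return ts.replace(bandpass_array(ts.values, ts.tr_seconds, low_hz, high_hz, order))


def hf_power_fraction(series: np.ndarray, tr_seconds: float, cutoff_hz: float = 0.10) -> float:
    """Fraction of non-DC spectral power above ``cutoff_hz``.

    Periodogram of the demeaned series; DC is excluded from "total spectral
    power".  Raises for an (all-)constant series, whose fraction is undefined.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 8:
        raise ValueError("series must have at least 8 samples")
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq}) Hz")
    x = series - series.mean()
    freqs, power = sps.periodogram(x, fs=1.0 / tr_seconds, detrend=False)
    nonzero = freqs > 0
    total = power[nonzero].sum()
    if total <= 0.0:
        raise ValueError("total spectral power is zero; fraction undefined")
    return float(power[freqs > cutoff_hz].sum() / total)


def is_hf_noise(
    series: np.ndarray,
    tr_seconds: float,
    cutoff_hz: float = 0.10,
    min_fraction: float = 0.75,
) -> bool:
    """High-frequency noise flag: >= 75% of non-DC power above the cutoff."""
    return hf_power_fraction(series, tr_seconds, cutoff_hz) >= min_fraction


def sd_bold_map(ts: VoxelTimeSeries, ddof: int = 0) -> SDMap:
    """Per-voxel SD of the conditioned series.

    The default population form (``ddof=0``) makes SD^2 exactly the mean
    power of the demeaned series (Parseval); ``ddof=1`` gives the sample SD.
    """
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for an SD")
    sd = ts.values.std(axis=1, ddof=ddof)
    return SDMap(values=sd, voxel_ids=ts.voxel_ids, subject_id=ts.subject_id, occasion=ts.occasion)


def sd_change_map(t1: SDMap, t2: SDMap) -> SDMap:
    """Longitudinal change in SD_BOLD: Time 2 minus Time 1, per voxel."""
    if t1.subject_id != t2.subject_id:
        raise ValueError("SD maps belong to different subjects")
    if not np.array_equal(t1.voxel_ids, t2.voxel_ids):
        raise ValueError("SD maps use different voxel masks")
    change = t2.values - t1.values
    # A change map is signed; bypass the nonnegativity check of SDMap.
    out = SDMap.__new__(SDMap)
    out.values = np.asarray(change, dtype=float)
    out.voxel_ids = np.asarray(t1.voxel_ids, dtype=int)
    out.subject_id = t1.subject_id
    out.occasion = 0
    return out


def condition(
    ts: VoxelTimeSeries,
    n_discard: int = 4,
    detrend_order: int = 2,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    filter_order: int = 8,
) -> VoxelTimeSeries:
    """Full conditioning pipeline: discard -> detrend -> band-pass.

    The order is fixed; SD_BOLD of the output is invariant to adding a
    constant to the raw series (removed at the detrend step).
    """
    out = discard_initial_volumes(ts, n_discard)
    out = detrend_poly(out, detrend_order)
    out = butterworth_bandpass(out, low_hz, high_hz, filter_order)
    if not np.all(np.isfinite(out.values)):
        raise ValueError("non-finite values after conditioning")
    return out
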