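"""Signal conditioning between raw recordings and feature extraction.

Covers the modified Beer–Lambert conversion from optical-density
changes to chromophore concentrations, scalp-coupling-style channel
quality pruning, a simplified spline + wavelet motion-artifact
correction, and leakage-aware feature standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt

from .exceptions import AllChannelsPrunedError, SpecError
from .synthetic_data import BANDS, FNIRSRecord


@dataclass(frozen=True)
class OpticalConversionParams:
    """Parameters of the modified Beer–Lambert law for a two-wavelength system.

    ``extinction`` is the 2×2 matrix of specific extinction coefficients,
    rows per wavelength, columns (HbO, HbR), in 1/(µM·cm).  Defaults use
    Gratzer-style tabulated values for 757 and 843 nm, a differential
    pathlength factor of 6 and a 3 cm source–detector separation.
    """

    wavelengths_nm: tuple[float, float] = (757.0, 843.0)
    extinction: tuple[tuple[float, float], ...] = (
        (1.4866e-3, 3.8437e-3),
        (2.5264e-3, 1.7986e-3),
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0

    def matrix(self) -> np.ndarray:
        e = np.asarray(self.extinction, dtype=float)
        if e.shape != (2, 2):
            raise SpecError("extinction must be a 2x2 matrix")
        if not np.isfinite(np.linalg.cond(e)) or np.linalg.cond(e) > 1e12:
            raise SpecError("extinction matrix is singular or near-singular")
        return e


def od_forward(
    hbo: np.ndarray, hbr: np.ndarray, params: OpticalConversionParams
) -> np.ndarray:
    """Forward model: concentration changes (µM) → optical-density changes.

    Returns a (2, n) array, one row per wavelength.  This is the exact
    inverse of :func:`beer_lambert` and exists so the conversion can be
    validated round-trip and so optical-density inputs can be simulated.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise SpecError("HbO and HbR must have equal length")
    e = params.matrix()
    conc = np.vstack([hbo, hbr])
    scale = np.asarray(params.dpf) * params.distance_cm
    return (e @ conc) * scale[:, None]


def beer_lambert(
    od_changes: np.ndarray, params: OpticalConversionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 2×2 modified Beer–Lambert system per sample.

    ``od_changes`` holds one row per wavelength.  Returns (HbO, HbR)
    concentration-change series in µM.
    """
    od = np.asarray(od_changes, dtype=float)
    if od.ndim != 2 or od.shape[0] != 2:
        raise SpecError("od_changes must be a (2, n) array, one row per wavelength")
    e = params.matrix()
    scale = np.asarray(params.dpf) * params.distance_cm
    conc = np.linalg.solve(e, od / scale[:, None])
    return conc[0], conc[1]


def total_hemoglobin(hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
    """Samplewise HbT = HbO + HbR."""
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise SpecError("HbO and HbR must have equal length")
    return hbo + hbr


@dataclass
class PruneReport:
    quality: np.ndarray  # per-channel score in [0, 1]
    retained: np.ndarray  # boolean mask, original channel order
    threshold: float


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    b, a = butter(3, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x, axis=-1)


def channel_quality(record: FNIRSRecord, band_hz=(0.7, 1.5)) -> np.ndarray:
    """Cardiac-band coupling score per channel.

    The absolute Pearson correlation between the band-passed (default
    0.7–1.5 Hz) HbO and HbR traces: a well-coupled optode sees the same
    cardiac pulsation in both chromophores, so |r| is near 1, while a
    channel dominated by instrument noise decorrelates.  This is the
    scalp-coupling-index idea applied to the chromophore pair.
    """
    hbo = _bandpass(record.data[0], record.fs, *band_hz)
    hbr = _bandpass(record.data[1], record.fs, *band_hz)
    q = np.empty(record.n_channels)
    for ch in range(record.n_channels):
        a, b = hbo[ch] - hbo[ch].mean(), hbr[ch] - hbr[ch].mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        q[ch] = 0.0 if denom == 0 else abs(float((a * b).sum() / denom))
    return q


def prune_channels(
    record: FNIRSRecord, quality_threshold: float = 0.7
) -> tuple[FNIRSRecord, PruneReport]:
    """Flag poor channels (quality below threshold) as not retained.

    Data are kept in place and never reordered; downstream feature
    extraction median-fills flagged channels so the feature layout stays
    fixed.  Channels already flagged stay flagged (idempotent).  Raises
    :class:`AllChannelsPrunedError` if nothing survives.
    """
    q = channel_quality(record)
    prior = np.array([m.retained for m in record.channel_meta])
    keep = (q >= quality_threshold) & prior
    if not keep.any():
        raise AllChannelsPrunedError(
            f"all {record.n_channels} channels fall below quality "
            f"{quality_threshold}; pipeline cannot proceed"
        )
    out = record.copy()
    out.channel_meta = [
        replace(m, retained=bool(k)) for m, k in zip(out.channel_meta, keep)
    ]
    return out, PruneReport(q, keep, quality_threshold)


def _flag_motion_samples(
    x: np.ndarray, fs: float, detection_zscore: float, window_s: float = 0.4
) -> np.ndarray:
    """Boolean mask of samples whose local (moving-sd) amplitude is anomalous.

    The moving standard deviation is compared against its own robust
    centre/scale (median and MAD); spikes and step edges inflate it far
    beyond the bulk.  Flagged samples are dilated by one window so the
    artifact's flanks are included.
    """
    if not np.isfinite(detection_zscore):
        return np.zeros(x.size, dtype=bool)
    w = max(3, int(round(window_s * fs)))
    mean = uniform_filter1d(x, w)
    sq = uniform_filter1d(x * x, w)
    msd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    med = np.median(msd)
    mad = np.median(np.abs(msd - med)) * 1.4826
    if mad == 0:
        mad = msd.std() or 1.0
    z = (msd - med) / mad
    flagged = z > detection_zscore
    if flagged.any():
        flagged = uniform_filter1d(flagged.astype(float), 2 * w + 1) > 0
    return flagged


# public name: useful for validating detection against injected ground truth
flag_motion_samples = _flag_motion_samples


def _spline_fill(x: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    good = ~flagged
    if good.sum() < 4:
        raise SpecError("artifact segment spans (nearly) the entire record")
    idx = np.arange(x.size)
    cs = CubicSpline(idx[good], x[good])
    out = x.copy()
    out[flagged] = cs(idx[flagged])
    return out


def _wavelet_despike(x: np.ndarray, level: int, k: float = 5.0) -> np.ndarray:
    """Clamp outlier wavelet detail coefficients.

    Detail coefficients beyond k robust-SDs of their level are shrunk to
    the clamp boundary; on artifact-free data essentially nothing
    exceeds 5σ so the trace passes through unchanged.
    """
    level = min(level, pywt.dwt_max_level(x.size, pywt.Wavelet("db4").dec_len))
    if level < 1:
        return x
    coeffs = pywt.wavedec(x, "db4", level=level, mode="symmetric")
    for d in coeffs[1:]:
        sigma = np.median(np.abs(d)) * 1.4826
        if sigma == 0:
            continue
        np.clip(d, -k * sigma, k * sigma, out=d)
    rec = pywt.waverec(coeffs, "db4", mode="symmetric")
    return rec[: x.size]


def correct_motion(
    record: FNIRSRecord,
    detection_zscore: float = 5.0,
    wavelet_level: int = 4,
) -> FNIRSRecord:
    """Simplified spline + wavelet motion-artifact correction.

    Per channel and chromophore: samples whose moving-SD z-score exceeds
    ``detection_zscore`` are replaced by cubic-spline interpolation of
    the flanking clean samples, then residual high-amplitude wavelet
    detail coefficients are clamped.  HbT is recomputed from the
    corrected HbO and HbR.  ``detection_zscore=inf`` with
    ``wavelet_level=0`` is the identity.
    """
    out = record.copy()
    for b in (0, 1):  # hbo, hbr
        for ch in range(out.n_channels):
            x = out.data[b, ch]
            flagged = _flag_motion_samples(x, out.fs, detection_zscore)
            if flagged.any():
                x = _spline_fill(x, flagged)
            if wavelet_level > 0:
                x = _wavelet_despike(x, wavelet_level)
            out.data[b, ch] = x
    out.data[2] = out.data[0] + out.data[1]
    return out


@dataclass
class Standardization:
    """Per-feature location/scale fitted on a chosen row subset."""

    mean: np.ndarray
    sd: np.ndarray  # zero-variance columns carry sd 1 and are flagged
    zero_variance: np.ndarray  # boolean


def fit_standardization(
    values: np.ndarray, fit_rows: np.ndarray | None = None
) -> Standardization:
    """Compute column means/SDs on ``fit_rows`` only (all rows by default).

    Zero-variance columns are flagged and given unit scale so they pass
    through centred rather than crashing the transform.
    """
    v = np.asarray(values, dtype=float)
    rows = np.arange(v.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    if rows.size == 0:
        raise SpecError("fit_rows must be non-empty")
    sub = v[rows]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s) passed through centred",
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    return Standardization(mean, sd, zero)


def apply_standardization(values: np.ndarray, stats: Standardization) -> np.ndarray:
    return (np.asarray(values, dtype=float) - stats.mean) / stats.sd


def invert_standardization(values: np.ndarray, stats: Standardization) -> np.ndarray:
    return np.asarray(values, dtype=float) * stats.sd + stats.mean


def standardize(
    values: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, Standardization]:
    """Centre/scale columns using statistics from ``fit_rows`` only.

    Returning the fitted statistics lets held-out rows be transformed
    with the training distribution instead of their own — the
    leakage-guard contract.
    """
    stats = fit_standardization(values, fit_rows)
    return apply_standardization(values, stats), stats
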