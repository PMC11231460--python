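"""Temporal and spectral feature extraction for multichannel fNIRS records.

Each (channel, chromophore-band) trace yields twelve features: six
temporal — maximum absolute value, mean, variance, skewness, mean
inter-zero-crossing interval, mean zero-crossing-to-peak interval — and
six spectral — mean, variance, skewness, kurtosis, energy and dominant
frequency of the one-sided magnitude spectrum.  At the default
22-channel × 3-band layout this is the 792-column feature vector per
subject (396 temporal + 396 spectral).

Conventions (documented in the emitted feature dictionary):

* zero crossings are sign changes of the mean-removed trace; a sample
  exactly at zero counts as one crossing;
* the crossing-to-peak interval runs from each zero crossing to the
  next local extremum of the mean-removed trace;
* the spectrum is the magnitude of the DFT of the mean-removed,
  untapered trace, one-sided, DC excluded, normalised so that the sum
  of squared magnitudes equals the time-domain energy (Parseval);
* skewness and kurtosis are population moment ratios, kurtosis
  non-excess; variance divides by N.

Signals with no zero crossings report the record duration as a sentinel
for the interval features and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import json
import numpy as np
import pandas as pd

from .exceptions import SpecError
from .synthetic_data import BANDS, Cohort

TEMPORAL_NAMES = ("max_abs", "mean", "variance", "skewness", "zc_interval", "zc_to_peak")
SPECTRAL_NAMES = ("mean", "variance", "skewness", "kurtosis", "energy", "dominant_freq")
N_FEATURES_PER_BAND = len(TEMPORAL_NAMES) + len(SPECTRAL_NAMES)


@dataclass(frozen=True)
class Signal:
    """A single-channel, single-band concentration trace."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise SpecError("signal must be 1-D with at least 2 samples")
        if self.fs <= 0:
            raise SpecError("fs must be positive")
        object.__setattr__(self, "samples", x)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum, DC bin excluded."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.size != m.size or f.size == 0:
            raise SpecError("freqs and magnitude must be non-empty, equal length")
        if np.any(np.diff(f) <= 0):
            raise SpecError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "magnitude", m)


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness, kurtosis (non-excess); 0 on flat."""
    mu = float(x.mean())
    d = x - mu
    m2 = float((d * d).mean())
    if m2 == 0:
        return mu, 0.0, 0.0, 0.0
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return mu, m2, m3 / m2**1.5, m4 / m2**2


def _zero_crossings(y: np.ndarray) -> np.ndarray:
    """Indices i where the mean-removed trace crosses zero between i and i+1.

    An exact zero sample counts as a single crossing at its own index.
    """
    s = np.sign(y)
    exact = np.flatnonzero(s == 0)
    # sign changes between consecutive non-zero samples
    nz = np.flatnonzero(s != 0)
    changes = nz[:-1][s[nz[:-1]] * s[nz[1:]] < 0] if nz.size > 1 else np.array([], int)
    return np.unique(np.concatenate([exact, changes]))


def _local_extrema(y: np.ndarray) -> np.ndarray:
    d = np.diff(y)
    s = np.sign(d)
    # carry the last non-zero slope through plateaus
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return np.flatnonzero(s[:-1] * s[1:] < 0) + 1


def temporal_features(sig: Signal) -> dict[str, float]:
    """The six temporal features of one trace.

    Interval features (5–6) operate on the mean-removed trace and are
    returned in seconds.  A trace that never crosses zero gets the
    record duration as a flagged sentinel for both.
    """
    x = sig.samples
    mu, var, skew, _ = _moments(x)
    out = {
        "max_abs": float(np.max(np.abs(x))),
        "mean": mu,
        "variance": var,
        "skewness": skew,
    }
    y = x - mu
    # a flat trace has no genuine crossings even though every sample is zero
    zc = _zero_crossings(y) if np.any(y != 0) else np.array([], dtype=int)
    if zc.size >= 2:
        out["zc_interval"] = float(np.diff(zc).mean() / sig.fs)
    else:
        out["zc_interval"] = sig.duration_s  # sentinel: no crossing pair
    ext = _local_extrema(y)
    if zc.size and ext.size:
        pos = np.searchsorted(ext, zc, side="right")
        valid = pos < ext.size
        if valid.any():
            out["zc_to_peak"] = float(((ext[pos[valid]] - zc[valid]) / sig.fs).mean())
        else:
            out["zc_to_peak"] = sig.duration_s
    else:
        out["zc_to_peak"] = sig.duration_s
    return out


def power_spectrum(sig: Signal) -> Spectrum:
    """One-sided magnitude spectrum of the mean-removed trace.

    Normalised so that Σ magnitude² equals Σ (x−x̄)² exactly (the
    interior bins carry √(2/N), a Nyquist bin √(1/N)).
    """
    y = sig.samples - sig.samples.mean()
    n = y.size
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.fs)
    mag = np.abs(spec) * np.sqrt(2.0 / n)
    if n % 2 == 0:
        mag[-1] = np.abs(spec[-1]) * np.sqrt(1.0 / n)
    return Spectrum(freqs[1:], mag[1:])


def spectral_features(sp: Spectrum) -> dict[str, float]:
    """Mean, variance, skewness, kurtosis, energy and dominant frequency.

    Moments are taken over the magnitude values.  An all-zero spectrum
    reports zero moments and an undefined (NaN) dominant frequency.
    """
    m = sp.magnitude
    mu, var, skew, kurt = _moments(m)
    energy = float((m * m).sum())
    if np.all(m == 0):
        dom = float("nan")
    else:
        dom = float(sp.freqs_hz[int(np.argmax(m))])
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "dominant_freq": dom,
    }


def band_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """All 12 features of one trace, keyed ``t_<name>`` / ``s_<name>``."""
    sig = Signal(x, fs)
    out = {f"t_{k}": v for k, v in temporal_features(sig).items()}
    sp = power_spectrum(sig)
    out.update({f"s_{k}": v for k, v in spectral_features(sp).items()})
    return out


def feature_name(channel: int, band: str, domain: str, name: str) -> str:
    return f"ch{channel + 1:02d}_{band}_{domain}_{name}"


def parse_feature_name(col: str) -> tuple[int, str, str, str]:
    """Inverse of :func:`feature_name`; returns (channel0, band, domain, name)."""
    ch, band, domain, name = col.split("_", 3)
    if not ch.startswith("ch") or band not in BANDS or domain not in ("t", "s"):
        raise SpecError(f"unparseable feature name {col!r}")
    return int(ch[2:]) - 1, band, domain, name


def feature_columns(n_channels: int) -> list[str]:
    """Channel-major, band-minor, temporal-then-spectral column order."""
    cols = []
    for c in range(n_channels):
        for band in BANDS:
            for name in TEMPORAL_NAMES:
                cols.append(feature_name(c, band, "t", name))
            for name in SPECTRAL_NAMES:
                cols.append(feature_name(c, band, "s", name))
    return cols


@dataclass
class FeatureMatrix:
    """Subjects × named-features table with the binary label vector."""

    data: pd.DataFrame  # index: subject_id, columns: feature names
    y: np.ndarray  # 1 = disease class
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.data) != len(self.y):
            raise SpecError("label vector length must match row count")
        if self.data.columns.duplicated().any():
            raise SpecError("feature names must be unique")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def replace_values(self, values: np.ndarray) -> "FeatureMatrix":
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return FeatureMatrix(df, self.y.copy(), dict(self.provenance))

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "label", np.where(self.y == 1, "pd", "control"))
        df.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        if "label" not in df.columns:
            raise SpecError("feature CSV lacks a label column")
        y = (df.pop("label") == "pd").to_numpy(dtype=int)
        return cls(df, y)


def extract_feature_matrix(cohort: Cohort) -> FeatureMatrix:
    """Extract the full feature table for a cohort.

    Columns are ordered channel-major, band-minor, temporal before
    spectral; 12 features per (channel, band), i.e. 792 columns for the
    default 22-channel layout.  Channels flagged as not retained are
    filled with the cohort column median (column of zeros if a channel
    is pruned for every subject) so the layout is identical across
    subjects; filled cells are listed in ``provenance['median_filled']``.
    """
    if len(cohort) == 0:
        raise SpecError("cohort is empty")
    n_ch = cohort.records[0].n_channels
    fs = cohort.records[0].fs
    for rec in cohort.records:
        if rec.n_channels != n_ch or rec.fs != fs:
            raise SpecError(
                f"subject {rec.subject_id}: inconsistent channel layout or rate"
            )
    cols = feature_columns(n_ch)
    rows = np.full((len(cohort), len(cols)), np.nan)
    filled: list[tuple[str, int]] = []
    for i, rec in enumerate(cohort.records):
        j = 0
        for c in range(n_ch):
            retained = rec.channel_meta[c].retained
            for b in range(len(BANDS)):
                if retained:
                    feats = band_features(rec.data[b, c], fs)
                    for name in TEMPORAL_NAMES:
                        rows[i, j] = feats[f"t_{name}"]
                        j += 1
                    for name in SPECTRAL_NAMES:
                        rows[i, j] = feats[f"s_{name}"]
                        j += 1
                else:
                    j += N_FEATURES_PER_BAND
            if not retained:
                filled.append((rec.subject_id, c))
    # median-fill pruned channels from retained subjects, column-wise
    col_median = np.nanmedian(
        np.where(np.isfinite(rows), rows, np.nan), axis=0
    )
    col_median = np.where(np.isfinite(col_median), col_median, 0.0)
    nan_mask = ~np.isfinite(rows)
    rows[nan_mask] = np.broadcast_to(col_median, rows.shape)[nan_mask]
    df = pd.DataFrame(rows, index=pd.Index(cohort.subject_ids, name="subject_id"),
                      columns=cols)
    return FeatureMatrix(df, cohort.labels, {"median_filled": filled})


def feature_dictionary() -> dict[str, str]:
    """Name → definition map for the emitted features (units noted)."""
    t = {
        "max_abs": "maximum absolute amplitude of the trace (µM)",
        "mean": "arithmetic mean of the trace (µM)",
        "variance": "population variance, divide-by-N (µM²)",
        "skewness": "population skewness m3/m2^1.5 of the trace",
        "zc_interval": "mean time between consecutive zero crossings of the "
        "mean-removed trace (s); record duration if fewer than two crossings",
        "zc_to_peak": "mean time from a zero crossing to the next local "
        "extremum of the mean-removed trace (s)",
    }
    s = {
        "mean": "mean of the one-sided DFT magnitude spectrum (DC excluded)",
        "variance": "population variance of the magnitude values",
        "skewness": "population skewness of the magnitude values",
        "kurtosis": "population kurtosis (non-excess) of the magnitude values",
        "energy": "sum of squared magnitudes; equals time-domain energy of "
        "the mean-removed trace under the 1/sqrt(N) normalisation",
        "dominant_freq": "frequency (Hz) of the maximum-magnitude bin",
    }
    out = {}
    for name, desc in t.items():
        out[f"t_{name}"] = desc
    for name, desc in s.items():
        out[f"s_{name}"] = desc
    return out


def write_feature_dictionary(path) -> None:
    Path(path).write_text(json.dumps(feature_dictionary(), indent=2))
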