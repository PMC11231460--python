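"""Two-class synthetic resting-state fNIRS cohort generator.

Emulates the recording geometry of a 22-channel (20 long + 2 short
source–detector separations) continuous-wave system sampling oxy-,
deoxy- and total haemoglobin concentration changes at 25 Hz for six
minutes per subject.  Each channel is a superposition of the standard
spontaneous haemodynamic oscillations — cardiac pulsation (~1.1 Hz),
respiration (~0.25 Hz), Mayer waves (~0.1 Hz) and a slow vascular drift
— plus white measurement noise, with optional transient motion
artifacts.  A disease-class effect can be planted on a chosen subset of
long channels: the Mayer-wave amplitude is scaled and its centre
frequency shifted for affected subjects, so that both temporal and
spectral feature families become discriminative.

Signals are generated directly as concentration changes in µM; HbT is
HbO + HbR by construction.  Short channels carry only superficial
(systemic) oscillations and never the class effect.

Reproducibility: one root seed per cohort; subject *i* draws from the
i-th child of ``numpy.random.SeedSequence(seed)``, so appending
subjects never perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AliasingError, CohortFormatError, SpecError

BANDS = ("hbo", "hbr", "hbt")

# Fraction by which one unit of effect_size scales the Mayer-wave
# amplitude / shifts its centre frequency (Hz) on affected channels.
EFFECT_AMP_PER_UNIT = 0.5
EFFECT_FREQ_HZ_PER_UNIT = 0.01


@dataclass(frozen=True)
class OscillatoryComponent:
    """One sinusoidal constituent of the haemodynamic signal model."""

    name: str
    freq_hz: float
    amplitude_um: float
    phase_jitter: float = 1.0  # fraction of a full cycle randomised per channel
    superficial: bool = True  # present in short (scalp) channels
    class_sensitive: bool = False  # carries the planted disease effect


@dataclass(frozen=True)
class SignalModel:
    """Amplitudes, frequencies and artifact rates of the generative model.

    Defaults place the Mayer wave as the largest-amplitude component so
    the dominant spectral peak of every channel is the 0.1 Hz band, as
    is typical of eyes-closed resting recordings.
    """

    components: tuple[OscillatoryComponent, ...] = (
        OscillatoryComponent("cardiac", 1.1, 0.25),
        OscillatoryComponent("respiratory", 0.25, 0.40),
        OscillatoryComponent("mayer", 0.10, 1.00, class_sensitive=True),
        OscillatoryComponent("drift", 0.008, 0.60, superficial=False),
    )
    hbr_ratio: float = 1.0 / 3.0  # |HbR| oscillation amplitude relative to HbO
    spikes_per_min: float = 0.0
    shifts_per_min: float = 0.0

    def validate(self, fs: float) -> None:
        if self.spikes_per_min < 0 or self.shifts_per_min < 0:
            raise SpecError("artifact rates must be non-negative")
        for c in self.components:
            if c.freq_hz >= fs / 2:
                raise AliasingError(
                    f"component {c.name!r} at {c.freq_hz} Hz is not below "
                    f"the Nyquist frequency {fs / 2} Hz"
                )

    def dominant_component(self) -> OscillatoryComponent:
        return max(self.components, key=lambda c: c.amplitude_um)


@dataclass(frozen=True)
class CohortSpec:
    """Size, geometry and class-effect parameters of a synthetic cohort."""

    n_per_class: int = 20
    n_long_channels: int = 20
    n_short_channels: int = 2
    fs: float = 25.0
    duration_s: float = 360.0
    effect_channels: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 1.0
    noise_sd: float = 0.10  # µM, white, per chromophore
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.n_long_channels + self.n_short_channels

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise SpecError("n_per_class must be >= 1")
        if self.n_long_channels < 1 or self.n_short_channels < 0:
            raise SpecError("channel counts invalid")
        if self.duration_s <= 0 or self.fs <= 0:
            raise SpecError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise SpecError("duration_s * fs must be a whole number of samples")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        bad = [c for c in self.effect_channels if not 0 <= c < self.n_channels]
        if bad:
            raise SpecError(f"effect_channels out of range: {bad}")


@dataclass(frozen=True)
class ChannelMeta:
    source: str
    detector: str
    kind: str  # "long" | "short"
    retained: bool = True


@dataclass
class FNIRSRecord:
    """One subject's (band × channel × time) concentration-change array."""

    subject_id: str
    data: np.ndarray  # shape (3, n_channels, n_samples), µM; bands per BANDS
    fs: float
    channel_meta: list[ChannelMeta]
    label: str  # "pd" | "control"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(BANDS):
            raise SpecError("record data must have shape (3, channels, samples)")
        if self.data.shape[1] != len(self.channel_meta):
            raise SpecError("channel_meta length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        return self.data[BANDS.index(name)]

    def copy(self) -> "FNIRSRecord":
        return FNIRSRecord(
            self.subject_id,
            self.data.copy(),
            self.fs,
            [replace(m) for m in self.channel_meta],
            self.label,
        )


@dataclass
class Cohort:
    records: list[FNIRSRecord]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        """Binary label vector, 1 for the disease class."""
        return np.array([1 if r.label == "pd" else 0 for r in self.records])

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]


def _default_channel_meta(spec: CohortSpec) -> list[ChannelMeta]:
    meta = []
    for i in range(spec.n_long_channels):
        meta.append(ChannelMeta(f"S{i // 2 + 1}", f"D{i % 8 + 1}", "long"))
    for j in range(spec.n_short_channels):
        meta.append(ChannelMeta(f"S{j + 1}", f"D{j + 1}s", "short"))
    return meta


def generate_record(
    spec: CohortSpec,
    model: SignalModel,
    label: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> FNIRSRecord:
    """Synthesize one subject's three-band multichannel recording.

    Long channels receive every model component; short channels only the
    superficial (systemic) ones plus noise.  For a ``"pd"`` subject the
    class-sensitive component on ``spec.effect_channels`` has its
    amplitude scaled by ``1 + 0.5·effect_size`` and its frequency shifted
    by ``0.01·effect_size`` Hz.  HbR oscillations mirror HbO with
    opposite sign at ``hbr_ratio`` amplitude; HbT = HbO + HbR exactly.
    """
    spec.validate()
    model.validate(spec.fs)
    if label not in ("pd", "control"):
        raise SpecError(f"label must be 'pd' or 'control', got {label!r}")

    n_ch, n_t = spec.n_channels, spec.n_samples
    t = np.arange(n_t) / spec.fs
    hbo = np.zeros((n_ch, n_t))
    hbr = np.zeros((n_ch, n_t))
    effect = set(spec.effect_channels)

    for ch in range(n_ch):
        is_short = ch >= spec.n_long_channels
        for comp in model.components:
            if is_short and not comp.superficial:
                continue
            amp = comp.amplitude_um * rng.uniform(0.8, 1.2)
            freq = comp.freq_hz
            if (
                comp.class_sensitive
                and label == "pd"
                and ch in effect
                and not is_short
            ):
                amp *= 1.0 + EFFECT_AMP_PER_UNIT * spec.effect_size
                freq += EFFECT_FREQ_HZ_PER_UNIT * spec.effect_size
            phase = 2 * np.pi * comp.phase_jitter * rng.random()
            wave = np.sin(2 * np.pi * freq * t + phase)
            hbo[ch] += amp * wave
            hbr[ch] += -model.hbr_ratio * amp * wave
        hbo[ch] += rng.normal(0.0, spec.noise_sd, n_t)
        hbr[ch] += rng.normal(0.0, spec.noise_sd * model.hbr_ratio, n_t)

    data = np.stack([hbo, hbr, hbo + hbr])
    return FNIRSRecord(subject_id, data, spec.fs, _default_channel_meta(spec), label)


def generate_cohort(spec: CohortSpec, model: SignalModel | None = None) -> Cohort:
    """Generate a balanced two-class cohort of 2·n_per_class records.

    Disease-class subjects come first.  Subject *i* uses the *i*-th
    spawned child of the root seed sequence, making the cohort
    bit-reproducible and extension-stable.
    """
    spec.validate()
    model = model or SignalModel()
    n = 2 * spec.n_per_class
    children = np.random.SeedSequence(spec.seed).spawn(n)
    records = []
    for i in range(n):
        label = "pd" if i < spec.n_per_class else "control"
        rng = np.random.default_rng(children[i])
        records.append(
            generate_record(spec, model, label, rng, subject_id=f"sub-{i:03d}")
        )
    return Cohort(records)


@dataclass(frozen=True)
class ArtifactEvent:
    """Ground truth for one injected artifact."""

    channel: int
    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    kind: str  # "spike" | "shift"


def inject_artifacts(
    record: FNIRSRecord,
    rng: np.random.Generator,
    spikes_per_min: float = 1.0,
    shifts_per_min: float = 0.0,
    spike_amplitude_um: float = 10.0,
    spike_width_s: float = 0.4,
    shift_amplitude_um: float = 5.0,
) -> tuple[FNIRSRecord, list[ArtifactEvent]]:
    """Add motion-like transients and return them as ground truth.

    Spikes are Gaussian-shaped bumps of the given peak amplitude; shifts
    are step changes in baseline.  Counts are ``round(rate · minutes)``
    so a requested rate maps to a deterministic event count.  Both
    chromophores are perturbed (HbR at the model-typical 1/3 ratio) and
    HbT is recomputed, preserving the additivity invariant.
    """
    if spikes_per_min < 0 or shifts_per_min < 0:
        raise SpecError("artifact rates must be non-negative")
    out = record.copy()
    n_t = out.n_samples
    minutes = n_t / record.fs / 60.0
    n_spikes = int(round(spikes_per_min * minutes))
    n_shifts = int(round(shifts_per_min * minutes))
    events: list[ArtifactEvent] = []
    half = max(1, int(round(spike_width_s * record.fs / 2)))

    hbo, hbr = out.data[0], out.data[1]
    for _ in range(n_spikes):
        ch = int(rng.integers(out.n_channels))
        center = int(rng.integers(half, n_t - half))
        idx = np.arange(center - half, center + half + 1)
        bump = spike_amplitude_um * np.exp(
            -0.5 * ((idx - center) / (half / 2.0)) ** 2
        )
        sign = -1.0 if rng.random() < 0.5 else 1.0
        hbo[ch, idx] += sign * bump
        hbr[ch, idx] += sign * bump / 3.0
        events.append(ArtifactEvent(ch, int(idx[0]), int(idx[-1]) + 1, "spike"))
    for _ in range(n_shifts):
        ch = int(rng.integers(out.n_channels))
        start = int(rng.integers(1, n_t - 1))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        hbo[ch, start:] += sign * shift_amplitude_um
        hbr[ch, start:] += sign * shift_amplitude_um / 3.0
        events.append(ArtifactEvent(ch, start, n_t, "shift"))

    out.data[2] = hbo + hbr
    return out, events


# ---------------------------------------------------------------------------
# On-disk format: one CSV per band per subject + one JSON manifest.
# ---------------------------------------------------------------------------


def _channel_columns(n_channels: int) -> list[str]:
    return [f"ch{c + 1:02d}" for c in range(n_channels)]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as diffable CSV time series plus a JSON manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": 1, "bands": list(BANDS), "subjects": []}
    for rec in cohort.records:
        cols = _channel_columns(rec.n_channels)
        t = np.arange(rec.n_samples) / rec.fs
        files = {}
        for b, band in enumerate(BANDS):
            df = pd.DataFrame(rec.data[b].T, columns=cols)
            df.insert(0, "time_s", t)
            fname = f"{rec.subject_id}_{band}.csv"
            df.to_csv(root / fname, index=False)
            files[band] = fname
        manifest["subjects"].append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "fs": rec.fs,
                "files": files,
                "channel_meta": [
                    {
                        "source": m.source,
                        "detector": m.detector,
                        "kind": m.kind,
                        "retained": m.retained,
                    }
                    for m in rec.channel_meta
                ],
            }
        )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortFormatError` naming the offending subject,
    band or channel on any structural defect (missing label, missing
    band file, truncated channel column).
    """
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise CohortFormatError(f"no manifest.json under {root}")
    manifest = json.loads(mpath.read_text())
    records = []
    for sub in manifest.get("subjects", []):
        sid = sub.get("subject_id", "<unknown>")
        if "label" not in sub:
            raise CohortFormatError(f"subject {sid}: missing label in manifest")
        if sub["label"] not in ("pd", "control"):
            raise CohortFormatError(f"subject {sid}: bad label {sub['label']!r}")
        meta = [
            ChannelMeta(m["source"], m["detector"], m["kind"], m.get("retained", True))
            for m in sub["channel_meta"]
        ]
        cols = _channel_columns(len(meta))
        bands = []
        n_rows = None
        for band in BANDS:
            fname = sub.get("files", {}).get(band)
            if fname is None or not (root / fname).exists():
                raise CohortFormatError(f"subject {sid}: missing {band} file")
            df = pd.read_csv(root / fname)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise CohortFormatError(
                    f"subject {sid} band {band}: missing channel columns {missing}"
                )
            block = df[cols].to_numpy(dtype=float).T
            bad = np.where(~np.isfinite(block))
            if bad[0].size:
                raise CohortFormatError(
                    f"subject {sid} band {band}: non-finite/truncated data in "
                    f"channel {cols[bad[0][0]]}"
                )
            if n_rows is None:
                n_rows = block.shape[1]
            elif block.shape[1] != n_rows:
                raise CohortFormatError(
                    f"subject {sid} band {band}: {block.shape[1]} samples, "
                    f"expected {n_rows}"
                )
            bands.append(block)
        records.append(
            FNIRSRecord(sid, np.stack(bands), float(sub["fs"]), meta, sub["label"])
        )
    return Cohort(records)
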