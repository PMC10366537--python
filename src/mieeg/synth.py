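"""Synthetic class-conditioned EEG generator.

Emulates the structure of a 22-channel, 250 Hz motor-imagery recording:
each 3-second segment is a sum of 1/f^gamma background noise and five
band-limited oscillations (delta..gamma) built by spectrally filtering
white noise, so each band has realistic within-band variance.  The class
effect is an event-related-desynchronisation-like amplitude attenuation:
on each class's designated channels, the affected band's oscillation
amplitude is scaled by (1 - effect_size).  With effect_size = 0 the
labels carry no signal (the null mode).

Randomness is drawn from a per-segment substream seeded by
(seed, segment_index), so a dataset is bit-reproducible regardless of
generation order.

The module also exposes the trial-design bookkeeping of the reference
recording protocol (9 subjects x 6 runs x 48 trials, 12 per class),
whose four-class and two-class sample counts (2,592 and 1,296) fix the
shape of the full feature matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BANDS,
    BandDefinition,
    EEGSegment,
    SegmentSet,
    ValidationError,
)

__all__ = [
    "SynthParams", "generate_dataset", "generate_null_dataset",
    "write_dataset", "trial_design", "trial_design_counts",
    "DEFAULT_CLASS_NAMES", "DEFAULT_BAND_AMPLITUDES",
]

DEFAULT_CLASS_NAMES: tuple[str, ...] = ("LH", "RH", "F", "T")

#: Baseline oscillation amplitude per band (arbitrary units ~ uV RMS).
#: Alpha is the strongest rhythm at rest, gamma the weakest — the usual
#: shape of a resting EEG spectrum on sensorimotor channels.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 1.5, "theta": 1.0, "alpha": 2.0, "beta": 1.0, "gamma": 0.4,
}

_BACKGROUND_AMPLITUDE = 2.0   # RMS of the 1/f background
_AMPLITUDE_JITTER_SD = 0.1    # lognormal trial-to-trial amplitude variability


def default_affected_channels(
    class_names: tuple[str, ...], n_channels: int
) -> dict[str, tuple[int, ...]]:
    """Assign each class a disjoint block of 3 channels, spread over the montage."""
    n_classes = len(class_names)
    block = 3 if 3 * n_classes <= n_channels else max(1, n_channels // n_classes)
    stride = max(block, n_channels // n_classes)
    out: dict[str, tuple[int, ...]] = {}
    for i, name in enumerate(class_names):
        start = (i * stride) % n_channels
        out[name] = tuple((start + j) % n_channels for j in range(block))
    return out


@dataclass
class SynthParams:
    """Generator settings; defaults mirror the reference recording format."""

    n_channels: int = 22
    fs: float = 250.0
    duration_s: float = 3.0
    n_per_class: int = 10
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    effect_size: float = 0.5
    affected_channels: dict[str, tuple[int, ...]] | None = None
    affected_band: str = "alpha"
    noise_exponent: float = 1.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValidationError("effect_size must lie in [0, 1]")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("duration_s * fs must be an integer sample count")
        if self.affected_channels is None:
            self.affected_channels = default_affected_channels(
                self.class_names, self.n_channels
            )
        for cls, chans in self.affected_channels.items():
            if any(not 0 <= c < self.n_channels for c in chans):
                raise ValidationError(
                    f"affected channel index out of range for class {cls!r}"
                )
        if self.affected_band not in {b.name for b in self.bands}:
            raise ValidationError(f"unknown affected band {self.affected_band!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(f"ch{i + 1:02d}" for i in range(self.n_channels))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^gamma noise via spectral shaping, unit RMS."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    shape = np.zeros(n_bins)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: BandDefinition
) -> np.ndarray:
    """Band-limited random-phase noise, unit RMS (white noise filtered to the band)."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.low_hz) & (freqs < min(band.high_hz, fs / 2))
    spec = np.zeros(n_bins, dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _make_segment(params: SynthParams, label: str, segment_index: int) -> EEGSegment:
    rng = np.random.default_rng([params.seed, segment_index])
    n = params.n_samples
    affected = set(params.affected_channels.get(label, ()))
    data = np.empty((params.n_channels, n))
    for ch in range(params.n_channels):
        x = _BACKGROUND_AMPLITUDE * _pink_noise(rng, n, params.fs, params.noise_exponent)
        for band in params.bands:
            amp = params.band_amplitudes.get(band.name, 0.0)
            if amp == 0.0:
                continue
            amp *= float(np.exp(_AMPLITUDE_JITTER_SD * rng.standard_normal()))
            if band.name == params.affected_band and ch in affected:
                amp *= 1.0 - params.effect_size
            x = x + amp * _narrowband_noise(rng, n, params.fs, band)
        data[ch] = x
    return EEGSegment(data, params.fs, params.channel_labels, label=label)


def generate_dataset(params: SynthParams) -> SegmentSet:
    """n_per_class segments per class, class-major order, seed-deterministic."""
    segments = []
    idx = 0
    for label in params.class_names:
        for _ in range(params.n_per_class):
            segments.append(_make_segment(params, label, idx))
            idx += 1
    return SegmentSet(segments, class_names=params.class_names)


def generate_null_dataset(params: SynthParams) -> SegmentSet:
    """Same generative process with the class effect forced to zero."""
    return generate_dataset(dataclasses.replace(params, effect_size=0.0))


def write_dataset(segset: SegmentSet, out_dir: str | Path) -> Path:
    """Write matrix-format CSV files plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, seg in enumerate(segset):
        fname = f"segment_{i:04d}.csv"
        np.savetxt(out / fname, seg.data, delimiter=",")
        records.append(
            {"file": fname, "label": seg.label, "subject": seg.subject_id or "S1",
             "fs": seg.fs}
        )
    manifest = out / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Trial-design bookkeeping
# ---------------------------------------------------------------------------

def trial_design(
    n_subjects: int = 9,
    n_runs: int = 6,
    trials_per_class_per_run: int = 12,
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES,
) -> pd.DataFrame:
    """One row per trial of the reference protocol: subject, run, trial, label.

    The defaults (9 subjects, 6 runs of 48 trials, 12 per class) give
    2,592 four-class trials; restricting to the two hand classes gives 1,296.
    """
    rows = []
    for s in range(1, n_subjects + 1):
        for r in range(1, n_runs + 1):
            t = 0
            for label in class_names:
                for _ in range(trials_per_class_per_run):
                    rows.append(
                        {"subject": f"S{s}", "run": r, "trial": t, "label": label}
                    )
                    t += 1
    return pd.DataFrame(rows)


def trial_design_counts(
    binary_classes: tuple[str, str] = ("LH", "RH"), **kwargs
) -> tuple[int, int]:
    """(four-class sample count, two-class sample count) of the protocol."""
    design = trial_design(**kwargs)
    n_all = len(design)
    n_binary = int(design["label"].isin(binary_classes).sum())
    return n_all, n_binary
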