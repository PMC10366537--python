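"""Domain types, I/O, feature naming, and run configuration.

The package analyses multichannel motor-imagery EEG trials ("segments"):
fixed-length channels x samples matrices with a sampling rate, channel
labels and a class label (the imagined movement).  Everything downstream
— feature extraction, significance screening, classification — consumes
the types defined here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MieegError(Exception):
    """Base class for all package errors."""


class ValidationError(MieegError, ValueError):
    """Input violates a documented precondition or invariant."""


class StructuralError(MieegError, ValueError):
    """Segments in a set disagree on sampling rate, channel count or order."""


class LoadError(MieegError, IOError):
    """A referenced signal or manifest file could not be read."""


class FormatError(MieegError, ValueError):
    """An on-disk table does not conform to the expected layout."""


# ---------------------------------------------------------------------------
# Band definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A canonical EEG frequency band, half-open interval [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValidationError(
                f"band {self.name!r}: low_hz {self.low_hz} must be < high_hz {self.high_hz}"
            )

    def contains(self, freq_hz: float) -> bool:
        return self.low_hz <= freq_hz < self.high_hz


#: The five canonical EEG bands: delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


def validate_bands(bands: Sequence[BandDefinition]) -> None:
    """Check bands are valid and pairwise non-overlapping as [low, high)."""
    ordered = sorted(bands, key=lambda b: b.low_hz)
    for a, b in zip(ordered, ordered[1:]):
        if b.low_hz < a.high_hz:
            raise ValidationError(f"bands {a.name!r} and {b.name!r} overlap")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable knobs of the pipeline, serialisable to/from JSON.

    Defaults reproduce the reference analysis: five canonical bands,
    7-level Haar wavelet-packet decomposition, Poincare lags 1 and 9,
    per-feature significance screening at alpha = 0.05, and 10 repeats
    of stratified 5-fold cross-validation.
    """

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    wavelet_level: int = 7
    wavelet_name: str = "haar"
    wavelet_transform: str = "wpd"          # "wpd" (packet tree) or "dwt"
    wavelet_literal_entropy: bool = False   # unnormalised sum(d^2 log d^2) variant
    poincare_lags: tuple[int, ...] = (1, 9)
    fft_window: str = "none"                # "none" or "hann"
    alpha: float = 0.05
    ttest_variant: str = "pooled"           # "pooled" or "welch"
    selection_correction: str | None = None  # None or "bh"
    leakage_free_selection: bool = False    # refit the screen inside each CV fold
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelet_level < 1:
            raise ValidationError("wavelet_level must be >= 1")
        if any(lag < 1 for lag in self.poincare_lags):
            raise ValidationError("all poincare lags must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if self.wavelet_transform not in ("wpd", "dwt"):
            raise ValidationError("wavelet_transform must be 'wpd' or 'dwt'")
        if self.ttest_variant not in ("pooled", "welch"):
            raise ValidationError("ttest_variant must be 'pooled' or 'welch'")
        self.bands = tuple(self.bands)
        self.poincare_lags = tuple(self.poincare_lags)
        validate_bands(self.bands)

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if "bands" in d:
            d["bands"] = tuple(BandDefinition(**b) for b in d["bands"])
        if "poincare_lags" in d:
            d["poincare_lags"] = tuple(d["poincare_lags"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

@dataclass
class EEGSegment:
    """One trial: a channels x samples matrix plus metadata.

    Amplitudes are in arbitrary units (conventionally microvolts).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("segment data must be a 2-D channels x samples matrix")
        n_ch, n_samp = self.data.shape
        if n_ch < 1 or n_samp < 2:
            raise ValidationError("segment needs >= 1 channel and >= 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("segment contains non-finite samples")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != n_ch:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentSet:
    """An ordered collection of segments sharing fs and channel layout."""

    segments: list[EEGSegment]
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.segments = list(self.segments)
        if self.segments:
            first = self.segments[0]
            for i, seg in enumerate(self.segments):
                if seg.fs != first.fs:
                    raise StructuralError(
                        f"segment {i}: fs {seg.fs} differs from {first.fs}"
                    )
                if seg.channel_labels != first.channel_labels:
                    raise StructuralError(
                        f"segment {i}: channel layout differs from the first segment"
                    )
        if not self.class_names:
            seen: dict[str, None] = {}
            for seg in self.segments:
                if seg.label is not None:
                    seen.setdefault(seg.label, None)
            self.class_names = tuple(seen)
        else:
            self.class_names = tuple(self.class_names)
            known = set(self.class_names)
            for i, seg in enumerate(self.segments):
                if seg.label is not None and seg.label not in known:
                    raise ValidationError(
                        f"segment {i}: label {seg.label!r} not in class_names"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i: int) -> EEGSegment:
        return self.segments[i]

    @property
    def labels(self) -> list[str | None]:
        return [seg.label for seg in self.segments]


# ---------------------------------------------------------------------------
# Feature containers and naming
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """A named feature row for one segment."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.names = tuple(self.names)
        if len(self.values) != len(self.names):
            raise ValidationError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """Segments x features table with per-row class labels."""

    values: np.ndarray
    names: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.names))
        self.names = tuple(self.names)
        self.labels = tuple(self.labels)
        if self.values.shape[1] != len(self.names):
            raise ValidationError(
                f"{self.values.shape[1]} columns but {len(self.names)} names"
            )
        if self.values.shape[0] != len(self.labels):
            raise ValidationError(
                f"{self.values.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df["label"] = list(self.labels)
        return df

    def select_columns(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValidationError("mask length must equal feature count")
        names = tuple(n for n, m in zip(self.names, mask) if m)
        return FeatureMatrix(self.values[:, mask], names, self.labels)


#: Family order within each channel block.
FAMILY_ORDER: tuple[str, ...] = ("time", "fft", "wpd", "poincare")

#: The 24 time-domain feature names, in canonical order.
TEMPORAL_FEATURE_NAMES: tuple[str, ...] = (
    "min", "max", "mean", "sd", "ieeg", "mav", "ssi", "variance", "rms",
    "wl", "aac", "dasdv", "mode", "kurtosis", "skewness",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "q1", "q2", "q3", "zero_crossings", "slope_sign_changes", "range",
)

#: Per-band spectral statistics, shared by the FFT and wavelet families.
BAND_STAT_NAMES: tuple[str, ...] = ("energy", "variance", "entropy")

#: Per-lag Poincare descriptor names.
POINCARE_STAT_NAMES: tuple[str, ...] = ("SD1", "SD2", "SD1xSD2", "SD1_SD2_ratio")


def family_feature_names(config: RunConfig) -> dict[str, tuple[str, ...]]:
    """Per-family feature names for a single channel (no channel prefix)."""
    band_stats = tuple(
        f"{band.name}_{stat}" for band in config.bands for stat in BAND_STAT_NAMES
    )
    poinc = tuple(
        f"lag{m}_{stat}" for m in config.poincare_lags for stat in POINCARE_STAT_NAMES
    )
    return {
        "time": TEMPORAL_FEATURE_NAMES,
        "fft": band_stats,
        "wpd": band_stats,
        "poincare": poinc,
    }


def feature_names(channel_labels: Sequence[str], config: RunConfig | None = None) -> list[str]:
    """Deterministic column layout: channel-major, families in fixed order.

    For 22 channels and the default configuration this yields exactly
    22 x (24 + 15 + 15 + 8) = 1,364 names of the form
    ``<channel>__<family>__<feature>``.
    """
    if config is None:
        config = RunConfig()
    channel_labels = list(channel_labels)
    if len(set(channel_labels)) != len(channel_labels):
        raise ValidationError("channel labels must be unique")
    per_family = family_feature_names(config)
    names: list[str] = []
    for ch in channel_labels:
        for family in FAMILY_ORDER:
            names.extend(f"{ch}__{family}__{feat}" for feat in per_family[family])
    return names


# ---------------------------------------------------------------------------
# Segment loading
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("file", "label", "subject")


def _read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    path = Path(manifest_path)
    if not path.exists():
        raise LoadError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    return df


def _load_matrix_segment(path: Path, fs: float, label: str, subject: str) -> EEGSegment:
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except OSError as exc:
        raise LoadError(f"cannot read signal file: {path}") from exc
    except ValueError as exc:
        raise FormatError(f"non-numeric content in {path}") from exc
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"non-finite samples in {path}")
    labels = tuple(f"ch{i + 1:02d}" for i in range(data.shape[0]))
    return EEGSegment(data, fs, labels, label=label, subject_id=subject)


def _load_edf_segment(
    path: Path, label: str, subject: str, channel_labels: Sequence[str] | None
) -> EEGSegment:
    try:
        import mne  # heavy import, deferred
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise LoadError("EDF support requires the 'mne' package") from exc
    if not path.exists():
        raise LoadError(f"signal file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    names = list(raw.ch_names)
    if channel_labels is not None:
        unknown = [c for c in channel_labels if c not in names]
        if unknown:
            raise ValidationError(f"unknown EDF channels requested: {unknown}")
        idx = [names.index(c) for c in channel_labels]
        data = data[idx]
        names = list(channel_labels)
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"non-finite samples in {path}")
    return EEGSegment(data, float(raw.info["sfreq"]), tuple(names), label, subject)


def load_segments(
    manifest_path: str | Path,
    format: str = "matrix",
    channel_labels: Sequence[str] | None = None,
) -> SegmentSet:
    """Load a SegmentSet from a manifest CSV.

    The manifest has columns ``file,label,subject`` plus ``fs`` for the
    matrix format (Hz; EDF carries its own rate).  Matrix files are plain
    CSV channels x samples with no header.  Relative file paths resolve
    against the manifest's directory.  Channel order is taken from the
    first segment and enforced on all.
    """
    if format not in ("matrix", "edf"):
        raise ValidationError(f"unknown segment format: {format!r}")
    manifest = _read_manifest(manifest_path)
    base = Path(manifest_path).parent
    segments: list[EEGSegment] = []
    for _, rec in manifest.iterrows():
        fpath = Path(rec["file"])
        if not fpath.is_absolute():
            fpath = base / fpath
        if format == "matrix":
            if "fs" not in manifest.columns or pd.isna(rec.get("fs")):
                raise FormatError("matrix manifests require an 'fs' column")
            if not fpath.exists():
                raise LoadError(f"signal file not found: {fpath}")
            seg = _load_matrix_segment(
                fpath, float(rec["fs"]), str(rec["label"]), str(rec["subject"])
            )
        else:
            seg = _load_edf_segment(
                fpath, str(rec["label"]), str(rec["subject"]), channel_labels
            )
        segments.append(seg)
    return SegmentSet(segments)


# ---------------------------------------------------------------------------
# Feature-table persistence
# ---------------------------------------------------------------------------

def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: feature-name header, trailing label column."""
    df = fm.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature table written by :func:`write_feature_table`."""
    p = Path(path)
    if not p.exists():
        raise LoadError(f"feature table not found: {p}")
    df = pd.read_csv(p)
    if df.shape[1] < 1 or df.columns[-1] != "label":
        raise FormatError(f"feature table {p} must end with a 'label' column")
    names = tuple(df.columns[:-1])
    values = df.iloc[:, :-1].to_numpy(dtype=float).reshape(len(df), len(names))
    labels = tuple(str(v) for v in df["label"])
    return FeatureMatrix(values, names, labels)


def expect_feature_table(path: str | Path, names: Iterable[str]) -> FeatureMatrix:
    """Read a table and require an exact column-name match."""
    fm = read_feature_table(path)
    expected = tuple(names)
    if fm.names != expected:
        raise FormatError(f"feature table {path} columns do not match expected layout")
    return fm
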