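"""Time-domain descriptors of a single-channel EEG segment.

Twenty-four amplitude and shape statistics per channel: order statistics
(min, max, quartiles, range), moments (mean, SD, variance, skewness,
non-excess kurtosis), rectified-amplitude measures from the EMG feature
literature (IEEG, MAV, SSI, RMS), successive-difference measures (waveform
length, average amplitude change, DASDV), a discretised mode, the three
Hjorth parameters, and the zero-crossing / slope-sign-change counts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import TEMPORAL_FEATURE_NAMES, ValidationError

__all__ = ["temporal_features", "temporal_feature_matrix", "hjorth",
           "TEMPORAL_FEATURE_NAMES"]


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x), with first differences standing
    in for derivatives (the sampling interval cancels in the ratios).
    Zero-variance input yields (0, 0, 0) by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("hjorth needs at least 3 samples")
    var0 = float(np.var(x, ddof=1))
    if var0 == 0.0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var1 = float(np.var(d1, ddof=1))
    mobility = float(np.sqrt(var1 / var0))
    if var1 == 0.0 or d2.size < 2:  # N=3: a single second difference
        return var0, mobility, 0.0
    var2 = float(np.var(d2, ddof=1))
    mobility_d = float(np.sqrt(var2 / var1))
    return var0, mobility, mobility_d / mobility if mobility > 0 else 0.0


def _mode(x: np.ndarray, decimals: int = 2) -> float:
    # continuous data has no repeats; discretise, then smallest-most-frequent
    rounded = np.round(x, decimals)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])  # np.unique sorts: ties -> smallest


def temporal_features(x: np.ndarray) -> dict[str, float]:
    """All 24 time-domain features of one channel, keyed by canonical name."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("temporal_features expects a 1-D signal")
    n = x.size
    if n < 3:
        raise ValidationError("temporal features need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("temporal features require finite input")

    diffs = np.diff(x)
    ieeg = float(np.sum(np.abs(x)))
    ssi = float(np.sum(x * x))
    wl = float(np.sum(np.abs(diffs)))
    variance = float(np.var(x, ddof=1))
    sd = float(np.sqrt(variance))
    q1, q2, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    activity, mobility, complexity = hjorth(x)
    zc = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    ssc = int(np.count_nonzero(diffs[:-1] * diffs[1:] < 0))

    out = {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "sd": sd,
        "ieeg": ieeg,
        "mav": ieeg / n,
        "ssi": ssi,
        "variance": variance,
        "rms": float(np.sqrt(ssi / n)),
        "wl": wl,
        "aac": wl / (n - 1),
        "dasdv": float(np.sqrt(np.sum(diffs * diffs) / (n - 1))),
        "mode": _mode(x),
        "kurtosis": float(stats.kurtosis(x, fisher=False, bias=True)),
        "skewness": float(stats.skew(x, bias=True)),
        "hjorth_activity": activity,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "q1": q1,
        "q2": q2,
        "q3": q3,
        "zero_crossings": float(zc),
        "slope_sign_changes": float(ssc),
        "range": float(np.max(x) - np.min(x)),
    }
    return out


def temporal_feature_matrix(data: np.ndarray) -> np.ndarray:
    """Channels x 24 feature matrix; rows follow TEMPORAL_FEATURE_NAMES order."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rows = [temporal_features(ch) for ch in data]
    return np.array([[r[name] for name in TEMPORAL_FEATURE_NAMES] for r in rows])
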