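"""Lagged Poincare plot descriptors.

A Poincare plot scatters each sample x_i against its m-lagged successor
x_{i+m}.  Rotating the cloud by 45 degrees gives
x_a = (x_{i+m} - x_i)/sqrt(2) and x_b = (x_{i+m} + x_i)/sqrt(2);
their sample standard deviations SD1 (minor axis, short-term
variability) and SD2 (major axis, longer-term variability) summarise
the cloud's shape.  Per lag the features are SD1, SD2, their product
and their ratio; the defaults use lags 1 and 9, giving 8 features per
channel.  Descriptors are computed on the raw segment amplitudes.
"""

from __future__ import annotations

import numpy as np

from .core import POINCARE_STAT_NAMES, RunConfig, ValidationError

__all__ = ["poincare_sd", "poincare_features", "poincare_feature_matrix"]

_SQRT2 = np.sqrt(2.0)


def poincare_sd(x: np.ndarray, lag: int) -> tuple[float, float]:
    """(SD1, SD2) of the m-lagged Poincare plot, sample (n-1) denominator.

    Needs at least lag + 3 samples so the plot has >= 3 points.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("poincare_sd expects a 1-D signal")
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    if x.size < lag + 3:
        raise ValidationError(
            f"signal length {x.size} too short for lag {lag} (need >= {lag + 3})"
        )
    xi = x[:-lag]
    xl = x[lag:]
    xa = (xl - xi) / _SQRT2
    xb = (xl + xi) / _SQRT2
    return float(np.std(xa, ddof=1)), float(np.std(xb, ddof=1))


def poincare_features(x: np.ndarray, lags: tuple[int, ...] = (1, 9)) -> dict[str, float]:
    """SD1, SD2, SD1*SD2 and SD1/SD2 per lag, keyed ``lag<m>_<stat>``.

    SD2 = 0 makes the ratio 0 by convention, keeping feature rows finite.
    """
    out: dict[str, float] = {}
    for m in lags:
        sd1, sd2 = poincare_sd(x, m)
        out[f"lag{m}_SD1"] = sd1
        out[f"lag{m}_SD2"] = sd2
        out[f"lag{m}_SD1xSD2"] = sd1 * sd2
        out[f"lag{m}_SD1_SD2_ratio"] = sd1 / sd2 if sd2 > 0 else 0.0
    return out


def poincare_feature_matrix(data: np.ndarray, config: RunConfig) -> np.ndarray:
    """Channels x (4 * n_lags) matrix in lag-major POINCARE_STAT_NAMES order."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rows = []
    for ch in data:
        feats = poincare_features(ch, config.poincare_lags)
        rows.append(
            [feats[f"lag{m}_{stat}"] for m in config.poincare_lags
             for stat in POINCARE_STAT_NAMES]
        )
    return np.array(rows)
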