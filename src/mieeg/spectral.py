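"""FFT-based subband energy, variance and spectral entropy.

Each channel is transformed with a one-sided DFT; the bins falling in
each canonical EEG band (half-open intervals, so adjacent bands never
share a bin) contribute three statistics:

* energy:   sum of squared DFT magnitudes over the band's bins,
* variance: sample variance of the in-band DFT magnitudes,
* entropy:  normalised Shannon entropy of the in-band power distribution
  p_k = |Y_k|^2 / energy, scaled by 1/log(M) so it lies in [0, 1]
  (0 for a single spectral line, 1 for a flat in-band spectrum).
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import BandDefinition, RunConfig, ValidationError

__all__ = ["band_bins", "fft_band_features", "spectral_feature_matrix"]


def band_bins(fs: float, n: int, band: BandDefinition) -> np.ndarray:
    """One-sided DFT bin indices k with band.low <= k*fs/n < band.high.

    Raises if the band is narrower than the spectral resolution (no bins).
    """
    if fs <= 0 or n < 2:
        raise ValidationError("band_bins requires fs > 0 and n >= 2")
    if band.high_hz > fs / 2 + 1e-12:
        raise ValidationError(
            f"band {band.name!r} upper edge {band.high_hz} Hz exceeds Nyquist {fs / 2}"
        )
    k = np.arange(n // 2 + 1)
    freqs = k * fs / n
    idx = k[(freqs >= band.low_hz) & (freqs < band.high_hz)]
    if idx.size == 0:
        raise ValidationError(
            f"band {band.name!r} captures no DFT bins at fs={fs}, n={n}"
        )
    return idx


def _one_sided_spectrum(x: np.ndarray, window: str) -> np.ndarray:
    if window == "hann":
        x = x * np.hanning(x.shape[-1])
    elif window != "none":
        raise ValidationError(f"unknown FFT window: {window!r}")
    return np.fft.rfft(x, axis=-1)


def fft_band_features(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...],
    window: str = "none",
) -> dict[str, float]:
    """Energy, variance, entropy per band for one channel.

    Keys are ``<band>_energy``, ``<band>_variance``, ``<band>_entropy``.
    An all-zero band has entropy 0 by convention; a single-bin band has
    variance 0 (with a warning) since a sample variance needs two points.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("fft_band_features expects a 1-D signal")
    spectrum = _one_sided_spectrum(x, window)
    mags = np.abs(spectrum)
    # bands whose power is pure floating-point residue count as silent
    zero_tol = 1e-24 * float(np.sum(mags**2))
    out: dict[str, float] = {}
    for band in bands:
        idx = band_bins(fs, x.size, band)
        m = idx.size
        band_mags = mags[idx]
        power = band_mags**2
        energy = float(np.sum(power))
        if m < 2:
            warnings.warn(f"band {band.name!r} has a single bin; variance set to 0")
            variance = 0.0
        else:
            variance = float(np.var(band_mags, ddof=1))
        if energy > zero_tol and m > 1:
            p = power / energy
            nz = p[p > 0]
            entropy = float(-np.sum(nz * np.log(nz)) / np.log(m))
        else:
            entropy = 0.0
        out[f"{band.name}_energy"] = energy
        out[f"{band.name}_variance"] = variance
        out[f"{band.name}_entropy"] = entropy
    return out


def spectral_feature_matrix(data: np.ndarray, fs: float, config: RunConfig) -> np.ndarray:
    """Channels x (3 * n_bands) matrix; column order follows config.bands,
    with energy, variance, entropy within each band."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rows = []
    for ch in data:
        feats = fft_band_features(ch, fs, config.bands, config.fft_window)
        rows.append(
            [feats[f"{b.name}_{stat}"] for b in config.bands
             for stat in ("energy", "variance", "entropy")]
        )
    return np.array(rows)
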