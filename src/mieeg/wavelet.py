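"""Haar wavelet-packet subband features.

The signal is decomposed with a full wavelet-packet tree (default: Haar,
7 levels).  The 2^level terminal nodes form a uniform filter bank of
width fs / 2^(level+1); after remapping the tree's natural (Paley) order
to frequency order, node n covers [n, n+1) * fs / 2^(level+1) Hz.  Each
canonical EEG band collects the nodes whose centre frequency falls inside
it; the pooled coefficients give the band's energy, Shannon entropy of
the normalised coefficient energies, and sample variance.

Signals whose length is not a multiple of 2^level are zero-padded up to
the next multiple, which adds only zero coefficients under the Haar
filters with periodic boundary handling and keeps the transform
orthonormal (total coefficient energy equals the signal energy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import BandDefinition, RunConfig, ValidationError

__all__ = [
    "WaveletDecomposition", "wpd", "band_node_map", "node_center_frequencies",
    "wavelet_band_features", "wavelet_feature_matrix",
]


@dataclass
class WaveletDecomposition:
    """Terminal-level packet coefficients in frequency order."""

    level: int
    wavelet: str
    fs: float
    #: one coefficient vector per terminal node, index = frequency order
    node_coeffs: list[np.ndarray]

    @property
    def n_nodes(self) -> int:
        return len(self.node_coeffs)

    def total_energy(self) -> float:
        return float(sum(np.sum(c * c) for c in self.node_coeffs))


def _pad_to_multiple(x: np.ndarray, block: int) -> np.ndarray:
    rem = x.size % block
    if rem == 0:
        return x
    return np.concatenate([x, np.zeros(block - rem)])


def wpd(x: np.ndarray, level: int, wavelet: str = "haar", fs: float = 1.0) -> WaveletDecomposition:
    """Full wavelet-packet tree to `level`, terminal nodes frequency-ordered."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("wpd expects a 1-D signal")
    if level < 1:
        raise ValidationError("wavelet level must be >= 1")
    if x.size < 2**level:
        raise ValidationError(
            f"signal length {x.size} is shorter than 2^level = {2**level}"
        )
    padded = _pad_to_multiple(x, 2**level)
    wp = pywt.WaveletPacket(padded, wavelet, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    coeffs = [np.asarray(node.data, dtype=float) for node in nodes]
    return WaveletDecomposition(level, wavelet, fs, coeffs)


def node_center_frequencies(level: int, fs: float) -> np.ndarray:
    """Centre frequency of each frequency-ordered terminal node, in Hz."""
    width = fs / 2 ** (level + 1)
    return (np.arange(2**level) + 0.5) * width


def band_node_map(
    level: int, fs: float, bands: tuple[BandDefinition, ...]
) -> dict[str, list[int]]:
    """Assign each terminal node to the band containing its centre frequency.

    Nodes whose centre lies outside every band (e.g. 100-125 Hz content at
    the defaults) are left unassigned.  One exception: the DC node (node 0)
    joins the lowest band whenever its span overlaps it, even though its
    centre sits just below the band edge — it carries the segment mean and
    slow drift, which belong with the slowest rhythm rather than nowhere.
    A band capturing no nodes is an error: its features would be undefined.
    """
    if level < 1:
        raise ValidationError("wavelet level must be >= 1")
    centers = node_center_frequencies(level, fs)
    width = fs / 2 ** (level + 1)
    mapping: dict[str, list[int]] = {band.name: [] for band in bands}
    lowest = min(bands, key=lambda b: b.low_hz)
    for n, c in enumerate(centers):
        assigned = False
        for band in bands:
            if band.contains(c):
                mapping[band.name].append(n)
                assigned = True
                break
        if not assigned and n == 0 and lowest.low_hz < width:
            mapping[lowest.name].append(0)
    for band in bands:
        if not mapping[band.name]:
            raise ValidationError(
                f"band {band.name!r} captures no wavelet nodes at level {level}, fs={fs}"
            )
    return mapping


def _dwt_band_coeffs(
    x: np.ndarray, level: int, wavelet: str, fs: float,
    bands: tuple[BandDefinition, ...],
) -> dict[str, np.ndarray]:
    """Plain DWT mapping: detail level i covers [fs/2^(i+1), fs/2^i);
    the final approximation covers [0, fs/2^(level+1))."""
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    spans = [(0.0, fs / 2 ** (level + 1))]  # approximation
    spans += [(fs / 2 ** (i + 1), fs / 2**i) for i in range(level, 0, -1)]
    pooled: dict[str, list[np.ndarray]] = {band.name: [] for band in bands}
    for (lo, hi), c in zip(spans, coeffs):
        center = (lo + hi) / 2
        for band in bands:
            if band.contains(center):
                pooled[band.name].append(np.asarray(c, dtype=float))
                break
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if not pooled[band.name]:
            raise ValidationError(
                f"band {band.name!r} captures no DWT coefficient sets at level {level}"
            )
        out[band.name] = np.concatenate(pooled[band.name])
    return out


def _band_stats(c: np.ndarray, literal_entropy: bool) -> tuple[float, float, float]:
    energy = float(np.sum(c * c))
    if literal_entropy:
        sq = c * c
        nz = sq[sq > 0]
        entropy = float(np.sum(nz * np.log(nz)))
    elif energy > 0.0:
        p = c * c / energy
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log(nz)))
    else:
        entropy = 0.0
    variance = float(np.var(c, ddof=1)) if c.size > 1 else 0.0
    return energy, entropy, variance


def wavelet_band_features(x: np.ndarray, config: RunConfig, fs: float) -> dict[str, float]:
    """Per-band (energy, variance, entropy) from pooled subband coefficients.

    Keys are ``<band>_energy``, ``<band>_variance``, ``<band>_entropy``.
    """
    x = np.asarray(x, dtype=float)
    if config.wavelet_transform == "dwt":
        band_coeffs = _dwt_band_coeffs(
            _pad_to_multiple(x, 2**config.wavelet_level),
            config.wavelet_level, config.wavelet_name, fs, config.bands,
        )
    else:
        dec = wpd(x, config.wavelet_level, config.wavelet_name, fs)
        mapping = band_node_map(config.wavelet_level, fs, config.bands)
        band_coeffs = {
            name: np.concatenate([dec.node_coeffs[n] for n in nodes])
            for name, nodes in mapping.items()
        }
    out: dict[str, float] = {}
    for band in config.bands:
        energy, entropy, variance = _band_stats(
            band_coeffs[band.name], config.wavelet_literal_entropy
        )
        out[f"{band.name}_energy"] = energy
        out[f"{band.name}_variance"] = variance
        out[f"{band.name}_entropy"] = entropy
    return out


def wavelet_feature_matrix(data: np.ndarray, fs: float, config: RunConfig) -> np.ndarray:
    """Channels x (3 * n_bands) matrix, band-major energy/variance/entropy."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rows = []
    for ch in data:
        feats = wavelet_band_features(ch, config, fs)
        rows.append(
            [feats[f"{b.name}_{stat}"] for b in config.bands
             for stat in ("energy", "variance", "entropy")]
        )
    return np.array(rows)
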