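"""Assemble the full per-segment feature vector and the dataset matrix.

Per channel: 24 time-domain features, 3 FFT-band statistics per band,
3 wavelet-band statistics per band, and 4 Poincare descriptors per lag —
62 features at the defaults, concatenated channel-major so a 22-channel
segment yields a 1,364-dimensional named vector.
"""

from __future__ import annotations

import numpy as np

from .core import (
    EEGSegment,
    FeatureMatrix,
    FeatureVector,
    RunConfig,
    SegmentSet,
    ValidationError,
    feature_names,
)
from .poincare import poincare_feature_matrix
from .spectral import spectral_feature_matrix
from .temporal import temporal_feature_matrix
from .wavelet import wavelet_feature_matrix

__all__ = ["extract_features", "extract_matrix"]

_FAMILY_EXTRACTORS = (
    ("time", lambda seg, cfg: temporal_feature_matrix(seg.data)),
    ("fft", lambda seg, cfg: spectral_feature_matrix(seg.data, seg.fs, cfg)),
    ("wpd", lambda seg, cfg: wavelet_feature_matrix(seg.data, seg.fs, cfg)),
    ("poincare", lambda seg, cfg: poincare_feature_matrix(seg.data, cfg)),
)


def extract_features(segment: EEGSegment, config: RunConfig | None = None) -> FeatureVector:
    """All four feature families for every channel of one segment."""
    if config is None:
        config = RunConfig()
    blocks: list[np.ndarray] = []
    for family, extractor in _FAMILY_EXTRACTORS:
        try:
            blocks.append(extractor(segment, config))
        except ValidationError as exc:
            raise ValidationError(f"family {family!r}: {exc}") from exc
    # blocks[i] is channels x family_width; interleave channel-major
    per_channel = np.concatenate(blocks, axis=1)  # channels x 62
    names = feature_names(segment.channel_labels, config)
    return FeatureVector(per_channel.ravel(), names)


def extract_matrix(
    segments: SegmentSet,
    config: RunConfig | None = None,
    channel_labels=None,
) -> FeatureMatrix:
    """One feature row per segment, in segment order; all segments must be labeled.

    An empty SegmentSet yields a 0-row matrix with the full header, provided
    `channel_labels` supplies the channel layout the header depends on.
    """
    if config is None:
        config = RunConfig()
    for i, seg in enumerate(segments):
        if seg.label is None:
            raise ValidationError(f"segment {i} has no class label")
    if len(segments) == 0:
        if channel_labels is None:
            raise ValidationError(
                "empty SegmentSet: pass channel_labels to build the header"
            )
        return empty_matrix(channel_labels, config)
    rows = [extract_features(seg, config) for seg in segments]
    names = rows[0].names
    values = np.vstack([r.values for r in rows])
    labels = tuple(seg.label for seg in segments)
    return FeatureMatrix(values, names, labels)


def empty_matrix(channel_labels, config: RunConfig | None = None) -> FeatureMatrix:
    """A 0-row matrix with the full header for the given channel layout."""
    if config is None:
        config = RunConfig()
    names = tuple(feature_names(channel_labels, config))
    return FeatureMatrix(np.empty((0, len(names))), names, ())
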