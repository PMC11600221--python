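"""Glue: recording -> rendered fingerprint -> embedding set.

The encoding chain is: extract the test window, (optional) baseline
subtraction, concatenate channels into the spectrum-like vector, PAA-reduce
to the extractor resolution, min-max normalize to [-1, 1], GAF (optionally
weighted to GAF*), render to 8-bit pixels.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .features import FeatureExtractor, FingerprintSet, builtin_spec
from .imaging import RenderedImage, gaf, gaf_star, render_image, to_polar
from .signals import (
    SensorRecording,
    baseline_subtract,
    concatenate_channels,
    extract_test_window,
    minmax_normalize,
    paa_reduce,
)
from .simulate import TaskDataset

__all__ = ["encode_recording", "encode_dataset", "featurize_dataset"]


def encode_recording(
    rec: SensorRecording,
    resolution: int = 96,
    encoding: str = "GAF",
    channel_mode: str = "replicate",
    baseline_mode: str = "none",
) -> RenderedImage:
    """Encode one recording as a rendered GAF/GAF* fingerprint image."""
    window = extract_test_window(rec)
    window = baseline_subtract(window, rec, mode=baseline_mode)
    concat = concatenate_channels(window)
    reduced = paa_reduce(concat.values, resolution)
    norm = minmax_normalize(reduced)
    g = gaf(to_polar(norm))
    if encoding == "GAF*":
        g = gaf_star(g, reduced)
    elif encoding != "GAF":
        raise InvalidArgumentError(f"unknown encoding {encoding!r}; use 'GAF' or 'GAF*'")
    return render_image(g, resolution, channel_mode=channel_mode)


def encode_dataset(
    dataset: TaskDataset,
    resolution: int = 96,
    encoding: str = "GAF",
    channel_mode: str = "replicate",
    baseline_mode: str = "none",
) -> tuple[list[RenderedImage], np.ndarray, np.ndarray]:
    """Encode every recording; returns (images, labels, product_ids)."""
    images = [
        encode_recording(r, resolution, encoding, channel_mode, baseline_mode)
        for r in dataset.recordings
    ]
    return images, dataset.labels, dataset.product_ids


def featurize_dataset(
    dataset: TaskDataset,
    extractor: FeatureExtractor | None = None,
    resolution: int | None = None,
    encoding: str = "GAF",
    channel_mode: str = "replicate",
    baseline_mode: str = "none",
) -> FingerprintSet:
    """Full front half of the pipeline: dataset -> embeddings + labels."""
    if extractor is None:
        extractor = FeatureExtractor(builtin_spec(resolution or 96))
    res = resolution or extractor.spec.input_resolution
    images, labels, pids = encode_dataset(dataset, res, encoding, channel_mode, baseline_mode)
    return extractor.extract_set(images, labels, pids)
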