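"""Raw-signal handling for multichannel potentiometric recordings.

A measurement is a matrix of differential voltages, one row per channel and
one column per second: a reference phase (electrode array resting in the
reference liquid) followed by a test phase (array immersed in the sample).
Only the test phase carries sample information; the stages below isolate it,
optionally subtract the late-reference baseline, flatten the channels into a
single spectrum-like vector, rescale it to [-1, 1] and downsample it with
piecewise aggregate approximation (PAA) to the working length of the image
encoder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError, SchemaError

__all__ = [
    "SensorRecording",
    "ConcatenatedSignal",
    "NormalizedSignal",
    "read_recording",
    "write_recording",
    "extract_test_window",
    "baseline_subtract",
    "concatenate_channels",
    "minmax_normalize",
    "paa_reduce",
]

_CHANNEL_RE = re.compile(r"^ch(\d+)$")


@dataclass
class SensorRecording:
    """One measurement: ``voltages`` is channels x time (volts).

    ``ref_duration_s`` and ``test_duration_s`` partition the time axis; the
    product of total duration and ``sample_rate_hz`` must equal the number of
    time samples.
    """

    voltages: np.ndarray
    sample_rate_hz: float = 1.0
    ref_duration_s: float = 100.0
    test_duration_s: float = 60.0
    label: str | None = None
    product_id: str | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise InvalidArgumentError("voltages must be a 2-D channels x time array")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def declared_samples(self) -> int:
        return int(round((self.ref_duration_s + self.test_duration_s) * self.sample_rate_hz))


@dataclass
class ConcatenatedSignal:
    """Channel-concatenated test-phase vector x_1..x_N (channel-major)."""

    values: np.ndarray
    channel_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class NormalizedSignal:
    """A signal affinely mapped onto [-1, 1]; keeps the scale used."""

    values: np.ndarray
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size


def read_recording(path: str | Path, manifest_entry: Mapping | None = None) -> SensorRecording:
    """Read one recording CSV (``t_s,ch01..chNN``, one row per sample).

    ``manifest_entry`` may carry ``label``, ``product_id`` and
    ``phase_split_s`` (reference/test boundary in seconds); the test phase is
    whatever follows the split.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if "t_s" not in df.columns:
        raise SchemaError(f"{path}: missing required column 't_s'")
    chan_cols = [c for c in df.columns if _CHANNEL_RE.match(c)]
    if not chan_cols:
        raise SchemaError(f"{path}: no channel columns matching 'chNN' found")
    chan_cols.sort(key=lambda c: int(_CHANNEL_RE.match(c).group(1)))
    numeric = df[chan_cols].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric/missing value at row {bad[0] + 2}, column {chan_cols[bad[1]]}"
        )
    mat = numeric.to_numpy(dtype=float).T  # channels x time

    n_samples = mat.shape[1]
    t = df["t_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t))) if n_samples > 1 else 1.0

    entry = dict(manifest_entry or {})
    split = float(entry.get("phase_split_s", 100.0))
    total_s = n_samples / rate
    rec = SensorRecording(
        voltages=mat,
        sample_rate_hz=rate,
        ref_duration_s=split,
        test_duration_s=total_s - split,
        label=entry.get("label"),
        product_id=entry.get("product_id"),
    )
    return rec


def write_recording(rec: SensorRecording, path: str | Path) -> Path:
    """Write a recording in the package CSV dialect (header ``t_s,ch01..``)."""
    path = Path(path)
    n_ch, n_t = rec.voltages.shape
    cols = {"t_s": np.arange(n_t) / rec.sample_rate_hz}
    for c in range(n_ch):
        cols[f"ch{c + 1:02d}"] = rec.voltages[c]
    # %.17g guarantees bit-exact float64 round-trips through text
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def extract_test_window(rec: SensorRecording) -> np.ndarray:
    """Return the final test-phase samples, channels x T.

    T = test_duration_s * sample_rate_hz; at the defaults (60 s at 1 Hz over
    15 channels) this is a 15 x 60 matrix.
    """
    t_test = int(round(rec.test_duration_s * rec.sample_rate_hz))
    if rec.declared_samples > rec.n_samples:
        raise InvalidArgumentError(
            f"recording has {rec.n_samples} samples but phases declare {rec.declared_samples}"
        )
    if t_test < 1 or t_test > rec.n_samples:
        raise InvalidArgumentError(f"test window of {t_test} samples not available")
    return rec.voltages[:, -t_test:].copy()


def baseline_subtract(
    window: np.ndarray,
    rec: SensorRecording,
    mode: str = "none",
    ref_tail_s: float = 10.0,
) -> np.ndarray:
    """Optionally subtract each channel's late-reference mean from the window.

    ``mode='none'`` is the identity (the default pipeline encodes raw
    test-phase voltages). ``mode='last_ref_mean'`` subtracts the per-channel
    mean over the final ``ref_tail_s`` seconds of the reference phase, so the
    test window starts near zero.
    """
    if mode == "none":
        return np.asarray(window, dtype=float)
    if mode != "last_ref_mean":
        raise InvalidArgumentError(f"unknown baseline mode {mode!r}")
    n_ref = int(round(rec.ref_duration_s * rec.sample_rate_hz))
    if n_ref < 1:
        raise InvalidArgumentError("baseline correction requires a reference phase")
    n_tail = max(1, int(round(ref_tail_s * rec.sample_rate_hz)))
    n_tail = min(n_tail, n_ref)
    ref_tail = rec.voltages[:, n_ref - n_tail : n_ref]
    return np.asarray(window, dtype=float) - ref_tail.mean(axis=1, keepdims=True)


def concatenate_channels(
    window: np.ndarray, order: Sequence[int] | None = None
) -> ConcatenatedSignal:
    """Flatten a channels x T window into one channel-major vector.

    ``order`` is a permutation of channel indices (default ascending); the
    output lists channel order[0]'s T samples, then order[1]'s, and so on,
    giving N = channels * T values.
    """
    window = np.asarray(window, dtype=float)
    n_ch = window.shape[0]
    if order is None:
        order = list(range(n_ch))
    order = list(order)
    if sorted(order) != list(range(n_ch)):
        raise InvalidArgumentError("order must be a permutation of channel indices")
    return ConcatenatedSignal(values=window[order].ravel(), channel_order=order)


def minmax_normalize(sig: ConcatenatedSignal | np.ndarray) -> NormalizedSignal:
    """Affinely map [min, max] of the signal onto [-1, 1].

    A constant signal (zero range) maps to all zeros rather than erroring,
    so degenerate fixtures flow through the pipeline.
    """
    values = sig.values if isinstance(sig, ConcatenatedSignal) else np.asarray(sig, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return NormalizedSignal(values=np.zeros_like(values), scale_min=lo, scale_max=hi)
    scaled = 2.0 * (values - lo) / (hi - lo) - 1.0
    return NormalizedSignal(values=scaled, scale_min=lo, scale_max=hi)


def paa_reduce(sig: np.ndarray | ConcatenatedSignal | NormalizedSignal, target_length: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``target_length`` points.

    Element m is the mean of the input over the index segment
    [floor(m*N/M), floor((m+1)*N/M)). With M == N this is the identity; when
    M divides N every segment has equal size and the global mean is preserved
    exactly.
    """
    if isinstance(sig, (ConcatenatedSignal, NormalizedSignal)):
        sig = sig.values
    x = np.asarray(sig, dtype=float).ravel()
    n = x.size
    m = int(target_length)
    if m < 1 or m > n:
        raise InvalidArgumentError(f"target_length must be in [1, {n}], got {m}")
    if m == n:
        return x.copy()
    starts = (np.arange(m) * n) // m
    ends = (np.arange(1, m + 1) * n) // m
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[ends] - csum[starts]) / (ends - starts)
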