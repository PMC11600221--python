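"""Seeded simulator for multichannel potentiometric (electronic-tongue) data.

Real measurements from a cross-sensitive electrode array show, per channel,
a flat reference-phase trace followed by an exponential approach to a new
steady state once the array enters the test liquid. The simulator reproduces
exactly that statistical skeleton:

* each sample class has an *archetype*: a vector of per-channel steady-state
  voltage shifts (``delta_v``, volts);
* the test phase of channel c follows
  ``baseline[c] + delta_v[c] * (1 - exp(-t/tau)) + drift_rate * t + noise``;
* replicates differ by i.i.d. Gaussian noise and a small per-replicate
  baseline jitter.

Four canonical task layouts are provided mirroring typical small
electronic-tongue studies: 7 wines x 10 replicates, 6 protein products x 10,
2 sugars x 3 concentration levels x 10, and 12 milk products (5 protein
sources) x 5, plus a 4-category beverage layout for clustering and a fully
custom layout. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .signals import SensorRecording, read_recording, write_recording

__all__ = [
    "SimulationConfig",
    "ClassArchetype",
    "TaskDataset",
    "make_class_archetypes",
    "simulate_recording",
    "generate_task_dataset",
    "write_dataset",
    "read_dataset",
    "TASK_LAYOUTS",
]

# Scale (volts) of one unit of between-class separation: the per-channel
# steady-state shift is drawn from N(0, (separation * _DELTA_SCALE_V)^2).
_DELTA_SCALE_V = 0.010
# Within-class product offsets (milk/clustering layouts) relative to the
# between-class scale; products of one source stay closer together than
# different sources.
_PRODUCT_OFFSET_FRACTION = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic sensor-response model.

    noise_sd, drift_rate are in volts and volts/second; tau_s is the time
    constant of the exponential approach to the steady state.
    """

    n_classes: int = 7
    n_replicates_per_class: int = 10
    n_channels: int = 15
    ref_duration_s: float = 100.0
    test_duration_s: float = 60.0
    sample_rate_hz: float = 1.0
    separation: float = 1.0
    noise_sd: float = 0.0005
    drift_rate: float = 1.0e-5
    tau_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1 or self.n_replicates_per_class < 1 or self.n_channels < 1:
            raise InvalidArgumentError("counts must be >= 1")
        if self.noise_sd < 0 or self.separation < 0:
            raise InvalidArgumentError("noise_sd and separation must be >= 0")
        if self.tau_s <= 0:
            raise InvalidArgumentError("tau_s must be > 0")
        if self.ref_duration_s < 0 or self.test_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise InvalidArgumentError("durations and sample rate must be positive")


@dataclass(frozen=True)
class ClassArchetype:
    """A class's per-channel steady-state voltage shift (volts)."""

    class_label: str
    delta_v: np.ndarray

    def scaled(self, factor: float, label: str | None = None) -> "ClassArchetype":
        return ClassArchetype(label or self.class_label, self.delta_v * factor)

    def offset(self, delta: np.ndarray, label: str) -> "ClassArchetype":
        return ClassArchetype(label, self.delta_v + delta)


@dataclass
class TaskDataset:
    """A labeled collection of recordings plus the config that produced it."""

    task: str
    recordings: list[SensorRecording]
    config: SimulationConfig | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.recordings], dtype=object)

    @property
    def product_ids(self) -> np.ndarray:
        return np.array([r.product_id for r in self.recordings], dtype=object)

    def __len__(self) -> int:
        return len(self.recordings)


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def make_class_archetypes(
    n_classes: int,
    n_channels: int = 15,
    separation: float = 1.0,
    seed: int = 0,
    labels: Iterable[str] | None = None,
) -> list[ClassArchetype]:
    """Draw one steady-state shift vector per class.

    Shifts are N(0, (separation * 10 mV)^2) per channel, so the expected
    pairwise distance between classes grows linearly with ``separation``;
    separation = 0 collapses every class onto the same (zero) archetype.
    """
    if n_classes < 1 or n_channels < 1:
        raise InvalidArgumentError("n_classes and n_channels must be >= 1")
    if separation < 0:
        raise InvalidArgumentError("separation must be >= 0")
    rng = _rng(seed, 0xA5C)
    names = list(labels) if labels is not None else [f"class_{i + 1}" for i in range(n_classes)]
    if len(names) != n_classes:
        raise InvalidArgumentError("labels length must equal n_classes")
    return [
        ClassArchetype(names[i], separation * _DELTA_SCALE_V * rng.standard_normal(n_channels))
        for i in range(n_classes)
    ]


def simulate_recording(
    archetype: ClassArchetype,
    config: SimulationConfig,
    replicate_seed: int,
    baseline: np.ndarray | None = None,
    product_id: str | None = None,
) -> SensorRecording:
    """Simulate one measurement of ``archetype`` under ``config``.

    Reference phase: baseline + jitter + noise. Test phase: baseline +
    delta_v*(1 - exp(-t/tau)) + drift_rate*t + noise, t measured from entry
    into the test liquid. Identical (archetype, config, seed, baseline) give
    bit-identical output.
    """
    config.validate()
    n_ch = config.n_channels
    if archetype.delta_v.shape != (n_ch,):
        raise InvalidArgumentError(
            f"archetype has {archetype.delta_v.size} channels, config declares {n_ch}"
        )
    rng = _rng(int(replicate_seed))
    n_ref = int(round(config.ref_duration_s * config.sample_rate_hz))
    n_test = int(round(config.test_duration_s * config.sample_rate_hz))
    base = np.zeros(n_ch) if baseline is None else np.asarray(baseline, dtype=float)
    # small replicate-to-replicate offset on top of the dataset baseline
    jitter = rng.normal(0.0, config.noise_sd, size=n_ch)

    t_test = (np.arange(1, n_test + 1)) / config.sample_rate_hz
    response = archetype.delta_v[:, None] * (1.0 - np.exp(-t_test / config.tau_s))[None, :]
    drift = config.drift_rate * t_test

    ref = (base + jitter)[:, None] + rng.normal(0.0, config.noise_sd, size=(n_ch, n_ref))
    test = (
        (base + jitter)[:, None]
        + response
        + drift[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_ch, n_test))
    )
    return SensorRecording(
        voltages=np.concatenate([ref, test], axis=1),
        sample_rate_hz=config.sample_rate_hz,
        ref_duration_s=config.ref_duration_s,
        test_duration_s=config.test_duration_s,
        label=archetype.class_label,
        product_id=product_id,
    )


# task -> (n_classes, replicates per class) for the simple balanced layouts
TASK_LAYOUTS: dict[str, tuple[int, int]] = {
    "wine": (7, 10),
    "protein": (6, 10),
}

# milk: protein source -> number of distinct commercial products
_MILK_ROSTER: dict[str, int] = {"almond": 2, "cow": 2, "soy": 2, "oat": 3, "pea": 3}
# clustering: beverage category -> number of distinct products (replicates
# per product are uniform; see docs/methods.md)
_CLUSTER_ROSTER: dict[str, int] = {"coffee": 8, "juice": 9, "water": 8, "wine": 7}
_SUGAR_LEVELS = (2.5, 5.0, 10.0)


def _dataset_baseline(config: SimulationConfig) -> np.ndarray:
    """Per-channel resting voltage shared by a dataset (one electrode array)."""
    return _rng(config.seed, 0xBA5E).uniform(-0.05, 0.05, size=config.n_channels)


def _replicate_seed(config: SimulationConfig, class_idx: int, rep_idx: int) -> int:
    # deterministic, collision-free derivation from (seed, class, replicate)
    return int(
        np.random.SeedSequence([config.seed, class_idx, rep_idx]).generate_state(1)[0] % (2**31)
    )


def generate_task_dataset(task: str, config: SimulationConfig | None = None) -> TaskDataset:
    """Generate a full labeled dataset in one of the canonical layouts.

    ``wine``: 7 classes x 10 replicates (70 recordings). ``protein``: 6 x 10.
    ``sugar``: glucose/sucrose at 2.5/5/10 %w/w, 10 replicates per cell (60);
    labels are ``<sugar>_<level>``. ``milk``: 12 products over 5 protein
    sources, 5 replicates each (60); labels are the source, product_id the
    product. ``clustering``: 32 products over 4 beverage categories, 5
    replicates each. ``custom``: config.n_classes x config.n_replicates.
    """
    config = config or SimulationConfig()
    config.validate()
    baseline = _dataset_baseline(config)
    recs: list[SensorRecording] = []

    def emit(arch: ClassArchetype, class_idx: int, n_reps: int, product_id: str | None = None):
        for rep in range(n_reps):
            recs.append(
                simulate_recording(
                    arch,
                    config,
                    _replicate_seed(config, class_idx, rep),
                    baseline=baseline,
                    product_id=product_id,
                )
            )

    if task in TASK_LAYOUTS:
        n_classes, n_reps = TASK_LAYOUTS[task]
        prefix = {"wine": "wine", "protein": "protein"}[task]
        labels = [f"{prefix}_{i + 1}" for i in range(n_classes)]
        for i, arch in enumerate(
            make_class_archetypes(n_classes, config.n_channels, config.separation, config.seed, labels)
        ):
            emit(arch, i, n_reps, product_id=arch.class_label)
    elif task == "custom":
        for i, arch in enumerate(
            make_class_archetypes(
                config.n_classes, config.n_channels, config.separation, config.seed
            )
        ):
            emit(arch, i, config.n_replicates_per_class, product_id=arch.class_label)
    elif task == "sugar":
        sugars = ["glucose", "sucrose"]
        base_archs = make_class_archetypes(2, config.n_channels, config.separation, config.seed, sugars)
        idx = 0
        for arch in base_archs:
            for level in _SUGAR_LEVELS:
                # concentration ordering embedded by scaling the shift
                scaled = arch.scaled(level / max(_SUGAR_LEVELS), label=f"{arch.class_label}_{level:g}")
                emit(scaled, idx, 10, product_id=scaled.class_label)
                idx += 1
    elif task == "milk":
        recs_from_roster(_MILK_ROSTER, 5, config, baseline, recs)
    elif task == "clustering":
        recs_from_roster(_CLUSTER_ROSTER, 5, config, baseline, recs)
    else:
        raise InvalidArgumentError(f"unknown task {task!r}")
    return TaskDataset(task=task, recordings=recs, config=config)


def recs_from_roster(
    roster: dict[str, int],
    n_reps: int,
    config: SimulationConfig,
    baseline: np.ndarray,
    out: list[SensorRecording],
) -> None:
    """Emit recordings for layouts where classes contain multiple products.

    Each class gets one archetype; each product adds a smaller deterministic
    offset so leave-one-product-out is nontrivial but solvable.
    """
    classes = list(roster)
    archs = make_class_archetypes(len(classes), config.n_channels, config.separation, config.seed, classes)
    class_idx = 0
    for arch, cls in zip(archs, classes):
        for p in range(roster[cls]):
            off_rng = _rng(config.seed, zlib.crc32(cls.encode()) % (2**31), p)
            offset = (
                _PRODUCT_OFFSET_FRACTION
                * config.separation
                * _DELTA_SCALE_V
                * off_rng.standard_normal(config.n_channels)
            )
            product = arch.offset(offset, arch.class_label)
            pid = f"{cls}_{p + 1}"
            for rep in range(n_reps):
                out.append(
                    simulate_recording(
                        product,
                        config,
                        _replicate_seed(config, class_idx, rep),
                        baseline=baseline,
                        product_id=pid,
                    )
                )
            class_idx += 1


def write_dataset(dataset: TaskDataset, out_dir: str | Path) -> Path:
    """Write recordings as CSV files plus a ``manifest.csv``.

    Manifest columns: ``file,label,product_id,phase_split_s``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(dataset.recordings):
        fname = f"rec_{i:04d}.csv"
        write_recording(rec, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "label": rec.label,
                "product_id": rec.product_id or "",
                "phase_split_s": rec.ref_duration_s,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_dataset(data_dir: str | Path, task: str = "custom") -> TaskDataset:
    """Read a dataset written by :func:`write_dataset` (or hand-assembled)."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv", comment="#", keep_default_na=False)
    recs = []
    for _, row in manifest.iterrows():
        entry = row.to_dict()
        if not entry.get("product_id"):
            entry["product_id"] = None
        recs.append(read_recording(data_dir / row["file"], entry))
    return TaskDataset(task=task, recordings=recs)
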