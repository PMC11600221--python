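"""Pixel-wise mixup augmentation and the few-shot training harness.

A synthetic training image of class C_i is a convex pixel-wise combination
of a *primary* image from C_i and a *donor* image from a different class
C_j: s = a*p_primary + b*p_donor with a + b = 1 and a > 0.5, so the primary
dominates and the synthetic sample keeps its label. Geometric augmentations
(rotation, mirroring) are deliberately absent: the geometry of a GAF
fingerprint is the signal.

The few-shot harness draws k shots per class for training (the rest is
test), optionally augments each class up to a target count (default 50,
real + synthetic), reduces to 10 principal components, trains a head and
records test accuracy — repeated over many seeded splits, with a two-sided
t-test comparing the augmented and plain accuracy distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, ProtocolError
from .evaluation import (
    EvaluationReport,
    _fit_predict,
    compare_accuracy_distributions,
    pooled_accuracy,
)
from .features import FeatureExtractor, builtin_spec, FingerprintSet
from .imaging import RenderedImage
from .pipeline import encode_dataset
from .simulate import TaskDataset

__all__ = [
    "MixSpec",
    "SyntheticImage",
    "mix_images",
    "augment_training_set",
    "fewshot_experiment",
    "FewShotResult",
    "SUPPORTED_RATIOS",
]

# mixing-ratio grid a/b commonly explored; a single a is used per run
SUPPORTED_RATIOS = (0.95, 0.90, 0.85, 0.80, 0.75)


@dataclass(frozen=True)
class MixSpec:
    """Mixing weight a (donor gets b = 1 - a) and the per-class target count."""

    a: float = 0.85
    target_per_class: int = 50
    seed: int = 0

    @property
    def b(self) -> float:
        return 1.0 - self.a

    def validate(self) -> None:
        if not (0.5 < self.a < 1.0):
            raise InvalidArgumentError(f"mixing weight a must be in (0.5, 1), got {self.a}")
        if self.target_per_class < 1:
            raise InvalidArgumentError("target_per_class must be >= 1")


@dataclass
class SyntheticImage(RenderedImage):
    """A mixed image; labelled with the primary parent's class."""

    parent_class: str = ""
    donor_class: str = ""
    a_used: float = 0.0


def mix_images(
    primary: RenderedImage,
    donor: RenderedImage,
    a: float,
    primary_class: str = "",
    donor_class: str = "",
) -> SyntheticImage:
    """s = a*primary + (1-a)*donor per pixel, rounded half-to-even to 0..255.

    Requires matching resolutions, a in (0.5, 1) and distinct classes when
    class labels are given. Every output pixel lies between its parents'.
    """
    if not (0.5 < a < 1.0):
        raise InvalidArgumentError(f"mixing weight a must be in (0.5, 1), got {a}")
    if primary.pixels.shape != donor.pixels.shape:
        raise InvalidArgumentError("parent images must share resolution and channels")
    if primary_class and donor_class and primary_class == donor_class:
        raise InvalidArgumentError("donor must come from a different class than the primary")
    mixed = a * primary.pixels.astype(float) + (1.0 - a) * donor.pixels.astype(float)
    pixels = np.clip(np.rint(mixed), 0, 255).astype(np.uint8)
    return SyntheticImage(
        pixels=pixels,
        resolution=primary.resolution,
        channel_mode=primary.channel_mode,
        parent_class=primary_class,
        donor_class=donor_class,
        a_used=a,
    )


def augment_training_set(
    images: list[RenderedImage],
    labels,
    spec: MixSpec | None = None,
) -> tuple[list[RenderedImage], np.ndarray, list[dict]]:
    """Top every class up to ``spec.target_per_class`` with synthetic images.

    Real images are passed through untouched; synthetic ones are appended,
    each labelled with its primary's class, with primaries drawn from the
    class's real shots and donors from a uniformly chosen other class.
    Returns (images, labels, provenance records). Deterministic in
    ``spec.seed``.
    """
    spec = spec or MixSpec()
    spec.validate()
    labels = np.asarray(labels, dtype=object)
    if len(images) != labels.size:
        raise InvalidArgumentError("images and labels must align")
    classes = sorted(np.unique(labels))
    if len(classes) < 2:
        raise InvalidArgumentError("augmentation needs at least 2 classes (donors)")
    by_class = {c: np.where(labels == c)[0] for c in classes}
    out_images = list(images)
    out_labels = list(labels)
    provenance: list[dict] = []
    for ci, cls in enumerate(classes):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, ci]))
        n_real = by_class[cls].size
        for _ in range(max(0, spec.target_per_class - n_real)):
            p_idx = int(rng.choice(by_class[cls]))
            donor_cls = classes[int(rng.choice([j for j in range(len(classes)) if j != ci]))]
            d_idx = int(rng.choice(by_class[donor_cls]))
            syn = mix_images(images[p_idx], images[d_idx], spec.a, str(cls), str(donor_cls))
            out_images.append(syn)
            out_labels.append(cls)
            provenance.append(
                {"parent_index": p_idx, "donor_index": d_idx, "a": spec.a,
                 "parent_class": str(cls), "donor_class": str(donor_cls)}
            )
    return out_images, np.asarray(out_labels, dtype=object), provenance


@dataclass
class FewShotResult:
    """Paired few-shot outcome: plain vs augmented, plus the t-test p-value."""

    plain: EvaluationReport
    augmented: EvaluationReport
    p_value: float
    k_shots: int


def fewshot_experiment(
    dataset: TaskDataset,
    extractor: FeatureExtractor | None = None,
    head="LDA",
    k_shots: int = 3,
    spec: MixSpec | None = None,
    k_components: int = 10,
    reps: int = 50,
    seed: int = 0,
    resolution: int = 96,
    encoding: str = "GAF",
) -> FewShotResult:
    """k-shot training with and without mixup augmentation, paired splits.

    Per repetition: draw k shots per class for training, keep the rest as
    test, evaluate the head once on the raw shots and once on the shots
    augmented to ``spec.target_per_class`` images per class (synthetic
    samples are re-rendered through the extractor, never added to the test
    set). Returns both accuracy distributions and their t-test p-value.
    """
    spec = spec or MixSpec(seed=seed)
    if extractor is None:
        extractor = FeatureExtractor(builtin_spec(resolution))
    images, labels, _ = encode_dataset(dataset, resolution=resolution, encoding=encoding)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(np.unique(labels))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if any(counts[c] <= k_shots for c in classes):
        raise ProtocolError(f"k_shots={k_shots} must be < every class size {counts}")

    emb_all = extractor.extract_set(images, labels)

    accs_plain, accs_aug, seeds = [], [], []
    conf_shape = (len(classes), len(classes))
    conf_plain = np.zeros(conf_shape, dtype=int)
    conf_aug = np.zeros(conf_shape, dtype=int)
    from sklearn.metrics import confusion_matrix

    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        train_idx = np.concatenate(
            [rng.choice(np.where(labels == c)[0], size=k_shots, replace=False) for c in classes]
        )
        test_mask = np.ones(labels.size, dtype=bool)
        test_mask[train_idx] = False
        test = emb_all.subset(np.where(test_mask)[0])

        train_plain = emb_all.subset(train_idx)
        pred = _fit_predict(train_plain, test, head, k_components, seed + rep)
        accs_plain.append(pooled_accuracy(test.labels, pred))
        conf_plain += confusion_matrix(test.labels, pred, labels=classes)

        shot_images = [images[i] for i in train_idx]
        shot_labels = labels[train_idx]
        aug_images, aug_labels, _prov = augment_training_set(
            shot_images, shot_labels, MixSpec(spec.a, spec.target_per_class, seed=spec.seed + rep)
        )
        train_aug = extractor.extract_set(aug_images, aug_labels)
        pred_a = _fit_predict(train_aug, test, head, k_components, seed + rep)
        accs_aug.append(pooled_accuracy(test.labels, pred_a))
        conf_aug += confusion_matrix(test.labels, pred_a, labels=classes)
        seeds.append(seed + rep)

    common = {"head": str(head), "k_shots": k_shots, "k_components": k_components,
              "reps": reps, "seed": seed, "a": spec.a, "target_per_class": spec.target_per_class}
    plain = EvaluationReport("fewshot_plain", np.array(accs_plain), conf_plain,
                             list(classes), seeds, dict(common, augmented=False))
    aug = EvaluationReport("fewshot_augmented", np.array(accs_aug), conf_aug,
                           list(classes), seeds, dict(common, augmented=True))
    return FewShotResult(
        plain=plain,
        augmented=aug,
        p_value=compare_accuracy_distributions(accs_plain, accs_aug),
        k_shots=k_shots,
    )
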