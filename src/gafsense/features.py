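"""Fingerprint embeddings: frozen feature extraction + PCA reduction.

The pipeline treats the feature extractor as a frozen, pure function of the
pixels. Two kinds are supported:

* a built-in deterministic extractor (default) producing a 1280-dim vector:
  per-cell mean/std/min/max over an 8x8 grid of the gray plane (4 x 64 = 256
  values, stat-major order) followed by the lowest 32x32 block of the 2-D
  orthonormal discrete cosine transform of the gray plane (1024 values);
* external pretrained vision backbones, consumed through a registry of
  adapters. None is bundled: registering one is the caller's job, and asking
  for an unregistered backbone raises :class:`CapabilityError` with a hint to
  fall back to the built-in extractor.

PCA is always fitted on training embeddings only; protocols in
:mod:`gafsense.evaluation` refit it inside every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.fft import dctn
from sklearn.decomposition import PCA

from .errors import CapabilityError, InvalidArgumentError
from .imaging import RenderedImage

__all__ = [
    "ExtractorSpec",
    "FingerprintSet",
    "PCAModel",
    "builtin_spec",
    "builtin_extract",
    "backbone_extract",
    "register_backbone",
    "FeatureExtractor",
    "fit_pca",
    "transform_pca",
]

_GRID = 8
_DCT_BLOCK = 32
BUILTIN_DIM = 4 * _GRID * _GRID + _DCT_BLOCK * _DCT_BLOCK  # 1280


@dataclass(frozen=True)
class ExtractorSpec:
    """Identity card of a frozen feature extractor."""

    name: str
    input_resolution: int
    output_dim: int
    kind: str = "builtin-deterministic"


def builtin_spec(resolution: int = 96) -> ExtractorSpec:
    return ExtractorSpec(
        name=f"builtin-dct-{resolution}",
        input_resolution=resolution,
        output_dim=BUILTIN_DIM,
        kind="builtin-deterministic",
    )


@dataclass
class FingerprintSet:
    """n x d embedding matrix with aligned labels (and optional product ids)."""

    embeddings: np.ndarray
    labels: np.ndarray
    product_ids: np.ndarray | None = None
    extractor: ExtractorSpec | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.embeddings.shape[0] != self.labels.shape[0]:
            raise InvalidArgumentError("embeddings and labels must align")
        if np.isnan(self.embeddings).any():
            raise InvalidArgumentError("embeddings contain missing values")

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]

    def subset(self, idx) -> "FingerprintSet":
        pid = None if self.product_ids is None else np.asarray(self.product_ids, dtype=object)[idx]
        return FingerprintSet(self.embeddings[idx], self.labels[idx], pid, self.extractor)


def builtin_extract(img: RenderedImage) -> np.ndarray:
    """Deterministic 1280-dim embedding of a rendered fingerprint.

    Requires the resolution to be a multiple of 8 and at least 32 (for the
    DCT block). The gray plane is the channel mean scaled to [0, 1].
    """
    pixels = np.asarray(img.pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidArgumentError("expected an H x W x 3 pixel array")
    h, w = pixels.shape[:2]
    if h != w:
        raise InvalidArgumentError("image must be square")
    if h % _GRID != 0 or h < _DCT_BLOCK:
        raise InvalidArgumentError(
            f"resolution {h} must be a multiple of {_GRID} and >= {_DCT_BLOCK}"
        )
    gray = pixels.mean(axis=2) / 255.0
    cell = h // _GRID
    blocks = gray.reshape(_GRID, cell, _GRID, cell)
    means = blocks.mean(axis=(1, 3)).ravel()
    stds = blocks.std(axis=(1, 3)).ravel()
    mins = blocks.min(axis=(1, 3)).ravel()
    maxs = blocks.max(axis=(1, 3)).ravel()
    coeffs = dctn(gray, norm="ortho")[:_DCT_BLOCK, :_DCT_BLOCK].ravel()
    return np.concatenate([means, stds, mins, maxs, coeffs])


# name -> callable(pixels uint8 HxWx3) -> 1-D embedding
_BACKBONE_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_backbone(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an external frozen backbone adapter (pure pixels -> vector)."""
    _BACKBONE_REGISTRY[name] = fn


def backbone_extract(img: RenderedImage, spec: ExtractorSpec) -> np.ndarray:
    """Pooled output of an external pretrained backbone.

    Raises :class:`CapabilityError` when no adapter is registered for
    ``spec.name`` — the pipeline remains fully runnable with the built-in
    extractor — and :class:`InvalidArgumentError` on resolution mismatch.
    """
    if img.resolution != spec.input_resolution:
        raise InvalidArgumentError(
            f"image resolution {img.resolution} != extractor input {spec.input_resolution}"
        )
    if spec.kind == "builtin-deterministic":
        return builtin_extract(img)
    fn = _BACKBONE_REGISTRY.get(spec.name)
    if fn is None:
        raise CapabilityError(
            f"no backbone adapter registered for {spec.name!r}; register one with "
            "register_backbone() or use the builtin extractor (builtin_spec())"
        )
    return np.asarray(fn(img.pixels), dtype=float).ravel()


@dataclass
class FeatureExtractor:
    """A spec plus its function, with a content-hash embedding cache.

    Extraction is pure, so identical pixels always hit the cache; this makes
    the 50-repetition protocols and augmentation loops cheap.
    """

    spec: ExtractorSpec
    _cache: dict = field(default_factory=dict, repr=False)

    def extract(self, img: RenderedImage) -> np.ndarray:
        key = img.content_hash()
        out = self._cache.get(key)
        if out is None:
            out = backbone_extract(img, self.spec)
            self._cache[key] = out
        return out

    def extract_set(
        self,
        images: list[RenderedImage],
        labels,
        product_ids=None,
    ) -> FingerprintSet:
        emb = np.vstack([self.extract(im) for im in images])
        pid = None if product_ids is None else np.asarray(product_ids, dtype=object)
        return FingerprintSet(emb, np.asarray(labels, dtype=object), pid, self.spec)


@dataclass
class PCAModel:
    """Centered PCA basis fitted on training embeddings only."""

    n_components: int
    components: np.ndarray          # d x k
    explained_variance_ratio: np.ndarray
    train_mean: np.ndarray

    def transform(self, embeddings: np.ndarray) -> np.ndarray:
        embeddings = np.asarray(embeddings, dtype=float)
        if embeddings.shape[1] != self.train_mean.size:
            raise InvalidArgumentError(
                f"embedding dim {embeddings.shape[1]} != model dim {self.train_mean.size}"
            )
        return (embeddings - self.train_mean) @ self.components

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components.T + self.train_mean


def fit_pca(train: FingerprintSet | np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA on training embeddings (and nothing else)."""
    x = train.embeddings if isinstance(train, FingerprintSet) else np.asarray(train, dtype=float)
    if k < 1 or k > min(x.shape):
        raise InvalidArgumentError(f"k must be in [1, {min(x.shape)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x)
    return PCAModel(
        n_components=k,
        components=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        train_mean=pca.mean_,
    )


def transform_pca(model: PCAModel, fset: FingerprintSet) -> FingerprintSet:
    """Project a fingerprint set onto the PCA basis; labels carried through."""
    return FingerprintSet(
        model.transform(fset.embeddings), fset.labels, fset.product_ids, fset.extractor
    )
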