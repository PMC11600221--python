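"""Gramian Angular Field (GAF) encoding of sensor signals into images.

A normalized series x_1..x_N in [-1, 1] is lifted to polar coordinates,
phi_i = arccos(x_i) and r_i = i/N, and the summation-form Gram matrix
G_ij = cos(phi_i + phi_j) becomes the square "fingerprint" of the
measurement. The diagonal satisfies G_ii = 2 x_i^2 - 1, and the whole matrix
obeys the product identity G_ij = x_i x_j - sqrt(1-x_i^2) sqrt(1-x_j^2),
which tests use as an independent oracle.

GAF* re-injects raw signal amplitude (lost by per-measurement min-max
scaling) by multiplying each column j of G by a weight w_j derived from the
raw sensor response. Rendering maps a matrix affinely onto 8-bit pixels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .signals import ConcatenatedSignal, NormalizedSignal, paa_reduce

__all__ = [
    "PolarRepresentation",
    "GAFImage",
    "RenderedImage",
    "to_polar",
    "gaf",
    "gaf_star",
    "render_image",
    "save_png",
]

_DOMAIN_TOL = 1e-9


@dataclass
class PolarRepresentation:
    """Angles phi in [0, pi] and radii r_i = i/N of a normalized series."""

    phi: np.ndarray
    r: np.ndarray


@dataclass
class GAFImage:
    """Square Gram matrix G (variant 'GAF') or its column-weighted 'GAF*'."""

    matrix: np.ndarray
    variant: str = "GAF"
    weights: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RenderedImage:
    """8-bit H x W x 3 pixel array ready for a vision feature extractor."""

    pixels: np.ndarray
    resolution: int
    channel_mode: str = "replicate"

    def content_hash(self) -> str:
        return hashlib.sha1(self.pixels.tobytes()).hexdigest()


def to_polar(x: NormalizedSignal | np.ndarray) -> PolarRepresentation:
    """Map a normalized series onto polar coordinates (phi = arccos x).

    Values may exceed [-1, 1] by at most 1e-9 (float slop; clipped); larger
    violations raise, because they indicate a normalization bug upstream.
    """
    values = x.values if isinstance(x, NormalizedSignal) else np.asarray(x, dtype=float).ravel()
    overshoot = float(np.max(np.abs(values))) - 1.0 if values.size else 0.0
    if overshoot > _DOMAIN_TOL:
        raise InvalidArgumentError(
            f"values exceed [-1, 1] by {overshoot:.3e}; normalize before encoding"
        )
    clipped = np.clip(values, -1.0, 1.0)
    n = clipped.size
    return PolarRepresentation(phi=np.arccos(clipped), r=np.arange(1, n + 1) / n)


def gaf(p: PolarRepresentation | NormalizedSignal | np.ndarray) -> GAFImage:
    """Summation-form Gramian Angular Field: G_ij = cos(phi_i + phi_j)."""
    if not isinstance(p, PolarRepresentation):
        p = to_polar(p)
    g = np.cos(p.phi[:, None] + p.phi[None, :])
    return GAFImage(matrix=g, variant="GAF")


def gaf_star(
    g: GAFImage,
    raw: ConcatenatedSignal | NormalizedSignal | np.ndarray,
    unit_scale: bool = True,
) -> GAFImage:
    """Intensity-weighted variant: column j of G scaled by weight w_j.

    ``raw`` is the original (pre-normalization) sensor response; it is
    PAA-reduced to the matrix size if longer. With ``unit_scale`` (default)
    the weights are the raw signal min-max mapped onto [0, 1], keeping the
    image within the renderable range; ``unit_scale=False`` uses raw volts
    as-is. A constant raw signal yields unit weights (G unchanged).
    """
    if isinstance(raw, (ConcatenatedSignal, NormalizedSignal)):
        raw = raw.values
    raw = np.asarray(raw, dtype=float).ravel()
    m = g.size
    if raw.size > m:
        raw = paa_reduce(raw, m)
    if raw.size != m:
        raise InvalidArgumentError(f"weight vector length {raw.size} != matrix size {m}")
    if unit_scale:
        lo, hi = float(raw.min()), float(raw.max())
        w = np.ones(m) if hi == lo else (raw - lo) / (hi - lo)
    else:
        w = raw
    return GAFImage(matrix=g.matrix * w[None, :], variant="GAF*", weights=w)


def render_image(g: GAFImage, resolution: int, channel_mode: str = "replicate") -> RenderedImage:
    """Render a GAF matrix to an 8-bit RGB image.

    The matrix range [min, max] maps affinely to [0, 255] with
    round-half-to-even; a constant matrix renders as all zeros. ``replicate``
    copies the gray plane to three channels; ``colormap`` applies a fixed
    perceptually-uniform (viridis) lookup table.
    """
    m = g.matrix
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidArgumentError("GAF matrix must be square")
    if m.shape[0] != resolution:
        raise InvalidArgumentError(
            f"matrix size {m.shape[0]} != requested resolution {resolution}; "
            "choose the PAA length upstream to match"
        )
    lo, hi = float(m.min()), float(m.max())
    unit = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    if channel_mode == "replicate":
        gray = np.rint(unit * 255.0).astype(np.uint8)
        pixels = np.repeat(gray[:, :, None], 3, axis=2)
    elif channel_mode == "colormap":
        from matplotlib import colormaps

        rgba = colormaps["viridis"](unit)
        pixels = np.rint(rgba[:, :, :3] * 255.0).astype(np.uint8)
    else:
        raise InvalidArgumentError(f"unknown channel_mode {channel_mode!r}")
    return RenderedImage(pixels=pixels, resolution=resolution, channel_mode=channel_mode)


def save_png(img: RenderedImage, path) -> None:
    from PIL import Image

    Image.fromarray(img.pixels, mode="RGB").save(path)
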