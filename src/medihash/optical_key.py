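"""Radial lens distortion and the optical key derived from it.

A camera's radial distortion displaces an ideal image point along the ray
from the distortion center ``(x_c, y_c)`` by the factor ``T(r) = 1 + k1 r^2``
with ``r`` the Euclidean distance from the center; ``k1`` is the first radial
distortion coefficient (per squared pixel-radius; barrel for k1 < 0,
pincushion for k1 > 0).

The optical key binds a base bit key to the acquiring optics: ``k1`` is
encoded as a 64-bit fixed-point word (scale 2^-32, two's complement), tiled
to the base key's length, and XORed in.  The derivation is an involution and
depends only on ``(base, k1)`` — never on pixel data — so ordinary signal
processing of the image cannot change the derived key; only a different
optical characterization can.  How ``k1`` is obtained (e.g. from camera
calibration metadata) is outside this module: it is accepted as
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistortionModel",
    "OpticalKey",
    "distort_point",
    "encode_k1",
    "derive_optical_key",
]

#: Fixed-point scale of the k1 encoding: 32 fractional bits.
K1_FRACTIONAL_BITS = 32
K1_WORD_BITS = 64


@dataclass(frozen=True)
class DistortionModel:
    """First-order radial distortion: center plus coefficient ``k1``."""

    center: tuple[float, float] = (0.0, 0.0)
    k1: float = 0.0


@dataclass(frozen=True)
class OpticalKey:
    base_key: np.ndarray
    k1_code: np.ndarray
    derived: np.ndarray


def distort_point(p, model: DistortionModel) -> tuple[float, float]:
    """Map an ideal point to its radially distorted position.

    ``x_d = x_c + (x_mu - x_c) * T(r)`` and likewise for y, with
    ``r = sqrt((x_mu - x_c)^2 + (y_mu - y_c)^2)`` and ``T(r) = 1 + k1 r^2``.
    ``k1 = 0`` is the identity and the center is always a fixed point.
    """
    x, y = float(p[0]), float(p[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    xc, yc = model.center
    dx, dy = x - xc, y - yc
    t = 1.0 + model.k1 * (dx * dx + dy * dy)
    return (xc + dx * t, yc + dy * t)


def encode_k1(k1: float) -> np.ndarray:
    """64-bit two's-complement fixed-point encoding of k1 (scale 2^-32), MSB first."""
    word = int(round(k1 * (1 << K1_FRACTIONAL_BITS))) & ((1 << K1_WORD_BITS) - 1)
    return np.array(
        [(word >> (K1_WORD_BITS - 1 - i)) & 1 for i in range(K1_WORD_BITS)],
        dtype=np.uint8,
    )


def derive_optical_key(base, model: DistortionModel) -> OpticalKey:
    """XOR the tiled k1 code into the base key.

    Deterministic, length-preserving, and an involution: deriving twice with
    the same model returns the base key.
    """
    base = np.asarray(base, dtype=np.uint8).ravel()
    if base.size == 0:
        raise ValueError("base key must be non-empty")
    if not np.all((base == 0) | (base == 1)):
        raise ValueError("base key must be a bit sequence")
    code = encode_k1(model.k1)
    reps = -(-base.size // code.size)  # ceil division
    pad = np.tile(code, reps)[: base.size]
    return OpticalKey(base_key=base, k1_code=code, derived=base ^ pad)
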