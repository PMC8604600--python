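"""Keyed dither (jitter) quantization of wavelet coefficients.

A base quantization matrix ``M^q`` (constant step by default) is perturbed
elementwise by a keyed +/-1 dither matrix ``M^d`` scaled by the jitter factor
``beta``::

    Q^d = M^q * (1 + beta * M^d)

so every quantization step lands in ``[step*(1-beta), step*(1+beta)]`` and
stays strictly positive for ``beta < 1``.  Coefficients are then quantized by

    E0 = round(L / Q^d) * Q^d

with ties rounded half away from zero, which keeps the error bound
``|L - E0| <= Q^d / 2`` symmetric and platform-independent.  With ``beta=0``
the mechanism reduces to plain uniform quantization; the key enters only
through the dither matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaotic_keys import (
    DitherMatrix,
    LogisticParams,
    logistic_iterate,
    sequence_to_dither,
)

__all__ = [
    "DEFAULT_DELTA",
    "DEFAULT_BETA",
    "JitterQuantMatrix",
    "build_jitter_quant_matrix",
    "keyed_quant_matrix",
    "dither_quantize",
]

#: Default quantization step of the base matrix.
DEFAULT_DELTA = 20.0

#: Default jitter factor.
DEFAULT_BETA = 0.1


@dataclass(frozen=True)
class JitterQuantMatrix:
    base: np.ndarray
    dither: DitherMatrix
    beta: float
    q_matrix: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.q_matrix.shape


def build_jitter_quant_matrix(
    base: np.ndarray, dither: DitherMatrix, beta: float
) -> JitterQuantMatrix:
    """Combine a positive base matrix with a +/-1 dither matrix.

    Raises on shape mismatch, non-positive base entries, or ``beta`` outside
    ``[0, 1)`` (``beta >= 1`` would create non-positive steps).
    """
    base = np.asarray(base, dtype=np.float64)
    if base.shape != dither.shape:
        raise ValueError(f"shape mismatch: base {base.shape} vs dither {dither.shape}")
    if not (0.0 <= beta < 1.0):
        raise ValueError(f"beta must be in [0, 1), got {beta}")
    if np.any(base <= 0):
        raise ValueError("base quantization matrix must be strictly positive")
    q = base * (1.0 + beta * dither.values)
    return JitterQuantMatrix(base=base, dither=dither, beta=beta, q_matrix=q)


def keyed_quant_matrix(
    shape: tuple[int, int],
    logistic: LogisticParams,
    *,
    delta: float = DEFAULT_DELTA,
    beta: float = DEFAULT_BETA,
) -> JitterQuantMatrix:
    """Build the jitter quantization matrix for ``shape`` from a logistic orbit.

    One keyed orbit dithers every subband: the dither matrix for each shape is
    cut from the same post-burn-in sequence, so the whole pipeline shares a
    single quantization key.
    """
    rows, cols = shape
    seq = logistic_iterate(logistic, rows * cols)
    dither = sequence_to_dither(seq, rows, cols)
    base = np.full(shape, float(delta))
    return build_jitter_quant_matrix(base, dither, beta)


def dither_quantize(coeffs: np.ndarray, qm: JitterQuantMatrix) -> np.ndarray:
    """Quantize a coefficient matrix: ``round(L / Q^d) * Q^d``.

    Rounding is half away from zero.  Every output entry is an integer
    multiple of its step, and requantizing a quantized matrix is the identity.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != qm.shape:
        raise ValueError(
            f"shape mismatch: coefficients {coeffs.shape} vs quant matrix {qm.shape}"
        )
    ratio = coeffs / qm.q_matrix
    rounded = np.sign(ratio) * np.floor(np.abs(ratio) + 0.5)
    return rounded * qm.q_matrix
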