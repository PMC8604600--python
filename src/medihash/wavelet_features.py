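"""Wavelet-domain features and the robust statistics that binarize them.

The canonical input is a 512x512 grayscale frame.  A two-level orthogonal
Haar decomposition yields the approximation ``LL2`` plus six detail subbands.
Three feature matrices feed the hash:

* the content-level feature — the dither-quantized ``LL2`` (coarse image
  content, the most robust);
* ``E2`` — the level-2 subband energy ``x_HL2^2 + x_LH2^2 + x_HH2^2`` per
  position, a robust mid-frequency feature;
* ``E1`` — the analogous level-1 energy, the detailed (most fragile) feature.

Each detail subband is dither-quantized before squaring, so small
content-preserving perturbations are absorbed by the quantizer.  Every
feature matrix is binarized against its own trimean
``0.25*Q1 + 0.5*median + 0.25*Q3`` — a location statistic that a handful of
outlier coefficients cannot drag, unlike the mean.  The quartile spread
``(Q3 - Q1)/1.349`` (a normal-consistent standard-deviation estimate) is
recorded as hash metadata but does not enter the bits.

Haar is used because it is orthogonal and exact on dyadic sizes: the
round-trip reconstruction test holds to machine precision and the subband
shapes halve cleanly (512 -> 256 -> 128).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import pywt
from PIL import Image

from .jitter_quantization import JitterQuantMatrix, dither_quantize

__all__ = [
    "CANONICAL_SIZE",
    "WAVELET",
    "SubbandSet",
    "FeatureStack",
    "RobustSummary",
    "preprocess",
    "decompose",
    "reconstruct",
    "content_feature",
    "energy_features",
    "median",
    "p_quantile",
    "trimean",
    "quartile_sd",
    "robust_summary",
    "binarize_feature",
]

CANONICAL_SIZE = 512
WAVELET = "haar"

#: Normal-consistency constant: IQR of a standard normal is ~1.349 sigma.
IQR_TO_SD = 1.349

_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class SubbandSet:
    """Two-level wavelet decomposition: LL2 plus six detail subbands."""

    LL2: np.ndarray
    HL2: np.ndarray
    LH2: np.ndarray
    HH2: np.ndarray
    HL1: np.ndarray
    LH1: np.ndarray
    HH1: np.ndarray

    def __post_init__(self) -> None:
        if self.HL1.shape[0] != 2 * self.HL2.shape[0]:
            raise ValueError("level-1 subbands must be twice the side of level-2")


@dataclass(frozen=True)
class FeatureStack:
    """The three per-level feature matrices of one image."""

    content: np.ndarray
    e2: np.ndarray
    e1: np.ndarray


@dataclass(frozen=True)
class RobustSummary:
    median: float
    q1: float
    q3: float
    trimean: float
    quartile_sd: float


def preprocess(image) -> np.ndarray:
    """Canonicalize a raster to the 512x512 float grayscale frame.

    Accepts a 2-D array, an RGB(A) array, or a PIL image; RGB collapses to
    luminance with the 0.299/0.587/0.114 weights and the result is
    bilinear-resized to 512x512.
    """
    if isinstance(image, Image.Image):
        image = np.asarray(image)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected RGB(A) channels last, got shape {arr.shape}")
        arr = _LUMA[0] * arr[..., 0] + _LUMA[1] * arr[..., 1] + _LUMA[2] * arr[..., 2]
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got shape {arr.shape}")
    if arr.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
        pil = Image.fromarray(arr.astype(np.float32), mode="F")
        pil = pil.resize((CANONICAL_SIZE, CANONICAL_SIZE), Image.BILINEAR)
        arr = np.asarray(pil, dtype=np.float64)
    return arr


def decompose(image: np.ndarray) -> SubbandSet:
    """Two-level Haar decomposition of the canonical 512x512 frame."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
        raise ValueError(
            f"expected canonical {CANONICAL_SIZE}x{CANONICAL_SIZE} input, "
            f"got {image.shape}; run preprocess() first"
        )
    LL2, (HL2, LH2, HH2), (HL1, LH1, HH1) = pywt.wavedec2(image, WAVELET, level=2)
    return SubbandSet(LL2=LL2, HL2=HL2, LH2=LH2, HH2=HH2, HL1=HL1, LH1=LH1, HH1=HH1)


def reconstruct(s: SubbandSet) -> np.ndarray:
    """Inverse of :func:`decompose`; exact to numerical tolerance."""
    coeffs = [s.LL2, (s.HL2, s.LH2, s.HH2), (s.HL1, s.LH1, s.HH1)]
    return pywt.waverec2(coeffs, WAVELET)


QuantSource = Union[JitterQuantMatrix, Callable[[tuple[int, int]], JitterQuantMatrix]]


def _qm_for(shape: tuple[int, int], qm: QuantSource) -> JitterQuantMatrix:
    if isinstance(qm, JitterQuantMatrix):
        if qm.shape != shape:
            raise ValueError(f"quant matrix shape {qm.shape} does not match {shape}")
        return qm
    return qm(shape)


def content_feature(LL2: np.ndarray, qm: QuantSource) -> np.ndarray:
    """Dither-quantize the approximation band: the content-level feature."""
    return dither_quantize(LL2, _qm_for(np.asarray(LL2).shape, qm))


def energy_features(s: SubbandSet, qm: QuantSource) -> tuple[np.ndarray, np.ndarray]:
    """Per-position subband energies ``(E1, E2)`` after dither quantization.

    ``qm`` is either one jitter quantization matrix (its shape must match) or
    a factory called per subband shape, so both decomposition levels share a
    single quantization key.
    """
    def q(band: np.ndarray) -> np.ndarray:
        return dither_quantize(band, _qm_for(band.shape, qm))

    e2 = q(s.HL2) ** 2 + q(s.LH2) ** 2 + q(s.HH2) ** 2
    e1 = q(s.HL1) ** 2 + q(s.LH1) ** 2 + q(s.HH1) ** 2
    return e1, e2


# ---------------------------------------------------------------------------
# Robust order statistics.
#
# The quantile follows the specific order-statistic rule (not an
# interpolating quantile): with x_(1..n) sorted ascending,
#   n*p not an integer -> x_([n*p] + 1)
#   n*p an integer     -> (x_(n*p) + x_(n*p + 1)) / 2
# which reduces to the usual median at p = 1/2.


def median(values) -> float:
    """Middle order statistic (odd n) or mean of the two central ones (even n)."""
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n == 0:
        raise ValueError("median of empty sequence")
    if n % 2 == 1:
        return float(x[(n - 1) // 2])
    return float((x[n // 2 - 1] + x[n // 2]) / 2.0)


def p_quantile(values, p: float) -> float:
    """Order-statistic p-quantile (see the rule above)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n == 0:
        raise ValueError("quantile of empty sequence")
    k = n * p
    k_round = round(k)
    if abs(k - k_round) < 1e-9:  # n*p is an integer
        lo = min(max(k_round, 1), n)
        hi = min(k_round + 1, n)
        return float((x[lo - 1] + x[hi - 1]) / 2.0)
    return float(x[int(np.floor(k))])  # 1-based index [n*p] + 1


def trimean(values) -> float:
    """Tukey's trimean ``0.25*Q1 + 0.5*median + 0.25*Q3``; needs n >= 4."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("trimean needs at least 4 values")
    return 0.25 * p_quantile(x, 0.25) + 0.5 * median(x) + 0.25 * p_quantile(x, 0.75)


def quartile_sd(values) -> float:
    """IQR-based scale estimate ``(Q3 - Q1) / 1.349``; ~sigma under normality."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("quartile_sd needs at least 4 values")
    return (p_quantile(x, 0.75) - p_quantile(x, 0.25)) / IQR_TO_SD


def robust_summary(values) -> RobustSummary:
    x = np.asarray(values, dtype=np.float64).ravel()
    return RobustSummary(
        median=median(x),
        q1=p_quantile(x, 0.25),
        q3=p_quantile(x, 0.75),
        trimean=trimean(x),
        quartile_sd=quartile_sd(x),
    )


def binarize_feature(feature: np.ndarray) -> np.ndarray:
    """Threshold a feature matrix at its own trimean: bit = entry > trimean.

    Strict inequality, so a constant matrix binarizes to all zeros.
    """
    feature = np.asarray(feature, dtype=np.float64)
    t = trimean(feature)
    return (feature > t).astype(np.uint8)
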