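"""Synthetic test images, content-preserving/tampering attacks, and the
packaged clinical tables.

The image generator emulates a microscopy-like diagnostic frame: a smooth
illumination gradient, a field of seeded Gaussian "cell" blobs, and mild
sensor noise.  Blood-smear frames are texture-rich, and that texture is what
gives the detail-level wavelet energies non-degenerate statistics; distinct
seeds lay the blobs out differently, so distinct seeds hash far apart.

Attacks come in two families: content-preserving (JPEG recompression,
additive Gaussian noise, mean filtering), which perturb pixels while keeping
global structure, and ``block_tamper``, which overwrites one rectangle —
the malicious-modification case a perceptual hash must flag.

Two clinical tables ship with the package as plain CSV: paired
bleeding-volume records and paired recovery scores for a control and a test
group, 40 records each, values unitless as printed in their source.  Stored
MD5 digests guard the transcriptions against drift.  Descriptive summaries
reuse this package's own robust order statistics.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .wavelet_features import median as _median
from .wavelet_features import p_quantile, quartile_sd, trimean

__all__ = [
    "AttackSpec",
    "ClinicalRecord",
    "ClinicalTable",
    "TABLE_NAMES",
    "generate_test_image",
    "apply_attack",
    "load_clinical_table",
    "summarize_group",
]

_TABLE_FILES = {
    "bleeding_volume": "table1_bleeding_volume.csv",
    "recovery": "table2_recovery.csv",
}
# MD5 of the shipped CSVs; transcription drift breaks loading loudly.
_TABLE_DIGESTS = {
    "bleeding_volume": "27194566cd9ae4782834f8b17c95c345",
    "recovery": "e0cbb0bf7f7ebda33fad33c1b62f1082",
}
TABLE_NAMES = tuple(_TABLE_FILES)

_ATTACK_KINDS = ("jpeg", "gaussian_noise", "mean_filter", "block_tamper")


@dataclass(frozen=True)
class AttackSpec:
    """One attack: kind, kind-specific params, and a seed for stochastic kinds.

    params: jpeg -> {"quality": 1..100}; gaussian_noise -> {"sigma": >=0};
    mean_filter -> {"window": odd >= 3}; block_tamper -> {"rect": (r0, c0, h, w),
    "fill": gray value}.
    """

    kind: str
    params: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _ATTACK_KINDS:
            raise ValueError(f"unknown attack kind {self.kind!r}")
        p = self.params
        if self.kind == "jpeg" and not (1 <= p["quality"] <= 100):
            raise ValueError("jpeg quality must be in [1, 100]")
        if self.kind == "gaussian_noise" and p["sigma"] < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "mean_filter" and (p["window"] < 3 or p["window"] % 2 == 0):
            raise ValueError("window must be odd and >= 3")
        if self.kind == "block_tamper" and len(p["rect"]) != 4:
            raise ValueError("rect must be (row, col, height, width)")


@dataclass(frozen=True)
class ClinicalRecord:
    number: int
    control_value: float
    test_value: float


@dataclass(frozen=True)
class ClinicalTable:
    name: str
    records: tuple[ClinicalRecord, ...]

    def column(self, group: str) -> np.ndarray:
        if group not in ("control", "test"):
            raise ValueError(f"group must be 'control' or 'test', got {group!r}")
        attr = f"{group}_value"
        return np.array([getattr(r, attr) for r in self.records])


def generate_test_image(seed: int, size: tuple[int, int] = (512, 512)) -> np.ndarray:
    """Deterministic microscopy-like frame in [0, 255].

    Smooth illumination gradient + ~140 sharp-rimmed cell disks +
    band-limited speckle.  The sharp rims and the speckle give the frame the
    high-frequency content of a stained-smear micrograph, so the detail-level
    wavelet energies carry real structure; same seed gives a byte-identical
    matrix, distinct seeds lay the cells out differently.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gx, gy = rng.uniform(-1, 1, 2)
    img = 128.0 + 40.0 * (gx * xx / w + gy * yy / h)

    n_cells = 140
    cy = rng.uniform(0, h, n_cells)
    cx = rng.uniform(0, w, n_cells)
    radius = rng.uniform(0.01, 0.035, n_cells) * min(h, w)
    amp = rng.uniform(35.0, 80.0, n_cells) * rng.choice((-1.0, 1.0), n_cells)
    edge = 1.2  # rim softness in pixels: sharp enough to excite level-1 details
    for y0, x0, r, a in zip(cy, cx, radius, amp):
        r0, r1 = int(max(0, y0 - r - 6 * edge)), int(min(h, y0 + r + 6 * edge + 1))
        c0, c1 = int(max(0, x0 - r - 6 * edge)), int(min(w, x0 + r + 6 * edge + 1))
        dy = yy[r0:r1, c0:c1] - y0
        dx = xx[r0:r1, c0:c1] - x0
        d = np.sqrt(dx * dx + dy * dy)
        img[r0:r1, c0:c1] += a / (1.0 + np.exp((d - r) / edge))

    speckle = ndimage.gaussian_filter(rng.normal(0.0, 60.0, size), sigma=0.8)
    img += speckle
    return np.clip(img, 0.0, 255.0)


def _jpeg_roundtrip(image: np.ndarray, quality: int) -> np.ndarray:
    pil = Image.fromarray(np.clip(image, 0, 255).astype(np.uint8), mode="L")
    buf = io.BytesIO()
    pil.save(buf, format="JPEG", quality=int(quality))
    buf.seek(0)
    return np.asarray(Image.open(buf), dtype=np.float64)


def apply_attack(image: np.ndarray, spec: AttackSpec) -> np.ndarray:
    """Apply one attack; content-preserving kinds keep global structure,
    ``block_tamper`` touches only the specified rectangle."""
    image = np.asarray(image, dtype=np.float64)
    if spec.kind == "jpeg":
        return _jpeg_roundtrip(image, spec.params["quality"])
    if spec.kind == "gaussian_noise":
        sigma = spec.params["sigma"]
        if sigma == 0:
            return image.copy()
        rng = np.random.default_rng(spec.seed)
        return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 255.0)
    if spec.kind == "mean_filter":
        return ndimage.uniform_filter(image, size=spec.params["window"], mode="nearest")
    r0, c0, hh, ww = spec.params["rect"]
    out = image.copy()
    out[r0 : r0 + hh, c0 : c0 + ww] = spec.params.get("fill", 0.0)
    return out


def _read_table_csv(name: str) -> pd.DataFrame:
    raw = (
        resources.files("medihash").joinpath("data", _TABLE_FILES[name]).read_bytes()
    )
    digest = hashlib.md5(raw).hexdigest()
    if digest != _TABLE_DIGESTS[name]:
        raise RuntimeError(
            f"clinical table {name!r} failed its integrity check "
            f"({digest} != {_TABLE_DIGESTS[name]})"
        )
    return pd.read_csv(io.BytesIO(raw))


def load_clinical_table(name: str) -> ClinicalTable:
    """Load a packaged clinical table ('bleeding_volume' or 'recovery')."""
    if name not in _TABLE_FILES:
        raise ValueError(f"unknown table {name!r}; choose from {TABLE_NAMES}")
    df = _read_table_csv(name)
    records = tuple(
        ClinicalRecord(int(row.number), float(row.control), float(row.test))
        for row in df.itertuples()
    )
    numbers = [r.number for r in records]
    if numbers != list(range(1, 41)):
        raise RuntimeError(f"table {name!r} must number records 1..40 without gaps")
    if any(r.control_value <= 0 or r.test_value <= 0 for r in records):
        raise RuntimeError(f"table {name!r} contains non-positive values")
    return ClinicalTable(name=name, records=records)


def summarize_group(table: ClinicalTable, group: str) -> dict:
    """Descriptive statistics for one group using the package's own
    robust order statistics."""
    x = table.column(group)
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "median": _median(x),
        "trimean": trimean(x),
        "q1": p_quantile(x, 0.25),
        "q3": p_quantile(x, 0.75),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "quartile_sd": quartile_sd(x),
    }
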