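"""Hash compression, scrambling, assembly and verification.

Each of the three binarized, coordinate-scrambled feature levels (content,
E2, E1) is compressed to 40 bits by one of two schemes:

* **Scheme 1** — the level matrix is serialized canonically (row-major,
  6-decimal fixed point), digested with MD5, and the first 40 digest bits
  are kept.  An exact hash on a robust feature: any change that survives
  binarization flips about half the bits.
* **Scheme 2** — the level matrix is partitioned into a 40-block grid
  (8 columns x 5 rows of near-equal rectangles; a plain 20x20 tiling is used
  whenever the level's dimensions produce exactly 40 such blocks) and each
  block contributes a majority bit: 0 when zeros are at least as many as
  ones, else 1.

Each level's 40 bits are then permuted by a key-seeded scrambling and the
levels concatenate content || E2 || E1 into the 120-bit authentication hash.
Verification compares hashes by normalized Hamming distance against a
threshold (default 0.15, an empirical choice on the synthetic corpus, not a
derived constant); hashes with mismatched parameter digests are incomparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import partial

import numpy as np

from .chaotic_keys import ChaosKey, LogisticParams, cat_map_permute, logistic_iterate
from .jitter_quantization import DEFAULT_BETA, DEFAULT_DELTA, keyed_quant_matrix
from .wavelet_features import (
    FeatureStack,
    binarize_feature,
    content_feature,
    decompose,
    energy_features,
    preprocess,
    quartile_sd,
)

__all__ = [
    "BITS_PER_LEVEL",
    "N_LEVELS",
    "HASH_BITS",
    "DEFAULT_THRESHOLD",
    "PerceptualHash",
    "VerificationResult",
    "scheme1_level_hash",
    "scheme2_level_hash",
    "scramble_bits",
    "unscramble_bits",
    "scramble_and_assemble",
    "hamming_verify",
    "compute_hash",
    "hash_from_array",
    "verify_image",
]

BITS_PER_LEVEL = 40
N_LEVELS = 3
HASH_BITS = BITS_PER_LEVEL * N_LEVELS
DEFAULT_THRESHOLD = 0.15

#: Preferred square block side; used when a level tiles into exactly 40 such blocks.
SQUARE_BLOCK = 20
#: Fallback grid: 8 columns x 5 rows = 40 near-equal blocks.
GRID_COLS, GRID_ROWS = 8, 5


@dataclass(frozen=True)
class PerceptualHash:
    """120-bit authentication hash plus the scheme tag and parameter digest."""

    bits: np.ndarray
    scheme: str
    params_digest: str
    metadata: dict | None = None

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8).ravel()
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("hash bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size

    def to_hex(self) -> str:
        """Lowercase hex, 4 bits per character, MSB first."""
        n = self.bits.size
        value = int("".join("1" if b else "0" for b in self.bits), 2) if n else 0
        return format(value, f"0{(n + 3) // 4}x")

    @classmethod
    def from_hex(cls, hex_str: str, scheme: str, params_digest: str) -> "PerceptualHash":
        n = 4 * len(hex_str)
        value = int(hex_str, 16)
        bits = np.array([(value >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)
        return cls(bits=bits, scheme=scheme, params_digest=params_digest)


@dataclass(frozen=True)
class VerificationResult:
    normalized_hamming: float
    threshold: float
    decision: str  # authentic | tampered | incomparable


def _block_edges(n: int, parts: int) -> np.ndarray:
    return np.linspace(0, n, parts + 1).round().astype(int)


def _block_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column edges of the 40-block partition for ``shape``."""
    rows, cols = shape
    if rows % SQUARE_BLOCK == 0 and cols % SQUARE_BLOCK == 0:
        n_blocks = (rows // SQUARE_BLOCK) * (cols // SQUARE_BLOCK)
        if n_blocks == BITS_PER_LEVEL:
            return (
                np.arange(0, rows + 1, SQUARE_BLOCK),
                np.arange(0, cols + 1, SQUARE_BLOCK),
            )
    if rows < GRID_ROWS or cols < GRID_COLS:
        raise ValueError(f"matrix {shape} smaller than the {GRID_ROWS}x{GRID_COLS} grid")
    return _block_edges(rows, GRID_ROWS), _block_edges(cols, GRID_COLS)


def scheme2_level_hash(bitmat: np.ndarray) -> np.ndarray:
    """Block-majority compression of one binarized level to 40 bits.

    Bit = 0 when the block's zero count N0 >= its one count N1, else 1
    (ties favour 0); blocks are scanned row-major.
    """
    bitmat = np.asarray(bitmat)
    if not np.all((bitmat == 0) | (bitmat == 1)):
        raise ValueError("scheme 2 consumes a binarized (0/1) matrix")
    row_edges, col_edges = _block_grid(bitmat.shape)
    bits = np.empty(BITS_PER_LEVEL, dtype=np.uint8)
    k = 0
    for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
        for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
            block = bitmat[r0:r1, c0:c1]
            n1 = int(block.sum())
            n0 = block.size - n1
            bits[k] = 0 if n0 >= n1 else 1
            k += 1
    return bits


def serialize_feature(feature: np.ndarray) -> bytes:
    """Canonical byte serialization: row-major, fixed 6-decimal entries.

    Negative zero is normalized so the bytes are platform-stable.
    """
    flat = np.asarray(feature, dtype=np.float64).ravel() + 0.0
    flat[flat == 0.0] = 0.0  # collapse -0.0
    return ",".join(f"{v:.6f}" for v in flat).encode("ascii")


def scheme1_level_hash(feature: np.ndarray) -> np.ndarray:
    """MD5 compression of one level: first 40 bits of the digest."""
    digest = hashlib.md5(serialize_feature(feature)).digest()
    bits = np.unpackbits(np.frombuffer(digest, dtype=np.uint8))
    return bits[:BITS_PER_LEVEL].astype(np.uint8)


def _keyed_permutation(logistic: LogisticParams, n: int, offset: int) -> np.ndarray:
    """Deterministic permutation of range(n) drawn from the logistic orbit.

    Indices are floor(x * n) over successive iterates, duplicates skipped;
    ``offset`` shifts the orbit so each level gets its own permutation.
    """
    params = LogisticParams(
        lam=logistic.lam, x0=logistic.x0, burn_in=logistic.burn_in + offset
    )
    chunk = 8 * n
    seen = np.zeros(n, dtype=bool)
    perm = np.empty(n, dtype=np.int64)
    k = 0
    start = 0
    while k < n and start < 100 * chunk:
        seq = logistic_iterate(
            LogisticParams(params.lam, params.x0, params.burn_in + start), chunk
        )
        for x in seq:
            idx = min(int(x * n), n - 1)
            if not seen[idx]:
                seen[idx] = True
                perm[k] = idx
                k += 1
                if k == n:
                    break
        start += chunk
    if k < n:  # orbit degenerated; fill the missing indices in order
        perm[k:] = np.flatnonzero(~seen)
    return perm


def scramble_bits(bits: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return np.asarray(bits)[perm]


def unscramble_bits(bits: np.ndarray, perm: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(bits))
    out[perm] = bits
    return out


def scramble_and_assemble(
    level_hashes, key: ChaosKey, scheme: str, params_digest: str, metadata=None
) -> PerceptualHash:
    """Permute each level's 40 bits with a key-seeded permutation and
    concatenate content || E2 || E1 into the final hash."""
    if len(level_hashes) != N_LEVELS:
        raise ValueError(f"expected {N_LEVELS} level hashes")
    pieces = []
    for lvl, bits in enumerate(level_hashes):
        bits = np.asarray(bits, dtype=np.uint8).ravel()
        if bits.size != BITS_PER_LEVEL:
            raise ValueError(f"level hash must be {BITS_PER_LEVEL} bits, got {bits.size}")
        perm = _keyed_permutation(key.logistic, BITS_PER_LEVEL, offset=1000 + lvl * 97)
        pieces.append(scramble_bits(bits, perm))
    return PerceptualHash(
        bits=np.concatenate(pieces),
        scheme=scheme,
        params_digest=params_digest,
        metadata=metadata,
    )


def hamming_verify(
    h1: PerceptualHash, h2: PerceptualHash, threshold: float = DEFAULT_THRESHOLD
) -> VerificationResult:
    """Normalized Hamming distance with an authenticity decision."""
    if len(h1) != len(h2) or h1.params_digest != h2.params_digest:
        return VerificationResult(float("nan"), threshold, "incomparable")
    d = float(np.mean(h1.bits != h2.bits))
    return VerificationResult(d, threshold, "authentic" if d <= threshold else "tampered")


# ---------------------------------------------------------------------------
# End-to-end pipeline.


def _params_digest(key: ChaosKey, scheme: str, delta: float, beta: float) -> str:
    payload = json.dumps(
        {"key": key.to_json(), "scheme": scheme, "delta": delta, "beta": beta},
        sort_keys=True,
    )
    return hashlib.md5(payload.encode("ascii")).hexdigest()[:16]


def hash_from_array(
    image: np.ndarray,
    key: ChaosKey,
    *,
    scheme: str = "scheme2",
    delta: float = DEFAULT_DELTA,
    beta: float = DEFAULT_BETA,
) -> PerceptualHash:
    """Hash a canonicalized (or raw) grayscale/RGB array.

    Pipeline: canonicalize -> 2-level Haar -> keyed dither quantization ->
    content + energy features -> trimean binarization -> cat-map coordinate
    scrambling -> per-level 40-bit compression -> keyed bit scrambling ->
    120-bit hash.
    """
    if scheme not in ("scheme1", "scheme2"):
        raise ValueError(f"unknown scheme {scheme!r}")
    canon = preprocess(image)
    subbands = decompose(canon)
    qm_factory = partial(keyed_quant_matrix, logistic=key.logistic, delta=delta, beta=beta)
    e1, e2 = energy_features(subbands, qm_factory)
    stack = FeatureStack(
        content=content_feature(subbands.LL2, qm_factory), e2=e2, e1=e1
    )
    level_hashes = []
    spreads = {}
    for name, feat in (("content", stack.content), ("e2", stack.e2), ("e1", stack.e1)):
        bits = binarize_feature(feat)
        scrambled = cat_map_permute(bits, key.cat.for_side(bits.shape[0]))
        if scheme == "scheme2":
            level_hashes.append(scheme2_level_hash(scrambled))
        else:
            level_hashes.append(scheme1_level_hash(scrambled))
        spreads[name] = quartile_sd(feat)
    digest = _params_digest(key, scheme, delta, beta)
    return scramble_and_assemble(
        level_hashes, key, scheme, digest, metadata={"quartile_sd": spreads}
    )


def compute_hash(
    image: np.ndarray,
    passphrase: str,
    *,
    scheme: str = "scheme2",
    delta: float = DEFAULT_DELTA,
    beta: float = DEFAULT_BETA,
    q: int = 5,
) -> PerceptualHash:
    """Hash an image under a passphrase-derived key (convenience wrapper)."""
    key = ChaosKey.from_passphrase(passphrase, q=q)
    return hash_from_array(image, key, scheme=scheme, delta=delta, beta=beta)


def verify_image(
    image: np.ndarray,
    reference: PerceptualHash,
    passphrase: str,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    delta: float = DEFAULT_DELTA,
    beta: float = DEFAULT_BETA,
    q: int = 5,
) -> VerificationResult:
    """Rehash ``image`` under the passphrase and compare to ``reference``."""
    fresh = compute_hash(image, passphrase, scheme=reference.scheme,
                         delta=delta, beta=beta, q=q)
    return hamming_verify(fresh, reference, threshold=threshold)
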