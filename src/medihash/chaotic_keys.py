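"""Keyed pseudorandom structures from chaotic maps.

The hashing pipeline is keyed three ways, all derived from a passphrase:

* a logistic-map orbit ``x_{k+1} = lam * x_k * (1 - x_k)`` seeds the +/-1
  dither matrix of the jitter quantizer and the bit-scrambling permutations;
* an Arnold cat map with integer parameters ``(a, b)`` scrambles the
  coordinates of each binarized feature matrix;
* the key space of the cat-map scrambling is ``(N - 1)^(2q)`` for an
  ``N x N`` matrix scrambled ``q`` times.

None of this is cryptographic-strength key derivation: the logistic map is a
chaotic pseudorandom source, and the passphrase mapping is a fixed arithmetic
pipeline.  It keys the perceptual hash; it does not protect secrets against a
resourceful attacker.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogisticParams",
    "DitherMatrix",
    "CatMapKey",
    "ChaosKey",
    "DEFAULT_LAMBDA",
    "DEFAULT_BURN_IN",
    "logistic_iterate",
    "sequence_to_dither",
    "passphrase_to_key",
    "cat_map_permute",
    "cat_map_unpermute",
    "key_space_size",
]

#: Default logistic parameter.  Deep in the chaotic regime; 4.0 is avoided
#: because it maps x = 0.5 onto the absorbing fixed point 0.
DEFAULT_LAMBDA = 3.99

#: Iterates discarded before the orbit is used, to escape transients.
DEFAULT_BURN_IN = 100

#: Iterations of the logistic map inside the passphrase-to-key pipeline.
PASSPHRASE_ITERATIONS = 50

#: Linear-expansion constant of the passphrase-to-key pipeline.
_EXPANSION = 10**6


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic map; ``x0`` is the key.

    ``lam`` must lie in (0, 4] so the orbit stays inside [0, 1], and
    ``x0`` must lie strictly inside (0, 1).
    """

    lam: float = DEFAULT_LAMBDA
    x0: float = 0.5
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if not (0.0 < self.x0 < 1.0):
            raise ValueError(f"x0 must be in (0, 1), got {self.x0}")
        if not (0.0 < self.lam <= 4.0):
            raise ValueError(f"lam must be in (0, 4], got {self.lam}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")


@dataclass(frozen=True)
class DitherMatrix:
    """Integer matrix with entries in {-1, +1}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        if not np.all(np.isin(vals, (-1, 1))):
            raise ValueError("dither matrix entries must be exactly -1 or +1")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CatMapKey:
    """Cat-map scrambling key: integers ``a, b``, iteration count ``q``, side ``N``."""

    a: int
    b: int
    iterations: int
    N: int

    def __post_init__(self) -> None:
        if not (0 < self.a < self.N):
            raise ValueError(f"a must satisfy 0 < a < N, got a={self.a}, N={self.N}")
        if not (0 < self.b < self.N):
            raise ValueError(f"b must satisfy 0 < b < N, got b={self.b}, N={self.N}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def for_side(self, N: int) -> "CatMapKey":
        """The same (a, b, q) reduced onto a matrix of side ``N``."""
        return CatMapKey(1 + (self.a - 1) % (N - 1), 1 + (self.b - 1) % (N - 1),
                         self.iterations, N)


@dataclass(frozen=True)
class ChaosKey:
    """Full key material derived from one passphrase.

    Bundles the logistic parameters that drive dithering and bit scrambling
    with the cat-map integers that drive coordinate scrambling.
    """

    passphrase_digest: str
    logistic: LogisticParams
    cat: CatMapKey
    salt: str = field(default="", compare=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passphrase_digest": self.passphrase_digest,
                "lambda": self.logistic.lam,
                "x0": self.logistic.x0,
                "burn_in": self.logistic.burn_in,
                "a": self.cat.a,
                "b": self.cat.b,
                "q": self.cat.iterations,
                "N": self.cat.N,
            },
            sort_keys=True,
        )

    @classmethod
    def from_passphrase(
        cls,
        passphrase: str,
        *,
        lam: float = DEFAULT_LAMBDA,
        q: int = 5,
        N: int = 128,
        burn_in: int = DEFAULT_BURN_IN,
    ) -> "ChaosKey":
        x0, a, b = passphrase_to_key(passphrase, n_iter=PASSPHRASE_ITERATIONS, N=N, lam=lam)
        digest = hashlib.md5(passphrase.encode("ascii")).hexdigest()[:16]
        return cls(
            passphrase_digest=digest,
            logistic=LogisticParams(lam=lam, x0=x0, burn_in=burn_in),
            cat=CatMapKey(a=a, b=b, iterations=q, N=N),
        )


def logistic_iterate(params: LogisticParams, n: int) -> np.ndarray:
    """Iterate the logistic map and return ``n`` post-burn-in values.

    Returns x_{burn_in+1}, ..., x_{burn_in+n}; every value lies in [0, 1]
    for valid parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x = params.x0
    lam = params.lam
    for _ in range(params.burn_in):
        x = lam * x * (1.0 - x)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        x = lam * x * (1.0 - x)
        out[i] = x
    return out


def sequence_to_dither(seq, rows: int, cols: int) -> DitherMatrix:
    """Threshold a [0, 1] sequence into a row-major +/-1 matrix.

    Values >= 0.5 map to +1, the rest to -1 (ties break upward so the rule
    is a single comparison).
    """
    seq = np.asarray(seq, dtype=np.float64).ravel()
    if seq.size < rows * cols:
        raise ValueError(
            f"sequence of length {seq.size} too short for {rows}x{cols} matrix"
        )
    bits = np.where(seq[: rows * cols] >= 0.5, 1, -1).reshape(rows, cols)
    return DitherMatrix(values=bits)


def passphrase_to_key(
    passphrase: str,
    n_iter: int = PASSPHRASE_ITERATIONS,
    *,
    N: int = 128,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[float, int, int]:
    """Map a printable-ASCII passphrase to ``(x0, a, b)``.

    The pipeline: the mean ASCII code divided by 128 becomes the logistic
    seed; the map is iterated ``n_iter`` times; the next two iterates are
    linearly expanded by 1e6, reduced modulo ``N - 1`` and shifted into
    [1, N-1] to give the cat-map integers.  ``x0`` is the orbit value after
    the ``n_iter`` iterations.  Fully deterministic.
    """
    if not passphrase:
        raise ValueError("passphrase must be non-empty")
    codes = [ord(c) for c in passphrase]
    if any(c < 32 or c > 126 for c in codes):
        raise ValueError("passphrase must be printable ASCII")
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10")
    x = float(np.mean(codes)) / 128.0
    for _ in range(n_iter):
        x = lam * x * (1.0 - x)
    x0 = x
    x = lam * x * (1.0 - x)
    a = 1 + int(np.floor(x * _EXPANSION)) % (N - 1)
    x = lam * x * (1.0 - x)
    b = 1 + int(np.floor(x * _EXPANSION)) % (N - 1)
    # Guard the degenerate orbit (x0 collapsed onto a fixed point of the map):
    # clamp the seed back inside the open interval so downstream orbits exist.
    if not (0.0 < x0 < 1.0):
        x0 = (float(np.mean(codes)) + 0.5) / 130.0
    return x0, a, b


def _cat_coords(i: np.ndarray, j: np.ndarray, a: int, b: int, N: int):
    return (i + a * j) % N, (b * i + (a * b + 1) * j) % N


def cat_map_permute(m: np.ndarray, key: CatMapKey) -> np.ndarray:
    """Scramble an ``N x N`` matrix with ``q`` rounds of the cat map.

    The element at 0-based ``(i, j)`` moves to
    ``((i + a*j) mod N, (b*i + (a*b + 1)*j) mod N)``.  The map has unit
    determinant, so it permutes the index grid and the output holds exactly
    the input's entries.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    N = m.shape[0]
    if N != key.N:
        raise ValueError(f"matrix side {N} does not match key side {key.N}")
    i, j = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    for _ in range(key.iterations):
        i, j = _cat_coords(i, j, key.a, key.b, N)
    out = np.empty_like(m)
    out[i, j] = m
    return out


def cat_map_unpermute(m: np.ndarray, key: CatMapKey) -> np.ndarray:
    """Invert :func:`cat_map_permute` exactly.

    ``A = [[1, a], [b, a*b + 1]]`` has det 1, so its inverse modulo N is
    ``[[a*b + 1, -a], [-b, 1]]``.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    N = m.shape[0]
    if N != key.N:
        raise ValueError(f"matrix side {N} does not match key side {key.N}")
    a, b = key.a, key.b
    i, j = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    for _ in range(key.iterations):
        i, j = ((a * b + 1) * i - a * j) % N, (-b * i + j) % N
    out = np.empty_like(m)
    out[i, j] = m
    return out


def key_space_size(N: int, q: int) -> int:
    """Size of the cat-map key space: ``(N - 1) ** (2 * q)``.

    Grows by a factor of ``(N - 1)^2`` with every extra mapping round.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if q < 1:
        raise ValueError("q must be >= 1")
    return (N - 1) ** (2 * q)
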