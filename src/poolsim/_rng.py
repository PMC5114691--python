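"""Counter-based deterministic randomness helpers.

Subsampling must be reproducible independent of record order, so instead of a
sequential RNG stream we hash (chromosome, position, population, master seed)
into a 64-bit key with splitmix64 and turn the key into a uniform deviate.
"""

from __future__ import annotations

import zlib

import numpy as np

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


def splitmix64(x) -> np.ndarray:
    """splitmix64 finalizer applied to ``x + golden_gamma`` (vectorized, wraps mod 2^64)."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=np.uint64) + _GOLDEN
        z = (z ^ (z >> _U64(30))) * _MIX1
        z = (z ^ (z >> _U64(27))) * _MIX2
        return z ^ (z >> _U64(31))


def chrom_hash(name: str) -> np.uint64:
    """Stable 64-bit hash of a chromosome name (crc32-based; independent of PYTHONHASHSEED)."""
    return _U64(zlib.crc32(name.encode()))


def site_uniforms(chrom_hashes, positions, stream, seed: int) -> np.ndarray:
    """One uniform in [0, 1) per site, keyed by (chrom, pos, stream index, seed).

    ``stream`` distinguishes independent draws at the same site (e.g. the
    population index); all inputs broadcast.
    """
    h = splitmix64(_U64(int(seed) & 0xFFFFFFFFFFFFFFFF))
    h = splitmix64(h + np.asarray(chrom_hashes, dtype=np.uint64))
    h = splitmix64(h + np.asarray(positions, dtype=np.uint64))
    h = splitmix64(h + np.asarray(stream, dtype=np.uint64))
    return (h >> _U64(11)).astype(np.float64) * (2.0 ** -53)


def derive_seed(seed: int, *salt: int) -> int:
    """Derive an independent 31-bit integer seed from a master seed and salt ints."""
    h = splitmix64(_U64(int(seed) & 0xFFFFFFFFFFFFFFFF))
    for s in salt:
        h = splitmix64(h + _U64(int(s) & 0xFFFFFFFFFFFFFFFF))
    return int(h & _U64(0x7FFFFFFF))


def as_generator(seed) -> np.random.Generator:
    """Accept an int seed or a ready Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
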