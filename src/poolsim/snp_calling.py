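"""SNP calling filters and without-replacement coverage subsampling.

Site filters follow the standard Pool-Seq pipeline: per-population coverage
bounds, a pooled minimum minor-allele count to guard against sequencing
errors, and a strictly biallelic requirement.  Coverage counts alleles only
(A+T+C+G); N and deletion reads are carried through the sync format but never
treated as alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from ._rng import as_generator, chrom_hash, site_uniforms
from .sync_io import ALLELE_BASES, SyncRecord, records_to_arrays

logger = logging.getLogger(__name__)

# lexicographic rank of the sync-order alleles (A, T, C, G) for tie-breaking
_ALPH_RANK = np.array([0, 3, 1, 2])  # A < C < G < T


@dataclass(frozen=True)
class SnpCall:
    """A biallelic site: per-population (major_count, minor_count)."""

    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    counts: tuple[tuple[int, int], ...]

    @property
    def n_populations(self) -> int:
        return len(self.counts)


@dataclass
class FilterConfig:
    """Site-filter thresholds.

    min/max coverage apply per population; ``min_count`` applies to the minor
    allele summed over all populations.  ``target_coverage`` (when set)
    triggers without-replacement subsampling and must not exceed
    ``min_coverage`` so every retained site can be subsampled.
    """

    min_coverage: int = 30
    max_coverage: int = 500
    min_count: int = 8
    target_coverage: int | None = None
    allowed_chroms: frozenset[str] | None = None

    def __post_init__(self):
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ValueError(
                f"need 0 < min_coverage <= max_coverage, got "
                f"{self.min_coverage}..{self.max_coverage}"
            )
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.target_coverage is not None:
            if self.target_coverage < 1:
                raise ValueError("target_coverage must be positive")
            if self.target_coverage > self.min_coverage:
                raise ValueError(
                    f"target_coverage ({self.target_coverage}) must not exceed "
                    f"min_coverage ({self.min_coverage})"
                )
        if self.allowed_chroms is not None:
            self.allowed_chroms = frozenset(self.allowed_chroms)


@dataclass
class FilterSummary:
    """Per-rule drop accounting for one call_snps run."""

    n_input: int = 0
    dropped_chrom: int = 0
    dropped_coverage: int = 0
    dropped_min_count: int = 0
    dropped_triallelic: int = 0
    n_called: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _major_minor(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (sync order) of the two most frequent alleles.

    Ties break lexicographically (A < C < G < T) so calls are deterministic
    and symmetric across replicates.
    """
    # composite sort key: count dominates, alphabet rank breaks ties
    key = pooled * 4 + (3 - _ALPH_RANK)[None, :]
    major = np.argmax(key, axis=1)
    key2 = key.copy()
    key2[np.arange(len(key)), major] = -1
    minor = np.argmax(key2, axis=1)
    return major, minor


def call_snps(
    records: Sequence[SyncRecord],
    cfg: FilterConfig,
    summary: FilterSummary | None = None,
) -> list[SnpCall]:
    """Apply all site filters and emit biallelic SNP calls.

    A site is emitted iff its chromosome is allowed, EVERY population's
    allele coverage (A+T+C+G) lies in [min_coverage, max_coverage], the
    pooled minor-allele count reaches ``min_count``, and no third allele
    also reaches ``min_count`` (strictly biallelic).  Filters drop sites
    silently; pass a :class:`FilterSummary` to collect per-rule counts.
    """
    if summary is None:
        summary = FilterSummary()
    chroms, pos, _refs, counts = records_to_arrays(records)
    n = len(chroms)
    summary.n_input = n
    if n == 0:
        return []

    keep = np.ones(n, dtype=bool)
    if cfg.allowed_chroms is not None:
        allowed = cfg.allowed_chroms
        chrom_ok = np.array([c in allowed for c in chroms])
    else:
        chrom_ok = np.ones(n, dtype=bool)

    allele_counts = counts[:, :, :4]  # (n, P, 4); N/del excluded
    cov = allele_counts.sum(axis=2)  # (n, P)
    cov_ok = np.all((cov >= cfg.min_coverage) & (cov <= cfg.max_coverage), axis=1)

    pooled = allele_counts.sum(axis=1)  # (n, 4)
    major, minor = _major_minor(pooled)
    rows = np.arange(n)
    minor_sum = pooled[rows, minor]
    count_ok = minor_sum >= cfg.min_count

    # third/fourth allele must stay below min_count
    rest = pooled.copy()
    rest[rows, major] = 0
    rest[rows, minor] = 0
    biallelic_ok = rest.max(axis=1) < cfg.min_count

    # drop accounting uses a fixed precedence; emission is the conjunction,
    # so filter order cannot change the result
    summary.dropped_chrom = int(np.sum(~chrom_ok))
    summary.dropped_coverage = int(np.sum(chrom_ok & ~cov_ok))
    summary.dropped_min_count = int(np.sum(chrom_ok & cov_ok & ~count_ok))
    summary.dropped_triallelic = int(np.sum(chrom_ok & cov_ok & count_ok & ~biallelic_ok))

    keep = chrom_ok & cov_ok & count_ok & biallelic_ok
    summary.n_called = int(keep.sum())
    logger.info(
        "call_snps: %d sites in, %d called (dropped: chrom %d, coverage %d, "
        "min_count %d, triallelic %d)",
        summary.n_input,
        summary.n_called,
        summary.dropped_chrom,
        summary.dropped_coverage,
        summary.dropped_min_count,
        summary.dropped_triallelic,
    )

    calls = []
    kept_idx = np.flatnonzero(keep)
    for i in kept_idx:
        mj, mn = major[i], minor[i]
        per_pop = tuple(
            (int(counts[i, p, mj]), int(counts[i, p, mn]))
            for p in range(counts.shape[1])
        )
        calls.append(
            SnpCall(
                chrom=chroms[i],
                pos=int(pos[i]),
                major_allele=ALLELE_BASES[mj],
                minor_allele=ALLELE_BASES[mn],
                counts=per_pop,
            )
        )
    return calls


def subsample_counts(counts, target: int, seed) -> tuple[int, ...]:
    """Subsample one population's counts without replacement to ``target``.

    Multivariate hypergeometric draw over the count categories (any arity:
    the 6-tuple A:T:C:G:N:del or a (major, minor) pair).  The output sums to
    exactly ``target`` with each component bounded by its input.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < target:
        raise ValueError(f"cannot subsample {total} reads to target {target}")
    if total == target:
        return tuple(int(c) for c in counts)
    rng = as_generator(seed)
    draw = rng.multivariate_hypergeometric(counts, target)
    return tuple(int(c) for c in draw)


def _hypergeom_from_uniform(
    u: np.ndarray, total: np.ndarray, good: np.ndarray, nsample
) -> np.ndarray:
    """Invert the hypergeometric CDF: smallest k with CDF(k) >= u.

    Vectorized over sites via the pmf ratio recurrence; exact for the modest
    sample sizes used here (target coverage <= a few hundred).
    """
    u = np.asarray(u, dtype=np.float64)
    total = np.asarray(total, dtype=np.int64)
    good = np.asarray(good, dtype=np.int64)
    nsample = np.broadcast_to(np.asarray(nsample, dtype=np.int64), total.shape)

    lo = np.maximum(0, nsample - (total - good))
    hi = np.minimum(nsample, good)

    # log pmf at the lower support bound, via log-binomials
    def _lbinom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logp = (
        _lbinom(good, lo)
        + _lbinom(total - good, nsample - lo)
        - _lbinom(total, nsample)
    )
    k = lo.astype(np.int64)
    pmf = np.exp(logp)
    cdf = pmf.copy()
    out = k.copy()
    active = np.flatnonzero((cdf < u) & (k < hi))
    k_a = k[active].astype(np.float64)
    pmf_a = pmf[active]
    cdf_a = cdf[active]
    good_a = good[active].astype(np.float64)
    tot_a = total[active].astype(np.float64)
    ns_a = nsample[active].astype(np.float64)
    hi_a = hi[active].astype(np.float64)
    u_a = u[active]
    while active.size:
        ratio = ((good_a - k_a) * (ns_a - k_a)) / (
            (k_a + 1.0) * (tot_a - good_a - ns_a + k_a + 1.0)
        )
        pmf_a = pmf_a * ratio
        k_a += 1.0
        cdf_a = cdf_a + pmf_a
        done = (cdf_a >= u_a) | (k_a >= hi_a)
        if done.any():
            out[active[done]] = k_a[done].astype(np.int64)
            live = ~done
            active = active[live]
            k_a, pmf_a, cdf_a = k_a[live], pmf_a[live], cdf_a[live]
            good_a, tot_a, ns_a = good_a[live], tot_a[live], ns_a[live]
            hi_a, u_a = hi_a[live], u_a[live]
    return out


def subsample_calls(
    calls: Sequence[SnpCall], cfg: FilterConfig, seed: int
) -> list[SnpCall]:
    """Subsample every population of every call to ``cfg.target_coverage``.

    Draws are independent per site and population, keyed by
    (chrom, pos, population, seed) so results do not depend on record order.
    """
    if cfg.target_coverage is None:
        raise ValueError("cfg.target_coverage must be set for subsampling")
    target = cfg.target_coverage
    if not calls:
        return []
    n = len(calls)
    n_pops = calls[0].n_populations
    maj = np.array([[c[0] for c in call.counts] for call in calls], dtype=np.int64)
    mino = np.array([[c[1] for c in call.counts] for call in calls], dtype=np.int64)
    tot = maj + mino
    if np.any(tot < target):
        bad = int(np.flatnonzero(np.any(tot < target, axis=1))[0])
        raise ValueError(
            f"site {calls[bad].chrom}:{calls[bad].pos} has coverage below "
            f"target {target}; filter on coverage first"
        )
    ch = np.array([chrom_hash(c.chrom) for c in calls], dtype=np.uint64)
    pos = np.array([c.pos for c in calls], dtype=np.uint64)

    maj_new = np.empty_like(maj)
    for p in range(n_pops):
        u = site_uniforms(ch, pos, np.uint64(p), seed)
        maj_new[:, p] = _hypergeom_from_uniform(u, tot[:, p], maj[:, p], target)
    min_new = target - maj_new

    out = []
    for i, call in enumerate(calls):
        out.append(
            SnpCall(
                chrom=call.chrom,
                pos=call.pos,
                major_allele=call.major_allele,
                minor_allele=call.minor_allele,
                counts=tuple(
                    (int(maj_new[i, p]), int(min_new[i, p])) for p in range(n_pops)
                ),
            )
        )
    return out


def calls_to_arrays(calls: Sequence[SnpCall]):
    """Columnar view of calls: (chroms, pos, major (n,P), minor (n,P))."""
    chroms = [c.chrom for c in calls]
    pos = np.array([c.pos for c in calls], dtype=np.int64)
    maj = np.array([[x[0] for x in c.counts] for c in calls], dtype=np.int64)
    mino = np.array([[x[1] for x in c.counts] for c in calls], dtype=np.int64)
    return chroms, pos, maj, mino


def write_calls(calls: Sequence[SnpCall], path: str | Path) -> None:
    """Tab-separated call table: chrom, pos, major, minor, per-pop major:minor."""
    with open(path, "w") as fh:
        if calls:
            n_pops = calls[0].n_populations
            pops = "\t".join(f"pop{i}" for i in range(n_pops))
            fh.write(f"#chrom\tpos\tmajor\tminor\t{pops}\n")
        for c in calls:
            fields = "\t".join(f"{a}:{b}" for a, b in c.counts)
            fh.write(f"{c.chrom}\t{c.pos}\t{c.major_allele}\t{c.minor_allele}\t{fields}\n")


def read_calls(path: str | Path) -> list[SnpCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            counts = tuple(
                (int(a), int(b))
                for a, b in (f.split(":") for f in fields[4:])
            )
            calls.append(
                SnpCall(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    major_allele=fields[2],
                    minor_allele=fields[3],
                    counts=counts,
                )
            )
    return calls
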