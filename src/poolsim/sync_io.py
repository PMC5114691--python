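"""Reading, writing and masking PoPoolation-style synchronized ("sync") files.

A sync file is tab-separated: chromosome, 1-based position, reference base,
then one colon-separated ``A:T:C:G:N:del`` count field per sequenced
population.  Mask intervals follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._rng import as_generator

#: fixed nucleotide order of the sync count field
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")
#: indices of true alleles within the 6-tuple (N and deletions are not alleles)
ALLELE_SLICE = slice(0, 4)
ALLELE_BASES = ("A", "T", "C", "G")


class SyncParseError(ValueError):
    """A sync line could not be parsed (reports the 1-based line number)."""


class SyncStructureError(ValueError):
    """Structural inconsistency, e.g. varying population count across lines."""


@dataclass(frozen=True)
class SyncRecord:
    """One genomic site: per-population (A, T, C, G, N, del) read counts."""

    chrom: str
    pos: int
    ref: str
    counts: tuple[tuple[int, int, int, int, int, int], ...]

    def coverage(self, population: int) -> int:
        """Total depth (all six categories) of one population."""
        return sum(self.counts[population])

    @property
    def n_populations(self) -> int:
        return len(self.counts)


def _parse_count_field(text: str, lineno: int) -> tuple[int, ...]:
    parts = text.split(":")
    if len(parts) != 6:
        raise SyncParseError(
            f"line {lineno}: count field {text!r} has {len(parts)} parts, expected 6"
        )
    try:
        vals = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise SyncParseError(f"line {lineno}: non-integer count in {text!r}") from exc
    if any(v < 0 for v in vals):
        raise SyncParseError(f"line {lineno}: negative count in {text!r}")
    return vals


def read_sync(path: str | Path) -> list[SyncRecord]:
    """Parse a sync file into records, skipping ``#`` comment lines.

    The population count is fixed by the first data line and enforced on
    every following line.
    """
    records: list[SyncRecord] = []
    n_pops: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {lineno}: expected at least 4 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise SyncParseError(f"line {lineno}: position {pos} < 1")
            counts = tuple(_parse_count_field(f, lineno) for f in fields[3:])
            if n_pops is None:
                n_pops = len(counts)
            elif len(counts) != n_pops:
                raise SyncStructureError(
                    f"line {lineno}: {len(counts)} populations, expected {n_pops}"
                )
            records.append(SyncRecord(chrom=chrom, pos=pos, ref=ref, counts=counts))
    return records


def format_sync_record(rec: SyncRecord) -> str:
    count_fields = "\t".join(":".join(str(c) for c in pop) for pop in rec.counts)
    return f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{count_fields}"


def write_sync(records: Sequence[SyncRecord], path: str | Path) -> None:
    """Write records in sync format; round-trip stable with :func:`read_sync`."""
    n_pops = None
    with open(path, "w") as fh:
        for rec in records:
            if n_pops is None:
                n_pops = rec.n_populations
            elif rec.n_populations != n_pops:
                raise SyncStructureError(
                    f"record {rec.chrom}:{rec.pos} has {rec.n_populations} "
                    f"populations, expected {n_pops}"
                )
            fh.write(format_sync_record(rec) + "\n")


class MaskIntervalSet:
    """A set of BED-style (chrom, start, end) intervals, 0-based half-open.

    Intervals may overlap; membership queries remain correct.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval ({chrom}, {start}, {end})")
            self._by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._arrays = {
            c: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
            for c, iv in self._by_chrom.items()
        }

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskIntervalSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def covers(self, chrom: str, pos0: int) -> bool:
        """True iff the 0-based coordinate ``pos0`` falls in some interval."""
        arr = self._arrays.get(chrom)
        if arr is None:
            return False
        starts, ends = arr
        return bool(np.any((starts <= pos0) & (pos0 < ends)))

    def covers_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        arr = self._arrays.get(chrom)
        if arr is None:
            return np.zeros(len(pos0), dtype=bool)
        starts, ends = arr
        p = np.asarray(pos0)[:, None]
        return np.any((starts[None, :] <= p) & (p < ends[None, :]), axis=1)

    def __len__(self) -> int:
        return sum(len(iv) for iv in self._by_chrom.values())


def apply_mask(records: Sequence[SyncRecord], mask: MaskIntervalSet) -> list[SyncRecord]:
    """Drop records whose (1-based) position falls inside a masked interval.

    A record at position p is removed iff some interval (chrom, s, e)
    satisfies s <= p-1 < e.  The surviving records keep their order.
    """
    if len(mask) == 0:
        return list(records)
    return [r for r in records if not mask.covers(r.chrom, r.pos - 1)]


@dataclass
class CoverageDistribution:
    """Empirical multiset of per-site total depths for one population."""

    depths: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.size == 0:
            raise ValueError("coverage distribution must be non-empty")
        if np.any(self.depths < 1):
            raise ValueError("all depths must be >= 1")

    @classmethod
    def constant(cls, depth: int, label: str = "") -> "CoverageDistribution":
        return cls(depths=np.array([depth]), label=label)

    @classmethod
    def from_file(cls, path: str | Path, label: str = "") -> "CoverageDistribution":
        """One-column plain-text depth list."""
        depths = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=1)
        return cls(depths=depths, label=label or str(path))

    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` depths with replacement from the multiset."""
        rng = as_generator(seed)
        if self.depths.size == 1:
            return np.full(n, self.depths[0], dtype=np.int64)
        return rng.choice(self.depths, size=n, replace=True)

    @property
    def mean(self) -> float:
        return float(self.depths.mean())


def load_coverage_distribution(
    source, population: int = 0, label: str = ""
) -> CoverageDistribution:
    """Build a CoverageDistribution from a depth-list file or sync records.

    For records the depth of a site is the sum of all six count categories of
    the chosen population.
    """
    if isinstance(source, (str, Path)):
        return CoverageDistribution.from_file(source, label=label)
    records = list(source)
    if not records:
        raise ValueError("no records to build a coverage distribution from")
    depths = np.array([r.coverage(population) for r in records], dtype=np.int64)
    return CoverageDistribution(depths=depths, label=label or f"pop{population}")


def records_to_arrays(records: Sequence[SyncRecord]):
    """Columnar view: (chrom list, pos int64 array, ref list, counts (n, P, 6) array)."""
    if not records:
        return [], np.empty(0, dtype=np.int64), [], np.empty((0, 0, 6), dtype=np.int64)
    n_pops = records[0].n_populations
    for r in records:
        if r.n_populations != n_pops:
            raise SyncStructureError("records have inconsistent population counts")
    chroms = [r.chrom for r in records]
    pos = np.array([r.pos for r in records], dtype=np.int64)
    refs = [r.ref for r in records]
    counts = np.array([r.counts for r in records], dtype=np.int64)
    return chroms, pos, refs, counts
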