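"""Cochran–Mantel–Haenszel testing of stratified allele counts, dual-mapper
intersection, and Benjamini–Hochberg FDR control.

Each SNP contributes a 2x2xK stack: stratum k is the 2x2 table of
(major, minor) read counts in one ancestral/derived population pair.  The CMH
chi-square (1 df) pools evidence for a consistent allele-frequency shift
across the K replicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .snp_calling import SnpCall, calls_to_arrays


@dataclass(frozen=True)
class ContingencyStack:
    """K stratified 2x2 tables; rows = (pop A, pop B), cols = (major, minor)."""

    tables: np.ndarray  # (K, 2, 2), non-negative ints

    def __post_init__(self):
        t = np.asarray(self.tables, dtype=np.int64)
        if t.ndim != 3 or t.shape[1:] != (2, 2):
            raise ValueError(f"expected shape (K, 2, 2), got {t.shape}")
        if t.shape[0] < 1:
            raise ValueError("need at least one stratum")
        if np.any(t < 0):
            raise ValueError("negative cell counts")
        object.__setattr__(self, "tables", t)

    @property
    def k(self) -> int:
        return self.tables.shape[0]


@dataclass(frozen=True)
class CmhResult:
    """One SNP's CMH outcome.  ``degenerate`` means no stratum was informative
    (zero margin or total <= 1 in every stratum); such SNPs report p = 1."""

    chrom: str | None
    pos: int | None
    statistic: float
    p_value: float
    degenerate: bool = False


def build_stack(call: SnpCall, pairs: Sequence[tuple[int, int]]) -> ContingencyStack:
    """Arrange a call's per-population counts into the stratified stack.

    ``pairs`` lists (ancestral_index, derived_index) per stratum, e.g.
    [(0, 2), (1, 3)] for populations ordered AP1, AP2, RAP1, RAP2.
    """
    n_pops = call.n_populations
    tables = []
    for ia, ib in pairs:
        if not (0 <= ia < n_pops and 0 <= ib < n_pops):
            raise IndexError(
                f"pair ({ia}, {ib}) out of range for {n_pops} populations"
            )
        tables.append([list(call.counts[ia]), list(call.counts[ib])])
    return ContingencyStack(tables=np.array(tables, dtype=np.int64))


def _cmh_batch(
    a: np.ndarray,
    r1: np.ndarray,
    c1: np.ndarray,
    n: np.ndarray,
    continuity_correction: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CMH over stacked sites.

    Inputs are (n_sites, K) arrays: top-left cell a, first row sum r1,
    first column sum c1, stratum total n.  Returns (statistic, p, degenerate).
    """
    a = a.astype(np.float64)
    r1 = r1.astype(np.float64)
    c1 = c1.astype(np.float64)
    n = n.astype(np.float64)
    r2 = n - r1
    c2 = n - c1
    informative = (n > 1) & (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        dev = a - r1 * c1 / n
        var = r1 * r2 * c1 * c2 / (n * n * (n - 1.0))
    dev = np.where(informative, dev, 0.0)
    var = np.where(informative, var, 0.0)
    num = dev.sum(axis=1)
    den = var.sum(axis=1)
    degenerate = ~informative.any(axis=1) | (den <= 0.0)

    cc = 0.5 if continuity_correction else 0.0
    base = np.maximum(np.abs(num) - cc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(degenerate, 0.0, base * base / np.where(den > 0, den, 1.0))
    p = np.where(degenerate, 1.0, chi2.sf(stat, df=1))
    return stat, p, degenerate


def cmh_test(
    stack: ContingencyStack,
    continuity_correction: bool = True,
    chrom: str | None = None,
    pos: int | None = None,
) -> CmhResult:
    """CMH chi-square (1 df) for one stack.

    statistic = (|sum_k (a_k - r1k c1k / n_k)| - cc)^2
                / sum_k r1k r2k c1k c2k / (n_k^2 (n_k - 1))

    with cc = 1/2 under the continuity correction (numerator base floored at
    zero).  Strata with n_k <= 1 or a zero margin contribute nothing; if all
    strata are uninformative the result is degenerate with p = 1.
    """
    t = stack.tables
    a = t[None, :, 0, 0]
    r1 = t[None, :, 0, :].sum(axis=2)
    c1 = t[None, :, :, 0].sum(axis=2)
    n = t[None].sum(axis=(2, 3))
    stat, p, deg = _cmh_batch(a, r1, c1, n, continuity_correction)
    return CmhResult(
        chrom=chrom,
        pos=pos,
        statistic=float(stat[0]),
        p_value=float(p[0]),
        degenerate=bool(deg[0]),
    )


def cmh_test_calls(
    calls: Sequence[SnpCall],
    pairs: Sequence[tuple[int, int]],
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """CMH test for every call; returns columns chrom, pos, statistic,
    p_value, degenerate (one row per SNP, input order)."""
    if not calls:
        return pd.DataFrame(
            columns=["chrom", "pos", "statistic", "p_value", "degenerate"]
        )
    chroms, pos, maj, mino = calls_to_arrays(calls)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    n_pops = maj.shape[1]
    if np.any(ia >= n_pops) or np.any(ib >= n_pops) or np.any(ia < 0) or np.any(ib < 0):
        raise IndexError(f"population pair index out of range for {n_pops} populations")
    a = maj[:, ia]
    r1 = maj[:, ia] + mino[:, ia]
    c1 = maj[:, ia] + maj[:, ib]
    n = r1 + maj[:, ib] + mino[:, ib]
    stat, p, deg = _cmh_batch(a, r1, c1, n, continuity_correction)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "statistic": stat,
            "p_value": p,
            "degenerate": deg,
        }
    )


def merge_dual_mappers(results_a, results_b) -> pd.DataFrame:
    """Intersect two mappers' SNP sets on (chrom, pos); keep the LARGER
    p-value (conservative: a SNP is only as significant as its worst mapper).

    Accepts DataFrames (as from :func:`cmh_test_calls`) or iterables of
    :class:`CmhResult`.
    """
    df_a = _as_frame(results_a)
    df_b = _as_frame(results_b)
    merged = df_a.merge(df_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    take_b = merged["p_value_b"].to_numpy() > merged["p_value_a"].to_numpy()
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "statistic": np.where(
                take_b, merged["statistic_b"], merged["statistic_a"]
            ),
            "p_value": np.maximum(merged["p_value_a"], merged["p_value_b"]),
            "degenerate": merged["degenerate_a"] | merged["degenerate_b"],
        }
    )
    return out.reset_index(drop=True)


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        (r.chrom, r.pos, r.statistic, r.p_value, r.degenerate) for r in results
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "statistic", "p_value", "degenerate"]
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def adjust_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``q_value`` column (BH over ``p_value``) to a cmh_test_calls frame."""
    out = table.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def count_significant(
    table: pd.DataFrame, alpha: float = 0.01
) -> tuple[int, pd.DataFrame]:
    """Rows with q_value strictly below ``alpha`` (the FDR threshold)."""
    if "q_value" not in table.columns:
        raise ValueError("table has no q_value column; run adjust_table first")
    hits = table[table["q_value"].to_numpy() < alpha]
    return len(hits), hits
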