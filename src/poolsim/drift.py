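"""Neutral simulator of allele-frequency change in panels of isofemale lines.

Each line descends from a cross of two individuals drawn from a large
parental population at Hardy-Weinberg equilibrium, so a locus enters the line
on 4 founder chromosomes carrying k in {0..4} copies of the focal allele.
Generations of small-census maintenance drive every initially heterozygous
line to fixation; under neutrality the allele fixes with probability k/4.
Allele-frequency change (AFC) is the difference between the panel-wide final
and founder frequencies, optionally re-measured through a round of binomial
Pool-Seq read sampling at empirical coverages.

Frequencies in the parental population follow a truncated exponential
spectrum (rate ``rate``, truncated to (0, upper_truncation]), the standard
shape of a minor-allele frequency spectrum under neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_generator
from .sync_io import CoverageDistribution

_CHUNK = 65_536  # SNPs per block in the panel samplers (bounds peak memory)


@dataclass
class SpectrumConfig:
    """Parental allele-frequency spectrum: Exponential(rate) truncated to
    (0, upper_truncation].  Defaults reproduce the published median drift
    AFC for a 202-line panel."""

    rate: float = 20.0
    upper_truncation: float = 0.5
    n_snps: int = 5_000_000

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not (0 < self.upper_truncation <= 1):
            raise ValueError("upper_truncation must lie in (0, 1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")


@dataclass
class LinePanel:
    """Focal-allele copy numbers, one row per SNP, one column per line.

    ``copies[s, l]`` counts the focal allele among line l's 4 founder
    chromosomes (0..4) — or, after fixation, is 0 or 4.
    """

    copies: np.ndarray  # (n_snps, n_lines) int8

    def __post_init__(self):
        self.copies = np.asarray(self.copies, dtype=np.int8)
        if self.copies.ndim != 2:
            raise ValueError("copies must be 2-D (n_snps, n_lines)")
        if self.copies.size and (self.copies.min() < 0 or self.copies.max() > 4):
            raise ValueError("copy numbers must lie in 0..4")

    @property
    def n_snps(self) -> int:
        return self.copies.shape[0]

    @property
    def n_lines(self) -> int:
        return self.copies.shape[1]

    def frequencies(self) -> np.ndarray:
        """Panel allele frequency per SNP: mean of k/4 over lines."""
        return self.copies.mean(axis=1, dtype=np.float64) / 4.0

    def is_fixed(self) -> bool:
        return bool(np.all((self.copies == 0) | (self.copies == 4)))


def sample_parental_freqs(cfg: SpectrumConfig, seed) -> np.ndarray:
    """Draw parental frequencies from the truncated exponential spectrum.

    Inverse-CDF sampling: with Z = 1 - exp(-rate * T) the mass inside the
    truncation window, p = -log(1 - u Z) / rate for u ~ U(0, 1).
    """
    rng = as_generator(seed)
    u = rng.random(cfg.n_snps)
    z = -np.expm1(-cfg.rate * cfg.upper_truncation)
    p = -np.log1p(-u * z) / cfg.rate
    # guard the open lower bound against u == 0
    tiny = np.nextafter(0.0, 1.0)
    return np.clip(p, tiny, cfg.upper_truncation)


def found_lines(freqs: np.ndarray, n_lines: int, seed) -> LinePanel:
    """Found ``n_lines`` isofemale lines per SNP by Hardy-Weinberg sampling.

    Each line draws TWO genotypes from (q^2 : 0 copies, 2pq : 1, p^2 : 2) —
    one per founding parent — and sums them, giving k in {0..4} distributed
    Binomial(4, p).
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if n_lines < 1:
        raise ValueError("n_lines must be positive")
    rng = as_generator(seed)
    n_snps = freqs.size
    copies = np.empty((n_snps, n_lines), dtype=np.int8)
    for start in range(0, n_snps, _CHUNK):
        stop = min(start + _CHUNK, n_snps)
        m = stop - start
        p = freqs[start:stop].astype(np.float32)[:, None]
        # contiguous full-size thresholds: broadcasted (stride-0) comparisons
        # hit a slow ufunc path, flat draws + contiguous operands do not
        thr_hom = np.ascontiguousarray(
            np.broadcast_to(p * p, (m, n_lines))
        )  # genotype AA (2 copies)
        thr_any = np.ascontiguousarray(
            np.broadcast_to(p * (2.0 - p), (m, n_lines))
        )  # AA or Aa (>= 1 copy): p^2 + 2p(1-p)
        block = np.zeros((m, n_lines), dtype=np.int8)
        for _parent in range(2):
            u = rng.random(m * n_lines, dtype=np.float32).reshape(m, n_lines)
            block += (u < thr_hom).view(np.int8)
            block += (u < thr_any).view(np.int8)
        copies[start:stop] = block
    return LinePanel(copies=copies)


_FIX_THRESHOLDS = np.arange(5, dtype=np.float32) * np.float32(0.25)


def simulate_fixation(panel: LinePanel, seed) -> LinePanel:
    """Drive every heterozygous line to fixation.

    A line carrying k in {1, 2, 3} focal copies fixes the focal allele
    (k -> 4) with probability k/4 and loses it otherwise; lines already at
    k in {0, 4} are unchanged.  One binomial step stands in for the many
    generations of small-census drift that guarantee fixation.
    """
    rng = as_generator(seed)
    k = panel.copies
    n_lines = k.shape[1]
    fixed = np.empty_like(k)
    for start in range(0, k.shape[0], _CHUNK):
        stop = min(start + _CHUNK, k.shape[0])
        m = stop - start
        block = k[start:stop]
        u = rng.random(m * n_lines, dtype=np.float32).reshape(m, n_lines)
        thr = _FIX_THRESHOLDS[block]  # k/4 per line
        fixed[start:stop] = (u < thr).view(np.int8) * np.int8(4)
    return LinePanel(copies=fixed)


def compute_afc(
    initial: LinePanel, final: LinePanel, p_parental: np.ndarray | None = None
) -> pd.DataFrame:
    """Allele-frequency change table: final minus founder panel frequency.

    Columns: p_parental (NaN when not supplied), f_initial, f_final,
    afc_signed, afc_abs.  Pure function of the two panels.
    """
    if initial.copies.shape != final.copies.shape:
        raise ValueError(
            f"panel shapes differ: {initial.copies.shape} vs {final.copies.shape}"
        )
    if not final.is_fixed():
        raise ValueError("final panel must be fully fixed (all k in {0, 4})")
    f_init = initial.frequencies()
    f_final = final.frequencies()
    afc = f_final - f_init
    if p_parental is None:
        p_col = np.full(initial.n_snps, np.nan)
    else:
        p_col = np.asarray(p_parental, dtype=np.float64)
        if p_col.shape != (initial.n_snps,):
            raise ValueError("p_parental length must match the panel")
    return pd.DataFrame(
        {
            "p_parental": p_col,
            "f_initial": f_init,
            "f_final": f_final,
            "afc_signed": afc,
            "afc_abs": np.abs(afc),
        }
    )


def poolseq_sample(
    freqs: np.ndarray, coverage_dist: CoverageDistribution, seed
) -> tuple[np.ndarray, np.ndarray]:
    """One round of Pool-Seq read sampling per SNP.

    Coverage c is drawn (with replacement) from the empirical distribution,
    then the focal read count is Binomial(c, f).  Returns (counts, coverages);
    the observed frequency is counts / coverages.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = as_generator(seed)
    cov = coverage_dist.sample(freqs.size, rng)
    counts = rng.binomial(cov, freqs)
    return counts.astype(np.int64), cov.astype(np.int64)


def add_poolseq_observation(
    table: pd.DataFrame, coverage_dist: CoverageDistribution, seed
) -> pd.DataFrame:
    """Re-measure initial and final frequencies through Pool-Seq noise.

    Adds f_initial_obs, f_final_obs, afc_obs (signed) and afc_obs_abs, with
    independent coverage draws for the two sequencing rounds.
    """
    rng = as_generator(seed)
    out = table.copy()
    c0, cov0 = poolseq_sample(table["f_initial"].to_numpy(), coverage_dist, rng)
    c1, cov1 = poolseq_sample(table["f_final"].to_numpy(), coverage_dist, rng)
    out["f_initial_obs"] = c0 / cov0
    out["f_final_obs"] = c1 / cov1
    out["afc_obs"] = out["f_final_obs"] - out["f_initial_obs"]
    out["afc_obs_abs"] = out["afc_obs"].abs()
    return out


_QUANTS = (0.05, 0.25, 0.5, 0.75, 0.95)


def summarize_afc(table: pd.DataFrame) -> dict:
    """Median, mean and quantiles of |AFC| — drift-only and, when present,
    Pool-Seq-observed."""
    if len(table) == 0:
        raise ValueError("empty AFC table")
    out: dict = {"n_snps": int(len(table))}
    for key, col in (("drift", "afc_abs"), ("poolseq", "afc_obs_abs")):
        if col not in table.columns:
            continue
        x = table[col].to_numpy()
        out[key] = {
            "median": float(np.median(x)),
            "mean": float(np.mean(x)),
            "quantiles": {str(q): float(np.quantile(x, q)) for q in _QUANTS},
        }
    return out


def qq_quantiles(x, y, n_quantiles: int = 199) -> pd.DataFrame:
    """Paired quantile vectors of two samples for a quantile-quantile plot."""
    probs = np.linspace(0.0, 1.0, n_quantiles + 2)[1:-1]
    return pd.DataFrame(
        {
            "prob": probs,
            "q_x": np.quantile(np.asarray(x, dtype=np.float64), probs),
            "q_y": np.quantile(np.asarray(y, dtype=np.float64), probs),
        }
    )


def simulate_drift_experiment(
    n_snps: int,
    n_lines: int,
    spectrum: SpectrumConfig | None = None,
    coverage_dist: CoverageDistribution | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full drift simulation: spectrum -> founding -> fixation -> AFC,
    plus Pool-Seq re-measurement when a coverage distribution is given."""
    cfg = spectrum or SpectrumConfig()
    cfg = SpectrumConfig(
        rate=cfg.rate, upper_truncation=cfg.upper_truncation, n_snps=n_snps
    )
    rng = as_generator(seed)
    freqs = sample_parental_freqs(cfg, rng)
    initial = found_lines(freqs, n_lines, rng)
    final = simulate_fixation(initial, rng)
    table = compute_afc(initial, final, p_parental=freqs)
    if coverage_dist is not None:
        table = add_poolseq_observation(table, coverage_dist, rng)
    return table
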