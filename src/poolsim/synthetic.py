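"""Synthetic 4-population Pool-Seq experiments under the neutral null model.

Emulates the ancestral-population (AP) versus reconstituted-ancestral-
population (RAP) design: two AP replicates are pooled from freshly founded
isofemale lines, and two RAP replicates are re-pooled years later from the
same, now fully inbred, lines.  One line panel per SNP therefore drives all
four populations — AP1/AP2 share the founder frequency and RAP1/RAP2 share
the post-fixation frequency — while sequencing (coverage draw + binomial
read sampling, optional uniform base-miscall errors) is independent per
population.  An optional "selection spike" shifts a fraction of RAP truth
frequencies to provide signal for power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator
from .drift import (
    LinePanel,
    SpectrumConfig,
    compute_afc,
    found_lines,
    sample_parental_freqs,
    simulate_fixation,
)
from .sync_io import ALLELE_BASES, CoverageDistribution, SyncRecord

#: population order of generated sync files
POPULATION_ORDER = ("AP1", "AP2", "RAP1", "RAP2")
#: strata pairing AP with its RAP replicate, in POPULATION_ORDER indices
DEFAULT_PAIRS = ((0, 2), (1, 3))

# plausible major-arm sizes (bp) for synthetic coordinates
DEFAULT_CHROM_SIZES = {
    "X": 22_000_000,
    "2L": 23_000_000,
    "2R": 21_000_000,
    "3L": 24_000_000,
    "3R": 28_000_000,
    "4": 1_300_000,
}


@dataclass
class ExperimentConfig:
    """Null-model experiment: sizes, spectrum, per-population coverage,
    error rate and optional selection spike."""

    n_snps: int = 100_000
    n_lines: int = 202
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    coverages: tuple = (150, 170, 40, 70)  # int or CoverageDistribution per pop
    error_rate: float = 0.0
    spike_fraction: float = 0.0
    spike_delta: float = 0.0
    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))

    def __post_init__(self):
        if self.n_snps < 1 or self.n_lines < 1:
            raise ValueError("n_snps and n_lines must be positive")
        if len(self.coverages) != len(POPULATION_ORDER):
            raise ValueError(
                f"need {len(POPULATION_ORDER)} coverage sources, got "
                f"{len(self.coverages)}"
            )
        if not (0 <= self.error_rate < 0.01):
            raise ValueError("error_rate must lie in [0, 0.01)")
        if not (0 <= self.spike_fraction <= 1):
            raise ValueError("spike_fraction must lie in [0, 1]")
        if abs(self.spike_delta) > 1:
            raise ValueError("|spike_delta| must be <= 1")
        if sum(self.chrom_sizes.values()) < self.n_snps:
            raise ValueError("genome too small for the requested SNP count")

    def coverage_dists(self) -> list[CoverageDistribution]:
        out = []
        for name, c in zip(POPULATION_ORDER, self.coverages):
            if isinstance(c, CoverageDistribution):
                out.append(c)
            else:
                out.append(CoverageDistribution.constant(int(c), label=name))
        return out


def _allocate_positions(rng, chrom_sizes: dict, n_snps: int):
    """Deterministic proportional split of SNPs over chromosomes, then
    positions drawn without replacement and sorted (1-based)."""
    names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=np.float64)
    share = sizes / sizes.sum() * n_snps
    counts = np.floor(share).astype(np.int64)
    # largest-remainder rounding
    rest = n_snps - counts.sum()
    order = np.argsort(-(share - counts), kind="stable")
    counts[order[:rest]] += 1
    chroms, positions = [], []
    for name, n_c in zip(names, counts):
        if n_c == 0:
            continue
        length = chrom_sizes[name]
        pool = np.unique(rng.integers(1, length + 1, size=int(n_c * 1.1) + 64))
        while pool.size < n_c:
            extra = rng.integers(1, length + 1, size=int(n_c * 0.2) + 64)
            pool = np.unique(np.concatenate([pool, extra]))
        pos = np.sort(rng.choice(pool, size=n_c, replace=False))
        chroms.extend([name] * int(n_c))
        positions.append(pos)
    return chroms, np.concatenate(positions)


def spike_selection(
    truth: pd.DataFrame, fraction: float, delta: float, seed
) -> pd.DataFrame:
    """Shift f_final by ``delta`` (clamped to [0, 1]) for a random
    ``fraction`` of SNPs and flag them ``selected``."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    out = truth.copy()
    if "selected" not in out.columns:
        out["selected"] = False
    n = len(out)
    k = int(round(fraction * n))
    if k == 0:
        return out
    rng = as_generator(seed)
    idx = rng.choice(n, size=k, replace=False)
    f = out["f_final"].to_numpy().copy()
    f[idx] = np.clip(f[idx] + delta, 0.0, 1.0)
    out["f_final"] = f
    sel = out["selected"].to_numpy().copy()
    sel[idx] = True
    out["selected"] = sel
    return out


def _sequence_population(
    rng, freqs: np.ndarray, cov_dist: CoverageDistribution, error_rate: float,
    base_a: np.ndarray, base_b: np.ndarray,
) -> np.ndarray:
    """Read counts (n, 6) in sync order for one population.

    Coverage per site from ``cov_dist``; focal-allele reads Binomial(c, f);
    each read independently miscalled to a uniform other base with
    probability ``error_rate``.
    """
    n = freqs.size
    cov = cov_dist.sample(n, rng)
    n_focal = rng.binomial(cov, freqs)
    n_other = cov - n_focal
    counts = np.zeros((n, 6), dtype=np.int64)
    rows = np.arange(n)
    counts[rows, base_a] = n_focal
    counts[rows, base_b] += n_other
    if error_rate > 0.0:
        snapshot = counts[:, :4].copy()
        for b in range(4):
            nb = snapshot[:, b]
            errs = rng.binomial(nb, error_rate)
            counts[:, b] -= errs
            others = [x for x in range(4) if x != b]
            e1 = rng.binomial(errs, 1.0 / 3.0)
            e2 = rng.binomial(errs - e1, 0.5)
            counts[:, others[0]] += e1
            counts[:, others[1]] += e2
            counts[:, others[2]] += errs - e1 - e2
    return counts


def generate_experiment(
    cfg: ExperimentConfig,
) -> tuple[list[SyncRecord], pd.DataFrame]:
    """Simulate a complete AP1/AP2/RAP1/RAP2 experiment.

    Returns 4-population sync records (population order
    :data:`POPULATION_ORDER`) and the truth table (chrom, pos, p_parental,
    f_initial, f_final, selected).
    """
    rng = as_generator(cfg.seed)

    spectrum = SpectrumConfig(
        rate=cfg.spectrum.rate,
        upper_truncation=cfg.spectrum.upper_truncation,
        n_snps=cfg.n_snps,
    )
    freqs = sample_parental_freqs(spectrum, rng)
    initial = found_lines(freqs, cfg.n_lines, rng)
    final = simulate_fixation(initial, rng)
    afc = compute_afc(initial, final, p_parental=freqs)

    chroms, positions = _allocate_positions(rng, cfg.chrom_sizes, cfg.n_snps)
    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "p_parental": afc["p_parental"].to_numpy(),
            "f_initial": afc["f_initial"].to_numpy(),
            "f_final": afc["f_final"].to_numpy(),
            "selected": False,
        }
    )
    if cfg.spike_fraction > 0:
        truth = spike_selection(truth, cfg.spike_fraction, cfg.spike_delta, rng)

    # two random distinct bases per SNP; the focal allele is the reference
    base_a = rng.integers(0, 4, cfg.n_snps)
    base_b = (base_a + rng.integers(1, 4, cfg.n_snps)) % 4

    f_initial = truth["f_initial"].to_numpy()
    f_final = truth["f_final"].to_numpy()
    pop_truth = (f_initial, f_initial, f_final, f_final)
    dists = cfg.coverage_dists()
    pop_counts = [
        _sequence_population(rng, f, d, cfg.error_rate, base_a, base_b)
        for f, d in zip(pop_truth, dists)
    ]

    stacked = np.stack(pop_counts, axis=1)  # (n, 4 pops, 6)
    counts_list = stacked.tolist()  # bulk C-level int conversion
    pos_list = truth["pos"].tolist()
    ref_list = [ALLELE_BASES[b] for b in base_a.tolist()]
    records = [
        SyncRecord(chrom=c, pos=p, ref=r, counts=tuple(map(tuple, cl)))
        for c, p, r, cl in zip(chroms, pos_list, ref_list, counts_list)
    ]
    return records, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
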