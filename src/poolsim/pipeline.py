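"""End-to-end pipeline orchestration: generate or read sync input, mask,
call SNPs, subsample coverage, CMH-test AP/RAP pairs, optionally intersect
two mappers' runs, BH-adjust, and report significant SNPs.

Driven by a plain YAML config; every stage seed derives deterministically
from the single master seed, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from . import cmh as cmh_mod
from .cmh import adjust_table, bh_adjust, count_significant, merge_dual_mappers, cmh_test_calls
from .snp_calling import (
    FilterConfig,
    FilterSummary,
    SnpCall,
    call_snps,
    calls_to_arrays,
    subsample_calls,
    write_calls,
)
from .sync_io import MaskIntervalSet, apply_mask, read_sync, write_sync
from .synthetic import DEFAULT_PAIRS, ExperimentConfig, generate_experiment, write_truth
from .drift import SpectrumConfig

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending key."""


@dataclass
class RunManifest:
    """Config snapshot, seeds and per-stage record accounting for one run."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    n_tested: int = 0
    n_significant: int = 0
    alpha: float = 0.01

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "stages": self.stages,
                    "outputs": {k: str(v) for k, v in self.outputs.items()},
                    "n_tested": self.n_tested,
                    "n_significant": self.n_significant,
                    "alpha": self.alpha,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _filter_config(cfg: dict) -> FilterConfig:
    f = cfg.get("filters", {})
    try:
        return FilterConfig(
            min_coverage=int(f.get("min_coverage", 30)),
            max_coverage=int(f.get("max_coverage", 500)),
            min_count=int(f.get("min_count", 8)),
            target_coverage=(
                int(f["target_coverage"])
                if f.get("target_coverage") is not None
                else None
            ),
            allowed_chroms=(
                frozenset(f["chroms"]) if f.get("chroms") else None
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"filters: {exc}") from exc


def _experiment_config(cfg: dict, seed: int) -> ExperimentConfig:
    e = cfg["experiment"]
    spectrum = e.get("spectrum", {})
    spike = e.get("spike", {})
    try:
        return ExperimentConfig(
            n_snps=int(e.get("n_snps", 100_000)),
            n_lines=int(e.get("n_lines", 202)),
            spectrum=SpectrumConfig(
                rate=float(spectrum.get("rate", 20.0)),
                upper_truncation=float(spectrum.get("truncation", 0.5)),
                n_snps=int(e.get("n_snps", 100_000)),
            ),
            coverages=tuple(e.get("coverages", (150, 170, 40, 70))),
            error_rate=float(e.get("error_rate", 0.0)),
            spike_fraction=float(spike.get("fraction", 0.0)),
            spike_delta=float(spike.get("delta", 0.0)),
            seed=seed,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"experiment: {exc}") from exc


def _pairs(cfg: dict) -> list[tuple[int, int]]:
    raw = cfg.get("pairs", [list(p) for p in DEFAULT_PAIRS])
    try:
        pairs = [(int(a), int(b)) for a, b in raw]
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"pairs: expected [[a, b], ...], got {raw!r}") from exc
    flat = [i for p in pairs for i in p]
    if len(set(flat)) != len(flat):
        raise ConfigError("pairs: population indices must be disjoint")
    return pairs


def maf_filter(
    table: pd.DataFrame, calls: list[SnpCall], min_maf: float
) -> pd.DataFrame:
    """Keep SNPs whose pooled (all populations) minor-allele frequency is at
    least ``min_maf``, then re-run BH on the retained subset."""
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    chroms, pos, maj, mino = calls_to_arrays(calls)
    pooled_min = mino.sum(axis=1)
    pooled_tot = (maj + mino).sum(axis=1)
    maf = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "maf": pooled_min / pooled_tot,
        }
    )
    out = table.merge(maf, on=["chrom", "pos"], how="left")
    out = out[out["maf"].to_numpy() >= min_maf].drop(columns="maf")
    out = out.reset_index(drop=True)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def _run_one_mapper(
    records, fcfg: FilterConfig, seed: int, stages: dict, tag: str
):
    summary = FilterSummary()
    calls = call_snps(records, fcfg, summary=summary)
    stages[f"call_snps{tag}"] = summary.as_dict()
    if fcfg.target_coverage is not None:
        calls = subsample_calls(calls, fcfg, seed)
    stages[f"subsample{tag}"] = {"n_sites": len(calls)}
    return calls


def run_pipeline(config, outdir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline described by ``config`` (YAML path or dict).

    Stages: [generate] -> mask -> call_snps -> subsample -> CMH ->
    [dual-mapper merge] -> [MAF filter] -> BH -> count significant.
    Writes calls, test results, a Manhattan-ready table and a manifest to
    ``outdir``; fully deterministic given the config seed.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", 0.01))
    correction = bool(cfg.get("continuity_correction", True))
    pairs = _pairs(cfg)
    fcfg = _filter_config(cfg)
    out = Path(outdir if outdir is not None else cfg.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config=cfg, seed=seed, alpha=alpha)
    stages = manifest.stages

    # --- inputs: synthetic experiment or existing sync file(s) -------------
    if "experiment" in cfg:
        ecfg = _experiment_config(cfg, derive_seed(seed, 1))
        records, truth = generate_experiment(ecfg)
        sync_path = out / "generated.sync"
        write_sync(records, sync_path)
        write_truth(truth, out / "truth.tsv")
        manifest.outputs["sync"] = sync_path
        manifest.outputs["truth"] = out / "truth.tsv"
        inputs = [records]
        stages["generate"] = {"n_snps": len(records)}
    elif "sync" in cfg:
        inputs = [read_sync(cfg["sync"])]
        if cfg.get("sync_b"):
            inputs.append(read_sync(cfg["sync_b"]))
        stages["read"] = {"n_sites": [len(r) for r in inputs]}
    else:
        raise ConfigError("config needs either an 'experiment' or a 'sync' key")

    if cfg.get("mask"):
        mask = MaskIntervalSet.from_bed(cfg["mask"])
        masked = [apply_mask(r, mask) for r in inputs]
        stages["mask"] = {
            "n_in": [len(r) for r in inputs],
            "n_out": [len(r) for r in masked],
        }
        inputs = masked

    # --- per-mapper calling, subsampling, testing --------------------------
    results = []
    calls_by_mapper = []
    for m, records in enumerate(inputs):
        tag = f"_m{m}" if len(inputs) > 1 else ""
        calls = _run_one_mapper(records, fcfg, derive_seed(seed, 2, m), stages, tag)
        calls_by_mapper.append(calls)
        results.append(cmh_test_calls(calls, pairs, continuity_correction=correction))

    if len(results) == 2:
        table = merge_dual_mappers(results[0], results[1])
        stages["merge"] = {
            "n_a": len(results[0]),
            "n_b": len(results[1]),
            "n_merged": len(table),
        }
    else:
        table = results[0]

    if cfg.get("min_maf") is not None:
        table = adjust_table(table)
        table = maf_filter(table, calls_by_mapper[0], float(cfg["min_maf"]))
        stages["maf_filter"] = {"n_out": len(table)}
    else:
        table = adjust_table(table)

    n_sig, hits = count_significant(table, alpha)
    manifest.n_tested = len(table)
    manifest.n_significant = n_sig
    stages["significant"] = {"alpha": alpha, "n_significant": n_sig}

    # --- outputs -----------------------------------------------------------
    write_calls(calls_by_mapper[0], out / "snps.tsv")
    table.to_csv(out / "cmh.tsv", sep="\t", index=False)
    manhattan = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "neglog10_p": -np.log10(np.maximum(table["p_value"].to_numpy(), 1e-300)),
        }
    )
    manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False)
    hits.to_csv(out / "significant.tsv", sep="\t", index=False)
    manifest.outputs.update(
        {
            "snps": out / "snps.tsv",
            "cmh": out / "cmh.tsv",
            "manhattan": out / "manhattan.tsv",
            "significant": out / "significant.tsv",
            "manifest": out / "manifest.json",
        }
    )
    manifest.to_json(out / "manifest.json")
    logger.info(
        "pipeline: %d SNPs tested, %d significant at FDR %g",
        manifest.n_tested,
        n_sig,
        alpha,
    )
    return manifest
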