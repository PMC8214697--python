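"""Pipeline orchestration: run configured analysis stages and write a
machine-readable summary.

A config is a mapping (or YAML file) with a ``stage`` key naming the
analysis (``kindred``, ``mutagen`` or ``offtarget``), a ``seed``, an
``outdir``, and stage-specific parameters.  Each run writes one TSV per
figure-style output plus ``summary.json``; reruns of the same config are
byte-identical.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .kindred import KindredModel
from .mutagenesis import dose_response_table, mutagen_unique_variants
from .offtarget import attribute_indels, attribute_svs, recurrence_filter
from .simulate import (
    simulate_edited_dataset,
    simulate_kindred_dataset,
    simulate_mutagen_dataset,
)
from .genome import read_fasta

logger = logging.getLogger("scwga")

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _stage_kindred(cfg: dict, outdir: Path, seed: int) -> dict:
    sim_kwargs = dict(cfg.get("simulate", {}))
    data = simulate_kindred_dataset(seed=seed, **sim_kwargs)
    res = KindredModel(
        data.bulk, data.cells, depths=data.depths,
        genome_mb=cfg.get("genome_mb", data.genome_mb),
        include_private_hq=cfg.get("include_private_hq", False),
    ).fit()
    _write_tsv(res.rates, outdir / "somatic_rates.tsv")
    _write_tsv(res.class_summary.per_cell, outdir / "per_cell_summary.tsv")
    counts = res.class_summary.class_counts
    per_cell = res.class_summary.per_cell
    return {
        "sensitivity": float(
            per_cell["germline_detected"].mean()
            / max(int(counts.get("germline", 0)), 1)),
        "precision": float(per_cell["precision"].mean()),
        "somatic_rate_per_mb": res.rate_mean,
        "somatic_rate_se": res.rate_se,
        "callable_mb": res.callable_mb,
        "class_counts": {k: int(v) for k, v in counts.items()},
    }


def _stage_mutagen(cfg: dict, outdir: Path, seed: int) -> dict:
    genome = read_fasta(cfg["genome_fasta"])
    data = simulate_mutagen_dataset(genome, seed=seed, **cfg.get("simulate", {}))
    per_cell = mutagen_unique_variants(data.cells, data.bulk, data.bulk_depths)
    meta = pd.DataFrame(
        [{"cell": c.sample, **c.meta} for c in data.cells]
    )
    table, groups = dose_response_table(per_cell, meta)
    _write_tsv(table, outdir / "mutagen_counts.tsv")
    _write_tsv(groups, outdir / "dose_response.tsv")
    return {
        "n_cells": len(data.cells),
        "total_mutagen_variants": int(table["count"].sum()),
        "group_means": {
            f"{r.compound}:{r.dose:g}": float(r.mean) for r in groups.itertuples()
        },
    }


def _stage_offtarget(cfg: dict, outdir: Path, seed: int) -> dict:
    genome = read_fasta(cfg["genome_fasta"])
    data = simulate_edited_dataset(
        genome, cfg["protospacer"], seed=seed, **cfg.get("simulate", {})
    )
    from .variants import CallSet

    bulk = CallSet(sample="bulk", role="bulk")
    att = attribute_indels(data.cells, {data.grna: data.sites}, bulk)
    filtered, removed = recurrence_filter(att.attributed)
    cell_grna = {c.sample: c.meta.get("grna", "control") for c in data.cells}
    svs = attribute_svs(data.breakpoints, {data.grna: data.sites}, cell_grna)
    _write_tsv(filtered, outdir / "attributed_indels.tsv")
    _write_tsv(att.presumed_fp, outdir / "presumed_fp_indels.tsv")
    _write_tsv(svs, outdir / "attributed_svs.tsv")
    return {
        "n_candidate_sites": len(data.sites),
        "attributed_indels": int(len(filtered)),
        "removed_nonrecurrent_1bp_ins": removed,
        "attributed_svs": int(len(svs)),
    }


def _stage_amplification(cfg: dict, outdir: Path, seed: int) -> dict:
    from .coverage import cv, gini, mapd, write_coverage_tsv
    from .simulate import SimConfig, pool_to_coverage, simulate_amplification

    genome = read_fasta(cfg["genome_fasta"])
    sim = SimConfig(**cfg.get("simulate", {}))
    pool = simulate_amplification(genome, sim, seed=seed)
    profile, _ = pool_to_coverage(
        pool, bin_size=cfg.get("bin_size", 1000),
        reads=cfg.get("reads", 10_000), seed=seed)
    write_coverage_tsv(profile, outdir / "coverage_bins.tsv")
    return {
        "mode": sim.mode,
        "amplicons": int(len(pool.daughters())),
        "mean_amplicon_length": float(pool.lengths[pool.daughters()].mean()),
        "cv": cv(profile), "mapd": mapd(profile), "gini": gini(profile),
    }


_STAGES = {
    "amplification": _stage_amplification,
    "kindred": _stage_kindred,
    "mutagen": _stage_mutagen,
    "offtarget": _stage_offtarget,
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stage; returns (and writes) the summary.

    Any stage failure aborts with the stage name and cause.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stage = config.get("stage")
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(_STAGES)}")
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage=%s seed=%d outdir=%s version=%s", stage, seed, outdir, __version__)
    try:
        summary = _STAGES[stage](config, outdir, seed)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    summary = {"stage": stage, "seed": seed, "version": __version__, **summary}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
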