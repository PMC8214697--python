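"""Mutagen-exposure analysis: per-cell mutation extraction, dose response,
and open-chromatin (DHS) enrichment.

A variant is attributed to the mutagen only if it was called in exactly one
cell and is absent from the bulk call set at a site the bulk covers with at
least 15 reads — absence can only be asserted where the bulk had power to
call.  Per-cell counts grouped by compound and dose give the dose-response
summary; comparing the fraction of mutations inside DNase-hypersensitive
sites (extended by two nucleosomes, 340 b, each side) with the fraction of
the well-covered genome inside those sites tests for chromatin-accessibility
enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    interval_length,
    intersect_intervals,
    merge_intervals,
    points_in_intervals,
)
from .variants import CallSet

__all__ = [
    "DhsPanel",
    "mutagen_unique_variants",
    "dose_response_table",
    "dhs_enrichment",
]


@dataclass
class DhsPanel:
    """DNase I hypersensitive intervals with nucleosome extension.

    ``intervals``: chrom -> half-open intervals.  ``extension`` bases are
    added on each side (two nucleosomes = 340 by default) and overlapping
    intervals merged.  ``min_depth`` is the per-base coverage a cell needs
    for a position to count as assayable.
    """

    intervals: dict[str, list[tuple[int, int]]]
    extension: int = 340
    min_depth: int = 10
    extended: dict[str, list[tuple[int, int]]] = field(init=False)

    def __post_init__(self):
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        self.extended = {
            chrom: merge_intervals(
                [(max(0, s - self.extension), e + self.extension) for s, e in ivs]
            )
            for chrom, ivs in self.intervals.items()
        }


def mutagen_unique_variants(
    cells: list[CallSet],
    bulk: CallSet,
    bulk_depths: pd.DataFrame,
    bulk_min_depth: int = 15,
) -> dict[str, pd.DataFrame]:
    """Per-cell mutagen-attributed variant sets.

    Keeps variants called in exactly one cell, absent from the bulk call
    set, at sites where the bulk depth (``bulk_depths``: chrom, pos, depth)
    is at least ``bulk_min_depth``.  Sets are pairwise disjoint by
    construction.
    """
    if bulk_depths is None or not {"chrom", "pos", "depth"} <= set(bulk_depths.columns):
        raise ValueError("bulk depth table with columns chrom, pos, depth is required")
    all_keys = pd.concat(
        [c.df[["chrom", "pos", "alt"]] for c in cells], ignore_index=True
    )
    n_cells_at = all_keys.groupby(["chrom", "pos", "alt"], sort=False).size()
    bulk_keys = set(zip(bulk.df["chrom"], bulk.df["pos"], bulk.df["alt"]))
    depth_at = {(c, p): d for c, p, d in
                zip(bulk_depths["chrom"], bulk_depths["pos"], bulk_depths["depth"])}

    out: dict[str, pd.DataFrame] = {}
    for cs in cells:
        keep = []
        for i, row in enumerate(cs.df.itertuples(index=False)):
            key = (row.chrom, row.pos, row.alt)
            if n_cells_at[key] != 1:
                continue
            if key in bulk_keys:
                continue
            if depth_at.get((row.chrom, row.pos), 0) < bulk_min_depth:
                continue
            keep.append(i)
        out[cs.sample] = cs.df.iloc[keep].reset_index(drop=True)
    return out


def dose_response_table(
    per_cell: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell mutagen counts with compound/dose group summaries.

    ``metadata`` has columns cell, compound, dose.  Returns (per-cell rows,
    group means/SDs/sizes ordered by compound then dose).
    """
    meta = metadata.set_index("cell")
    rows = []
    for cell, df in per_cell.items():
        if cell not in meta.index:
            raise ValueError(f"cell {cell!r} missing from metadata")
        rows.append({
            "compound": meta.loc[cell, "compound"],
            "dose": float(meta.loc[cell, "dose"]),
            "cell": cell,
            "count": len(df),
        })
    table = pd.DataFrame(rows).sort_values(
        ["compound", "dose", "cell"]).reset_index(drop=True)
    groups = (
        table.groupby(["compound", "dose"], sort=True)["count"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return table, groups


def dhs_enrichment(
    variants: pd.DataFrame,
    panel: DhsPanel,
    depth_intervals: pd.DataFrame,
) -> dict[str, float]:
    """Enrichment of mutations in covered DNase-hypersensitive sites.

    ``depth_intervals`` (chrom, start, end, depth) is the cell's coverage
    track; positions with depth >= panel.min_depth form the assayable
    genome.  Returns the proportion of variants inside covered DHS, the
    proportion of the assayable genome inside DHS, and their ratio (1 =
    no enrichment).
    """
    covered: dict[str, list[tuple[int, int]]] = {}
    for row in depth_intervals.itertuples(index=False):
        if row.depth >= panel.min_depth:
            covered.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    covered = {c: merge_intervals(ivs) for c, ivs in covered.items()}
    genome_cov = sum(interval_length(ivs) for ivs in covered.values())
    if genome_cov == 0:
        raise ValueError("no genome covered at the required depth")
    dhs_cov = sum(
        interval_length(intersect_intervals(covered.get(c, []), ivs))
        for c, ivs in panel.extended.items()
    )
    genome_prop = dhs_cov / genome_cov

    n_covered = n_in_dhs = 0
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        cov = points_in_intervals(pos, covered.get(chrom, []))
        n_covered += int(cov.sum())
        in_dhs = points_in_intervals(pos, panel.extended.get(chrom, []))
        n_in_dhs += int((cov & in_dhs).sum())
    snv_prop = n_in_dhs / n_covered if n_covered else np.nan
    ratio = snv_prop / genome_prop if genome_prop > 0 else np.nan
    return {
        "snv_in_dhs_prop": snv_prop,
        "genome_in_dhs_prop": genome_prop,
        "enrichment_ratio": ratio,
        "n_variants_covered": n_covered,
    }
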