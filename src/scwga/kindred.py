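"""Kindred-cell variant classification and somatic-rate estimation.

Kindred cells are single cells re-isolated from a clone grown out of one
founder cell; their genomes are near-identical, which lets the bulk sample
of the clone act as a ground-truth reference:

* **germline** — called in the bulk;
* **somatic** — absent from the bulk but called in >= 2 cells (a real
  founder mutation is inherited by every kindred cell, while amplification
  artefacts are private);
* **false positive** — absent from the bulk and private to one cell.

The per-cell somatic SNV rate divides the cell's high-quality somatic count
(DP >= 10, GQ >= 20, allele fraction >= 0.35) by the cell's high-quality
germline detection sensitivity and the callable span in Mb, so incomplete
detection cancels out of the estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .variants import CallSet

__all__ = [
    "callable_filter",
    "classify_variants",
    "summarize_classes",
    "estimate_somatic_rate",
    "ClassifiedVariants",
    "ClassSummary",
    "KindredModel",
    "KindredResults",
    "hq_mask",
    "GENOME_MB_GRCH38",
]

#: primary-assembly span of GRCh38 in Mb, used for genome-wide extrapolation
GENOME_MB_GRCH38 = 3088.0

#: high-quality call thresholds
HQ_MIN_DP = 10
HQ_MIN_GQ = 20
HQ_MIN_AF = 0.35


def hq_mask(dp, gq, vaf) -> np.ndarray:
    """High-quality call flag: DP >= 10, GQ >= 20, allele fraction >= 0.35."""
    dp = np.asarray(dp, dtype=float)
    gq = np.asarray(gq, dtype=float)
    vaf = np.asarray(vaf, dtype=float)
    return (dp >= HQ_MIN_DP) & (gq >= HQ_MIN_GQ) & (vaf >= HQ_MIN_AF)


def callable_filter(
    depths: pd.DataFrame,
    bulk_min: int = 15,
    cell_min: int = 5,
    cell_frac: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Callable-site mask and callable span in Mb.

    ``depths`` has columns chrom, pos, bulk, one column per cell, and
    optionally span_bp (bases of genome each depth row represents; default
    1, i.e. a per-base track).  A site is callable when the bulk depth is
    >= ``bulk_min`` and at least ceil(cell_frac * n_cells) cells have depth
    >= ``cell_min``.
    """
    reserved = {"chrom", "pos", "bulk", "span_bp"}
    cell_cols = [c for c in depths.columns if c not in reserved]
    if not cell_cols:
        raise ValueError("depth table has no cell columns")
    need = ceil(cell_frac * len(cell_cols))
    enough_cells = (depths[cell_cols].to_numpy() >= cell_min).sum(axis=1) >= need
    mask = (depths["bulk"].to_numpy() >= bulk_min) & enough_cells
    span = depths["span_bp"].to_numpy(dtype=float) if "span_bp" in depths.columns \
        else np.ones(len(depths))
    callable_mb = float(span[mask].sum() / 1e6)
    return mask, callable_mb


@dataclass
class ClassifiedVariants:
    """Variant classification against the bulk reference.

    ``variants`` — one row per distinct (chrom, pos, alt): ref, label,
    n_cells (number of carrier cells).
    ``carriers`` — one row per (variant, cell) call: variant row index,
    cell id, dp, gq, vaf, gt, hq.
    ``bulk`` — one row per bulk call: variant row index, dp, gq, vaf, gt, hq.
    """

    variants: pd.DataFrame
    carriers: pd.DataFrame
    bulk: pd.DataFrame
    cell_ids: list[str] = field(default_factory=list)

    def counts(self) -> pd.Series:
        return self.variants["label"].value_counts()


class _StringCoder:
    """Shared integer coding for string columns across frames.

    Categorical columns are mapped through their (small) category lists so
    multi-million-row inputs never pass through a string hash.
    """

    def __init__(self):
        self.index: dict[str, int] = {}

    def codes(self, series: pd.Series) -> np.ndarray:
        if isinstance(series.dtype, pd.CategoricalDtype):
            local = list(series.cat.categories)
            local_codes = series.cat.codes.to_numpy()
        else:
            local_codes, local_arr = pd.factorize(series)
            local = list(local_arr)
        remap = np.array(
            [self.index.setdefault(str(c), len(self.index)) for c in local],
            dtype=np.int64,
        ) if local else np.array([], dtype=np.int64)
        out = np.full(len(local_codes), -1, dtype=np.int64)
        valid = local_codes >= 0
        out[valid] = remap[local_codes[valid]]
        return out

    def labels(self) -> np.ndarray:
        out = np.empty(len(self.index), dtype=object)
        for s, i in self.index.items():
            out[i] = s
        return out


def _group_keys(key: np.ndarray):
    """(first_index, inverse) of distinct key values, stable order of firsts."""
    order = np.argsort(key, kind="stable")
    sk = key[order]
    new = np.empty(len(sk), dtype=bool)
    if len(sk):
        new[0] = True
        new[1:] = sk[1:] != sk[:-1]
    inverse = np.empty(len(sk), dtype=np.int64)
    inverse[order] = np.cumsum(new) - 1
    return order[new], inverse


def classify_variants(
    bulk: CallSet,
    cells: list[CallSet],
    callable_sites: pd.DataFrame | None = None,
) -> ClassifiedVariants:
    """Label every distinct variant germline / somatic / false_positive.

    ``callable_sites`` (chrom, pos) restricts all call sets to callable
    positions first.  Variant identity is (chrom, pos, alt); every variant
    gets exactly one label.
    """
    if not cells:
        raise ValueError("classification needs at least one cell")
    frames = [bulk.df] + [c.df for c in cells]
    chrom_coder, allele_coder, gt_coder = _StringCoder(), _StringCoder(), _StringCoder()

    cols: dict[str, list[np.ndarray]] = {
        "chrom": [], "pos": [], "ref": [], "alt": [],
        "dp": [], "gq": [], "ad_ref": [], "ad_alt": [], "gt": [], "sample": [],
    }
    for i, f in enumerate(frames):
        cols["chrom"].append(chrom_coder.codes(f["chrom"]))
        cols["pos"].append(f["pos"].to_numpy(dtype=np.int64))
        cols["ref"].append(allele_coder.codes(f["ref"]))
        cols["alt"].append(allele_coder.codes(f["alt"]))
        cols["gt"].append(gt_coder.codes(f["gt"]))
        for c in ("dp", "gq", "ad_ref", "ad_alt"):
            cols[c].append(f[c].to_numpy(dtype=np.int32))
        cols["sample"].append(np.full(len(f), i, dtype=np.int64))
    chrom_c, pos, ref_c, alt_c, gt_c, sample_idx = (
        np.concatenate(cols[c]) if cols[c] else np.array([], dtype=np.int64)
        for c in ("chrom", "pos", "ref", "alt", "gt", "sample")
    )
    dp, gq, ad_ref, ad_alt = (np.concatenate(cols[c]) for c in ("dp", "gq", "ad_ref", "ad_alt"))

    width = int(pos.max()) + 2 if len(pos) else 2
    site_key = chrom_c * width + pos
    if callable_sites is not None:
        ok = np.unique(
            chrom_coder.codes(callable_sites["chrom"]) * width
            + callable_sites["pos"].to_numpy(dtype=np.int64)
        )
        j = np.searchsorted(ok, site_key)
        j[j == len(ok)] = 0
        keep = (ok[j] == site_key) if len(ok) else np.zeros(len(site_key), dtype=bool)
        (site_key, chrom_c, pos, ref_c, alt_c, gt_c, sample_idx,
         dp, gq, ad_ref, ad_alt) = (
            a[keep] for a in (site_key, chrom_c, pos, ref_c, alt_c, gt_c,
                              sample_idx, dp, gq, ad_ref, ad_alt))

    n_alleles = max(len(allele_coder.index), 1)
    key = site_key * (n_alleles + 1) + alt_c
    first, inverse = _group_keys(key)
    n_var = len(first)

    in_bulk = np.zeros(n_var, dtype=bool)
    in_bulk[inverse[sample_idx == 0]] = True
    n_carriers = np.bincount(inverse[sample_idx > 0], minlength=n_var).astype(np.int64)
    label_codes = np.where(in_bulk, 0, np.where(n_carriers >= 2, 1, 2)).astype(np.int8)
    label = pd.Categorical.from_codes(
        label_codes, categories=["germline", "somatic", "false_positive"])

    chrom_labels = chrom_coder.labels()
    allele_labels = allele_coder.labels()
    gt_labels = gt_coder.labels()
    variants = pd.DataFrame({
        "chrom": chrom_labels[chrom_c[first]],
        "pos": pos[first],
        "ref": allele_labels[ref_c[first]],
        "alt": allele_labels[alt_c[first]],
        "label": label,
        "n_cells": n_carriers,
    })

    tot = (ad_ref + ad_alt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(tot > 0, ad_alt.astype(float) / tot, np.nan)
    hq = hq_mask(dp, gq, vaf)

    cell_ids = [c.sample for c in cells]
    is_cell = sample_idx > 0
    carriers = pd.DataFrame({
        "variant": inverse[is_cell],
        "cell": pd.Categorical.from_codes(sample_idx[is_cell] - 1, categories=cell_ids),
        "dp": dp[is_cell],
        "gq": gq[is_cell],
        "vaf": vaf[is_cell],
        "gt": pd.Categorical.from_codes(
            gt_c[is_cell].astype(np.int8), categories=list(gt_coder.index)),
        "hq": hq[is_cell],
    })
    is_bulk = sample_idx == 0
    bulk_df = pd.DataFrame({
        "variant": inverse[is_bulk],
        "dp": dp[is_bulk],
        "gq": gq[is_bulk],
        "vaf": vaf[is_bulk],
        "gt": pd.Categorical.from_codes(
            gt_c[is_bulk].astype(np.int8), categories=list(gt_coder.index)),
        "hq": hq[is_bulk],
    })
    return ClassifiedVariants(
        variants=variants, carriers=carriers, bulk=bulk_df, cell_ids=cell_ids
    )


@dataclass
class ClassSummary:
    """Per-class counts, heterozygous-call fractions, and per-cell precision."""

    class_counts: pd.Series
    het_fraction: pd.Series          # fraction of carrier calls that are 0/1
    per_cell: pd.DataFrame           # cell, germline_detected, fp_count, precision


def summarize_classes(classified: ClassifiedVariants) -> ClassSummary:
    """Summarise a classification: counts, het fractions, germline precision.

    Per-cell germline precision = germline detected in the cell /
    (germline detected + false positives private to that cell).
    """
    cv = classified
    counts = cv.variants["label"].value_counts()
    lab = cv.variants["label"].to_numpy()
    carrier_label = lab[cv.carriers["variant"].to_numpy()]
    is_het = (cv.carriers["gt"] == "0/1").to_numpy()
    het = pd.Series({
        cls: float(is_het[carrier_label == cls].mean())
        if (carrier_label == cls).any() else np.nan
        for cls in ("germline", "somatic", "false_positive")
    })

    rows = []
    for cell in cv.cell_ids:
        mine = cv.carriers["cell"] == cell
        germ = int((carrier_label[mine.to_numpy()] == "germline").sum())
        fp = int((carrier_label[mine.to_numpy()] == "false_positive").sum())
        precision = germ / (germ + fp) if germ + fp else np.nan
        rows.append({"cell": cell, "germline_detected": germ,
                     "fp_count": fp, "precision": precision})
    return ClassSummary(class_counts=counts, het_fraction=het,
                        per_cell=pd.DataFrame(rows))


def estimate_somatic_rate(
    classified: ClassifiedVariants,
    callable_mb: float,
    genome_mb: float = GENOME_MB_GRCH38,
    include_private_hq: bool = False,
) -> pd.DataFrame:
    """Sensitivity-corrected per-cell somatic SNV rate (per Mb).

    For each cell: rate = (high-quality somatic calls carried by the cell)
    / (high-quality germline sensitivity x callable Mb), extrapolated
    genome-wide by ``genome_mb``.  Sensitivity is estimated from
    bulk-heterozygous germline variants whose bulk call passes the same HQ
    filters — the cell's HQ recovery of those variants — keeping numerator
    and denominator filters identical so the correction is internally
    consistent (somatic variants are heterozygous single-allele events).

    ``include_private_hq`` additionally counts HQ private calls as somatic,
    for the looser reading under which the rate is an upper bound.
    """
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    cv = classified
    lab = cv.variants["label"].to_numpy()
    germ_het_hq = np.zeros(len(cv.variants), dtype=bool)
    b = cv.bulk
    bulk_ok = b.loc[(b["gt"] == "0/1") & b["hq"], "variant"].to_numpy()
    germ_het_hq[bulk_ok] = True
    germ_het_hq &= lab == "germline"
    denom = int(germ_het_hq.sum())

    carrier_var = cv.carriers["variant"].to_numpy()
    carrier_hq = cv.carriers["hq"].to_numpy()
    carrier_label = lab[carrier_var]

    rows = []
    for cell in cv.cell_ids:
        mine = (cv.carriers["cell"] == cell).to_numpy()
        num = int((mine & carrier_hq & germ_het_hq[carrier_var]).sum())
        sens = num / denom if denom else 0.0
        if sens <= 0:
            warnings.warn(f"cell {cell}: zero HQ germline sensitivity; estimate dropped")
            continue
        somatic_hq = int((mine & carrier_hq & (carrier_label == "somatic")).sum())
        if include_private_hq:
            somatic_hq += int((mine & carrier_hq & (carrier_label == "false_positive")).sum())
        rate = somatic_hq / (sens * callable_mb)
        rows.append({
            "cell": cell, "somatic_hq": somatic_hq, "sensitivity": sens,
            "callable_mb": callable_mb, "rate_per_mb": rate,
            "genome_wide": rate * genome_mb,
        })
    if not rows:
        raise ValueError("no cell had nonzero HQ germline sensitivity")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class KindredModel:
    """Kindred-cell analysis as a fit-able model.

    Parameters
    ----------
    bulk, cells
        The clone's bulk call set and the re-isolated single-cell call sets.
    depths
        Optional depth table (chrom, pos, bulk, per-cell columns,
        optional span_bp) for the callable-site filter.  Without it every
        site is callable and ``callable_mb`` must be given.
    """

    def __init__(self, bulk: CallSet, cells: list[CallSet],
                 depths: pd.DataFrame | None = None,
                 callable_mb: float | None = None,
                 bulk_min: int = 15, cell_min: int = 5, cell_frac: float = 0.5,
                 genome_mb: float = GENOME_MB_GRCH38,
                 include_private_hq: bool = False):
        if depths is None and callable_mb is None:
            raise ValueError("need a depth table or an explicit callable_mb")
        self.bulk, self.cells, self.depths = bulk, cells, depths
        self.callable_mb = callable_mb
        self.bulk_min, self.cell_min, self.cell_frac = bulk_min, cell_min, cell_frac
        self.genome_mb = genome_mb
        self.include_private_hq = include_private_hq

    def fit(self) -> "KindredResults":
        callable_sites = None
        callable_mb = self.callable_mb
        if self.depths is not None:
            mask, est_mb = callable_filter(
                self.depths, self.bulk_min, self.cell_min, self.cell_frac)
            callable_sites = self.depths.loc[mask, ["chrom", "pos"]]
            if callable_mb is None:
                callable_mb = est_mb
        classified = classify_variants(self.bulk, self.cells, callable_sites)
        summary = summarize_classes(classified)
        rates = estimate_somatic_rate(
            classified, callable_mb, self.genome_mb, self.include_private_hq)
        return KindredResults(self, classified, summary, rates, callable_mb)


@dataclass
class KindredResults:
    """Fitted kindred analysis: classification, summaries, rate estimates."""

    model: KindredModel
    classified: ClassifiedVariants
    class_summary: ClassSummary
    rates: pd.DataFrame
    callable_mb: float

    @property
    def rate_mean(self) -> float:
        return float(self.rates["rate_per_mb"].mean())

    @property
    def rate_se(self) -> float:
        r = self.rates["rate_per_mb"]
        return float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan

    def summary(self) -> str:
        counts = self.class_summary.class_counts
        lines = [
            "Kindred-cell somatic rate analysis",
            "=" * 50,
            f"cells: {len(self.classified.cell_ids)}   callable Mb: {self.callable_mb:,.1f}",
            "variant classes: " + ", ".join(
                f"{k}={counts.get(k, 0):,}" for k in
                ("germline", "somatic", "false_positive")),
            f"mean germline precision: "
            f"{self.class_summary.per_cell['precision'].mean():.4%}",
            "-" * 50,
            self.rates.to_string(
                index=False,
                formatters={"rate_per_mb": "{:.3f}".format,
                            "sensitivity": "{:.3f}".format,
                            "genome_wide": "{:,.0f}".format,
                            "callable_mb": "{:,.0f}".format},
            ),
            "-" * 50,
            f"somatic SNV rate: {self.rate_mean:.3f} +/- {self.rate_se:.3f} per Mb "
            f"(mean +/- SE over cells)",
        ]
        return "\n".join(lines)
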