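"""Bulk-referenced single-cell variant metrics and mutation spectra.

Sensitivity, discordance and allelic-skew metrics treat the unamplified
bulk sample as the reference: variants found in the cell but not the bulk
are "discordant" (false positives plus true somatic variants), and allele
fractions at bulk-heterozygous sites quantify allelic dropout (ADO) and
amplification skew.

Spectrum machinery collapses substitutions to the pyrimidine-reference
convention (G>A becomes C>T on the opposite strand) and tabulates either
the 6 base-change classes or the 96 trinucleotide channels; observed
spectra can be reconstructed as a non-negative combination of reference
signatures (non-negative least squares) with a cosine-similarity score.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genome import Genome
from .variants import CallSet

__all__ = [
    "snv_sensitivity",
    "discordant_calls",
    "het_allele_metrics",
    "base_change_spectrum",
    "trinucleotide_spectrum",
    "SignatureSet",
    "reconstruct_signature",
    "SPECTRUM_CLASSES",
    "CHANNELS_96",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS_96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in SPECTRUM_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _key_frame(cs: CallSet) -> pd.DataFrame:
    return cs.df[["chrom", "pos", "alt"]]


def snv_sensitivity(cell: CallSet, bulk: CallSet) -> float:
    """Fraction of bulk variants recovered in the cell.

    Matching is on (chrom, pos, alt); a genotype mismatch (0/1 vs 1/1)
    still counts as detected.
    """
    if len(bulk) == 0:
        raise ValueError("bulk call set is empty")
    shared = _key_frame(bulk).merge(_key_frame(cell), how="inner")
    return len(shared) / len(bulk)


def discordant_calls(cell: CallSet, bulk: CallSet) -> tuple[pd.DataFrame, float, np.ndarray]:
    """Cell calls absent from the bulk, with their allele fractions.

    Returns (discordant records, discordant rate = count / cell calls,
    VAF array).  In a normal diploid sample these are false positives plus
    true somatic variants.
    """
    if len(cell) == 0:
        return cell.df.copy(), 0.0, np.array([])
    merged = cell.df.merge(
        _key_frame(bulk).assign(_in_bulk=True), how="left",
        on=["chrom", "pos", "alt"],
    )
    disc_mask = merged["_in_bulk"].isna().to_numpy()
    disc = cell.df.loc[disc_mask].reset_index(drop=True)
    vafs = cell.vaf.to_numpy()[disc_mask]
    return disc, len(disc) / len(cell), vafs


def het_allele_metrics(
    cell: CallSet,
    bulk: CallSet,
    min_depth: int = 10,
    ado_bounds: tuple[float, float] = (0.1, 0.9),
    cell_depths: pd.DataFrame | None = None,
) -> tuple[np.ndarray, float]:
    """Allele fractions and ADO rate at bulk-heterozygous sites.

    Evaluable sites are bulk 0/1 sites where the cell has depth >=
    ``min_depth`` — either from its own call record or, for uncalled sites,
    from ``cell_depths`` (chrom, pos, depth).  An allelic-dropout event is a
    VAF outside ``ado_bounds``, or an uncalled site with sufficient
    coverage (the alt allele dropped out entirely).
    """
    het = bulk.df[bulk.df["gt"] == "0/1"]
    if len(het) == 0:
        raise ValueError("bulk has no heterozygous sites")
    merged = het[["chrom", "pos", "alt"]].merge(
        cell.df[["chrom", "pos", "alt", "dp", "ad_ref", "ad_alt"]],
        how="left", on=["chrom", "pos", "alt"],
    )
    called = merged["dp"].notna() & (merged["dp"] >= min_depth)
    tot = merged["ad_ref"] + merged["ad_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = (merged["ad_alt"] / tot.where(tot > 0)).to_numpy(dtype=float)

    uncalled_covered = np.zeros(len(merged), dtype=bool)
    if cell_depths is not None:
        dd = merged[["chrom", "pos"]].merge(
            cell_depths[["chrom", "pos", "depth"]], how="left", on=["chrom", "pos"]
        )
        uncalled_covered = (
            merged["dp"].isna() & (dd["depth"] >= min_depth)
        ).to_numpy()

    evaluable = called.to_numpy() | uncalled_covered
    if not evaluable.any():
        raise ValueError("no evaluable bulk-het sites at the requested depth")
    lo, hi = ado_bounds
    vaf_eval = vaf[called.to_numpy()]
    ado_events = int(((vaf_eval < lo) | (vaf_eval > hi)).sum()) + int(uncalled_covered.sum())
    return vaf_eval, ado_events / int(evaluable.sum())


def _collapse(ref: str, alt: str, context: str | None):
    """Map a substitution to the pyrimidine-reference class and context."""
    if ref in "CT":
        return f"{ref}>{alt}", context
    rc_ctx = None
    if context is not None:
        rc_ctx = "".join(_COMPLEMENT[b] for b in reversed(context))
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}", rc_ctx


def base_change_spectrum(variants: pd.DataFrame, genome: Genome | None = None) -> pd.Series:
    """Count the 6 pyrimidine-reference base-change classes.

    ``variants`` needs chrom, pos, ref, alt.  Non-SNV rows (ref/alt not a
    single base) are ignored.
    """
    counts = pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=np.int64)
    for row in variants.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1 or row.ref == row.alt:
            continue
        if row.ref not in "ACGT" or row.alt not in "ACGT":
            continue
        cls, _ = _collapse(row.ref, row.alt, None)
        counts[cls] += 1
    return counts


def trinucleotide_spectrum(
    variants: pd.DataFrame, genome: Genome
) -> tuple[pd.Series, int]:
    """96-channel single-base-substitution spectrum.

    Channels are keyed 5'base[class]3'base in the pyrimidine convention.
    Variants at sequence edges or with N in the context are skipped;
    returns (channel counts, number skipped).  Channel totals equal the
    number of spectrum-eligible SNVs.
    """
    counts = pd.Series(0, index=list(CHANNELS_96), dtype=np.int64)
    skipped = 0
    for row in variants.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1 or row.ref == row.alt:
            continue
        if row.ref not in "ACGT" or row.alt not in "ACGT":
            continue
        ctx = genome.trinucleotide(row.chrom, int(row.pos))
        if ctx is None:
            skipped += 1
            continue
        if ctx[1] != row.ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"genome has {ctx[1]}, record says {row.ref}")
        cls, ctx = _collapse(row.ref, row.alt, ctx)
        counts[f"{ctx[0]}[{cls}]{ctx[2]}"] += 1
    return counts, skipped


@dataclass
class SignatureSet:
    """NNLS decomposition of a 96-channel spectrum over reference signatures."""

    reference: pd.DataFrame       # 96 x k, columns sum to 1
    exposures: pd.Series          # k, >= 0
    reconstruction: np.ndarray    # 96
    cosine: float


def reconstruct_signature(spectrum, reference: pd.DataFrame) -> SignatureSet:
    """Decompose a spectrum into non-negative reference-signature exposures.

    Solves min ||s - M e||_2 subject to e >= 0 where M holds the reference
    signatures column-wise; reports the cosine similarity between the
    observed spectrum and the reconstruction M e.
    """
    s = np.asarray(spectrum, dtype=float).ravel()
    M = reference.to_numpy(dtype=float)
    if M.shape[0] != s.shape[0]:
        raise ValueError(f"spectrum has {s.shape[0]} channels, reference has {M.shape[0]}")
    if M.shape[1] < 1:
        raise ValueError("reference matrix needs >= 1 signature")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    s = s / total
    e, _ = nnls(M, s)
    recon = M @ e
    denom = np.linalg.norm(s) * np.linalg.norm(recon)
    cos = float(s @ recon / denom) if denom > 0 else 0.0
    return SignatureSet(
        reference=reference,
        exposures=pd.Series(e, index=reference.columns),
        reconstruction=recon,
        cosine=cos,
    )
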