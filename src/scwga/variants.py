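"""Variant call containers and minimal VCF I/O.

A :class:`CallSet` holds one sample's calls as a pandas DataFrame so that
multi-million-site kindred analyses stay vectorised.  Positions are 0-based
internally; the VCF boundary (pysam) converts to/from 1-based.

The VCF dialect is deliberately minimal: biallelic SNVs/indels with
FORMAT ``GT:DP:GQ:AD``.  Multiallelic records are split into biallelic
records on read.  Allele fraction is always recomputed as alt/(ref+alt)
from AD, never trusted from an AF tag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

__all__ = ["VariantRecord", "CallSet", "read_vcf_min", "write_vcf", "variant_keys"]

#: dtypes of the canonical CallSet frame
_COLUMNS = {
    "chrom": object,
    "pos": np.int64,      # 0-based
    "ref": object,
    "alt": object,
    "dp": np.int64,       # -1 = missing
    "gq": np.int64,       # -1 = missing
    "ad_ref": np.int64,
    "ad_alt": np.int64,
    "gt": object,         # '0/0', '0/1', '1/1', './.'
}

_VALID_GT = {"0/0", "0/1", "1/1", "./."}


class VariantRecord(NamedTuple):
    """One biallelic call for one sample (pos is 0-based internally)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dp: int
    gq: int
    ad_ref: int
    ad_alt: int
    gt: str


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _COLUMNS.items()})


@dataclass
class CallSet:
    """Per-sample variant calls.

    Parameters
    ----------
    sample
        Sample identifier (VCF column name).
    role
        ``"bulk"`` or ``"cell"``.
    df
        Frame with columns chrom, pos (0-based), ref, alt, dp, gq, ad_ref,
        ad_alt, gt.  (chrom, pos, alt) must be unique.
    meta
        Free-form cell metadata (dose, gRNA received, kit, ...).
    """

    sample: str
    role: str = "cell"
    df: pd.DataFrame = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("bulk", "cell"):
            raise ValueError(f"role must be 'bulk' or 'cell', got {self.role!r}")
        if self.df is None:
            self.df = empty_frame()
        missing = set(_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"CallSet frame missing columns {sorted(missing)}")
        if len(self.df):
            pos = self.df["pos"].to_numpy()
            # strictly increasing positions on a single chromosome are
            # unique without a (costly) hash-based duplicate scan
            sorted_unique = (
                self.df["chrom"].nunique() <= 1
                and (len(pos) < 2 or bool((np.diff(pos) > 0).all()))
            )
            dup = (
                pd.Series(False, index=self.df.index) if sorted_unique
                else self.df.duplicated(subset=["chrom", "pos", "alt"])
            )
            if dup.any():
                i = int(np.flatnonzero(dup.to_numpy())[0])
                row = self.df.iloc[i]
                raise ValueError(
                    f"duplicate variant ({row.chrom}, {row.pos}, {row.alt}) "
                    f"in sample {self.sample!r}"
                )
            bad_gt = ~self.df["gt"].isin(_VALID_GT)
            if bad_gt.any():
                raise ValueError(f"invalid genotype {self.df.loc[bad_gt, 'gt'].iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def vaf(self) -> pd.Series:
        """Alt allele fraction alt/(ref+alt); NaN where AD is missing/zero."""
        tot = self.df["ad_ref"] + self.df["ad_alt"]
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.df["ad_alt"] / tot.where(tot > 0)).astype(float)

    def keys(self) -> pd.Index:
        return variant_keys(self.df)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                row.chrom, int(row.pos), row.ref, row.alt,
                int(row.dp), int(row.gq), int(row.ad_ref), int(row.ad_alt), row.gt,
            )

    @classmethod
    def from_records(cls, sample, records, role="cell", meta=None) -> "CallSet":
        rows = [tuple(r) for r in records]
        df = pd.DataFrame(rows, columns=list(_COLUMNS)) if rows else empty_frame()
        return cls(sample=sample, role=role, df=df, meta=meta or {})


def variant_keys(df: pd.DataFrame) -> pd.Index:
    """Site identity index (chrom, pos, alt); genotype deliberately excluded."""
    return pd.MultiIndex.from_arrays(
        [df["chrom"], df["pos"], df["alt"]], names=["chrom", "pos", "alt"]
    )


def read_vcf_min(path, roles: dict[str, str] | None = None) -> list[CallSet]:
    """Read a minimal VCF into one CallSet per sample column.

    Multiallelic records are split into biallelic records; AD is carried as
    (ref depth, that alt's depth).  Records where a sample's genotype is
    missing or hom-ref are not calls for that sample.  Missing FORMAT keys
    produce a single warning and -1 fields.
    """
    roles = roles or {}
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows: dict[str, list] = {s: [] for s in samples}
    warned = set()
    for rec in vf:
        alts = rec.alts or ()
        for alt_idx, alt in enumerate(alts, start=1):
            for s in samples:
                call = rec.samples[s]
                gt_raw = call.get("GT")
                if gt_raw is None or all(a is None for a in gt_raw):
                    continue
                alleles = [0 if a is None else a for a in gt_raw]
                if alt_idx not in alleles:
                    continue
                n_alt = alleles.count(alt_idx)
                gt = "1/1" if n_alt == 2 else "0/1"
                dp = call.get("DP")
                gq = call.get("GQ")
                ad = call.get("AD")
                for key, val in (("DP", dp), ("GQ", gq), ("AD", ad)):
                    if val is None and (s, key) not in warned:
                        warnings.warn(f"sample {s}: FORMAT {key} missing; set to -1")
                        warned.add((s, key))
                ad_ref, ad_alt = (-1, -1)
                if ad is not None and len(ad) > alt_idx and ad[0] is not None:
                    ad_ref = int(ad[0])
                    ad_alt = int(ad[alt_idx]) if ad[alt_idx] is not None else -1
                rows[s].append(
                    (rec.chrom, rec.pos - 1, rec.ref, alt,
                     -1 if dp is None else int(dp), -1 if gq is None else int(gq),
                     ad_ref, ad_alt, gt)
                )
    out = []
    for s in samples:
        df = pd.DataFrame(rows[s], columns=list(_COLUMNS)) if rows[s] else empty_frame()
        out.append(CallSet(sample=s, role=roles.get(s, "cell"), df=df))
    return out


def write_vcf(callsets: list[CallSet], path, contigs: dict[str, int] | None = None) -> None:
    """Write CallSets as a single minimal VCF 4.2 with FORMAT GT:DP:GQ:AD."""
    if contigs is None:
        contigs = {}
        for cs in callsets:
            for chrom, pos in zip(cs.df["chrom"], cs.df["pos"]):
                contigs[chrom] = max(contigs.get(chrom, 0), int(pos) + 1000)
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    for cs in callsets:
        header.add_sample(cs.sample)
    gt_map = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}

    # collate records across samples on (chrom, pos, ref, alt)
    site_map: dict[tuple, dict[str, VariantRecord]] = {}
    for cs in callsets:
        for r in cs.records():
            site_map.setdefault((r.chrom, r.pos, r.ref, r.alt), {})[cs.sample] = r

    order = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(site_map, key=lambda k: (order.get(k[0], 1 << 30), k[1], k[3])):
            chrom, pos, ref, alt = key
            rec = out.new_record(contig=chrom, start=pos, alleles=(ref, alt))
            for cs in callsets:
                call = rec.samples[cs.sample]
                r = site_map[key].get(cs.sample)
                if r is None:
                    call["GT"] = (None, None)
                else:
                    call["GT"] = gt_map[r.gt]
                    if r.dp >= 0:
                        call["DP"] = r.dp
                    if r.gq >= 0:
                        call["GQ"] = r.gq
                    if r.ad_ref >= 0:
                        call["AD"] = (r.ad_ref, r.ad_alt)
            out.write(rec)
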