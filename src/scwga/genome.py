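"""Genome sequences, masked intervals, and BED/FASTA I/O.

Coordinates are 0-based half-open everywhere inside the package; BED shares
that convention so no conversion happens at the BED boundary.  VCF positions
are converted in :mod:`scwga.variants`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "write_intervals",
    "merge_intervals",
    "intersect_intervals",
    "interval_length",
    "points_in_intervals",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def merge_intervals(intervals):
    """Merge overlapping/adjacent half-open intervals; returns sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a, b):
    """Intersection of two merged half-open interval lists."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def interval_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def points_in_intervals(points, intervals) -> np.ndarray:
    """Boolean mask: which points fall inside the merged intervals."""
    merged = merge_intervals(intervals)
    pts = np.asarray(points, dtype=np.int64)
    if not merged:
        return np.zeros(pts.shape, dtype=bool)
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    ends = np.array([e for _, e in merged], dtype=np.int64)
    idx = np.searchsorted(starts, pts, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pts[ok] < ends[idx[ok]]
    return ok


@dataclass
class Genome:
    """Named sequences with per-chromosome masked intervals.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> upper-case sequence string (ACGTN).
    masks
        Mapping chromosome name -> list of half-open (start, end) intervals
        excluded from coverage statistics (assembly gaps, segmental
        duplications).
    """

    sequences: dict[str, str]
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}
        for name, ivs in self.masks.items():
            if name not in self.sequences:
                raise ValueError(f"mask for unknown sequence {name!r}")
            L = len(self.sequences[name])
            for s, e in ivs:
                if not (0 <= s <= e <= L):
                    raise ValueError(f"mask [{s},{e}) outside {name!r} (length {L})")
        self.masks = {name: merge_intervals(ivs) for name, ivs in self.masks.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def trinucleotide(self, chrom: str, pos: int) -> str | None:
        """Trinucleotide context centred on pos; None at edges or with N."""
        seq = self.sequences[chrom]
        if pos < 1 or pos >= len(seq) - 1:
            return None
        ctx = seq[pos - 1 : pos + 2]
        return None if "N" in ctx else ctx

    def reverse_complemented(self) -> "Genome":
        rc = {n: s.translate(_COMPLEMENT)[::-1] for n, s in self.sequences.items()}
        masks = {
            n: [(len(self.sequences[n]) - e, len(self.sequences[n]) - s) for s, e in ivs]
            for n, ivs in self.masks.items()
        }
        return Genome(rc, masks)


def read_fasta(path) -> Genome:
    """Read a FASTA file; sequences are upper-cased, N is allowed."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return Genome(seqs)


def write_fasta(genome: Genome, path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in genome.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 (0-based half-open) into chrom -> interval list."""
    out: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields: {line!r}")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end < start:
            raise ValueError(f"{path}:{lineno}: end < start")
        out.setdefault(chrom, []).append((start, end))
    return out


def write_intervals(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
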