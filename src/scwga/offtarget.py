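"""CRISPR off-target analysis: candidate-site enumeration and per-cell
indel/SV attribution.

Candidate sites are all genomic 23-mers on either strand whose last two
bases are GG (the N of NGG is free) and whose first 20 bases differ from
the gRNA protospacer at no more than five positions.  The canonical SpCas9
cleavage site — the blunt cut between protospacer positions 17 and 18,
3 bp 5' of the PAM — anchors the attribution windows: indels must fall
within +/- 50 bp of a cleavage site for the cell's gRNA, structural
variants need both breakpoints within +/- 200 bp of (possibly different)
cleavage sites.  Indels present in the bulk or in any cell that received a
different gRNA are excluded; non-recurrent single-base insertions — the
dominant artefact class in control cells — are removed by the recurrence
filter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .variants import CallSet

__all__ = [
    "ProtospacerQuery",
    "CandidateSite",
    "enumerate_candidate_sites",
    "attribute_indels",
    "recurrence_filter",
    "attribute_svs",
    "IndelAttribution",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ProtospacerQuery:
    """A 20-nt protospacer searched with an NGG PAM and a mismatch budget."""

    protospacer: str
    max_mismatches: int = 5

    def __post_init__(self):
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer alphabet must be ACGT")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class CandidateSite:
    """A genomic 23-mer matching the query; cleavage is the blunt-cut
    boundary coordinate 3 bp 5' of the PAM (between protospacer positions
    17 and 18), always in forward-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    cleavage: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_CODE = np.full(256, 4, dtype=np.uint8)
for b, v in _BASE_CODE.items():
    _CODE[ord(b)] = v
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _scan_strand(codes: np.ndarray, proto: np.ndarray, max_mm: int):
    """Window starts and mismatch counts for one strand's coded sequence."""
    n = codes.shape[0]
    if n < 23:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, 23)
    has_n = (win == 4).any(axis=1)
    pam_ok = (win[:, 21] == _BASE_CODE["G"]) & (win[:, 22] == _BASE_CODE["G"])
    mm = (win[:, :20] != proto[None, :]).sum(axis=1)
    hit = pam_ok & ~has_n & (mm <= max_mm)
    starts = np.flatnonzero(hit)
    return starts.astype(np.int64), mm[starts].astype(np.int64)


def enumerate_candidate_sites(genome: Genome, query: ProtospacerQuery) -> list[CandidateSite]:
    """Exhaustively scan both strands for protospacer matches with NGG PAM.

    Windows containing N are skipped.  Minus-strand sites are reported in
    forward coordinates; their cleavage boundary is start + 6 (vs start +
    17 on the plus strand).
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    proto = _CODE[_encode(query.protospacer)]
    sites: list[CandidateSite] = []
    for chrom, seq in genome.sequences.items():
        codes = _CODE[_encode(seq)]
        starts, mm = _scan_strand(codes, proto, query.max_mismatches)
        for s, m in zip(starts, mm):
            sites.append(CandidateSite(chrom, int(s), int(s) + 23, "+", int(m), int(s) + 17))
        rc = _RC[codes[::-1]]
        starts, mm = _scan_strand(rc, proto, query.max_mismatches)
        L = len(seq)
        for s, m in zip(starts, mm):
            fwd = L - 23 - int(s)
            sites.append(CandidateSite(chrom, fwd, fwd + 23, "-", int(m), fwd + 6))
    sites.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return sites


def _indel_span(pos: int, ref: str, alt: str) -> tuple[int, int]:
    """Half-open genomic span an indel record affects (VCF-style anchored)."""
    return pos, pos + max(len(ref), 1)


def _nearest_cleavage(chrom: str, pos: int, by_chrom: dict[str, np.ndarray]):
    """(distance, cleavage) of the nearest cleavage site; ties -> lower coord."""
    arr = by_chrom.get(chrom)
    if arr is None or arr.size == 0:
        return None
    d = np.abs(arr - pos)
    best = int(d.min())
    return best, int(arr[(d == best).argmax()])


def _cleavages_by_chrom(sites) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for s in sites:
        by.setdefault(s.chrom, []).append(s.cleavage)
    return {c: np.unique(np.array(v, dtype=np.int64)) for c, v in by.items()}


@dataclass
class IndelAttribution:
    """Attributed indels plus the control-cell presumed-false-positive set."""

    attributed: pd.DataFrame      # cell, chrom, pos, ref, alt, site_cleavage, distance
    presumed_fp: pd.DataFrame     # same columns, from control / other-gRNA cells


def attribute_indels(
    cells: list[CallSet],
    sites_by_grna: dict[str, list[CandidateSite]],
    bulk: CallSet,
    window: int = 50,
    span_overlap: bool = False,
) -> IndelAttribution:
    """Attribute per-cell indels to candidate cleavage sites.

    Each cell's ``meta['grna']`` names the gRNA it received (or
    ``"control"``).  An indel is kept when its leftmost coordinate lies
    within +/- ``window`` of a cleavage site of the cell's gRNA (with
    ``span_overlap=True``, any overlap of the indel span with the window
    qualifies), it is absent from the bulk, and it is absent from every
    cell that received a different gRNA.  Kept indels are assigned the
    nearest cleavage site (ties to the lower coordinate).  Indels in
    control (or other-gRNA) cells landing in some gRNA's windows are
    returned separately as presumed false positives.
    """
    if not sites_by_grna or all(not v for v in sites_by_grna.values()):
        raise ValueError("empty candidate site list")
    cleav = {g: _cleavages_by_chrom(s) for g, s in sites_by_grna.items()}
    bulk_keys = set(zip(bulk.df["chrom"], bulk.df["pos"], bulk.df["ref"], bulk.df["alt"]))
    keys_by_grna: dict[str, set] = {}
    for cs in cells:
        g = cs.meta.get("grna", "control")
        ks = set(zip(cs.df["chrom"], cs.df["pos"], cs.df["ref"], cs.df["alt"]))
        keys_by_grna.setdefault(g, set()).update(ks)

    def _window_hit(grna, chrom, pos, ref, alt):
        near = _nearest_cleavage(chrom, pos, cleav[grna])
        if near is None:
            return None
        dist, site = near
        if dist <= window:
            return dist, site
        if span_overlap:
            s, e = _indel_span(pos, ref, alt)
            arr = cleav[grna][chrom]
            lo, hi = s - window, e - 1 + window
            if ((arr >= lo) & (arr <= hi)).any():
                return dist, site
        return None

    att_rows, fp_rows = [], []
    for cs in cells:
        mine = cs.meta.get("grna", "control")
        for row in cs.df.itertuples(index=False):
            if len(row.ref) == len(row.alt):
                continue  # SNVs are out of scope here
            key = (row.chrom, row.pos, row.ref, row.alt)
            if mine in sites_by_grna:
                hit = _window_hit(mine, row.chrom, row.pos, row.ref, row.alt)
                if hit is not None:
                    in_other = any(
                        key in ks for g, ks in keys_by_grna.items() if g != mine
                    )
                    if key not in bulk_keys and not in_other:
                        att_rows.append((cs.sample, row.chrom, row.pos, row.ref,
                                         row.alt, hit[1], hit[0]))
                    continue
            # control cell, or cell whose own gRNA windows missed: check all
            for g in sites_by_grna:
                if g == mine:
                    continue
                hit = _window_hit(g, row.chrom, row.pos, row.ref, row.alt)
                if hit is not None:
                    fp_rows.append((cs.sample, row.chrom, row.pos, row.ref,
                                    row.alt, hit[1], hit[0]))
                    break
    cols = ["cell", "chrom", "pos", "ref", "alt", "site_cleavage", "distance"]
    return IndelAttribution(
        attributed=pd.DataFrame(att_rows, columns=cols),
        presumed_fp=pd.DataFrame(fp_rows, columns=cols),
    )


def recurrence_filter(attributed: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop non-recurrent single-base insertions.

    A 1-bp insertion observed at its site in exactly one cell is removed;
    deletions, multi-base insertions, and recurrent 1-bp insertions are
    kept.  Returns (filtered table, number removed).
    """
    if len(attributed) == 0:
        return attributed.copy(), 0
    is_1bp_ins = (
        attributed["alt"].str.len() - attributed["ref"].str.len() == 1
    ) & (attributed["ref"].str.len() == 1)
    n_cells = attributed.groupby(["chrom", "pos", "ref", "alt"])["cell"].transform("nunique")
    drop = is_1bp_ins & (n_cells == 1)
    return attributed.loc[~drop].reset_index(drop=True), int(drop.sum())


def attribute_svs(
    breakpoints: pd.DataFrame,
    sites_by_grna: dict[str, list[CandidateSite]],
    cell_grna: dict[str, str],
    window: int = 200,
) -> pd.DataFrame:
    """Attribute structural variants to off-target cleavage sites.

    ``breakpoints`` lists one event per row: cell, chrom_a, pos_a, chrom_b,
    pos_b.  An event is kept when both breakpoints are within +/-
    ``window`` of some cleavage site of the cell's gRNA (the two ends may
    match different sites) and the same breakpoint pair is absent from
    every control / other-gRNA cell.  Rows with a missing end are rejected.
    """
    need = {"cell", "chrom_a", "pos_a", "chrom_b", "pos_b"}
    if not need <= set(breakpoints.columns):
        raise ValueError(f"breakpoint table needs columns {sorted(need)}")
    bad = breakpoints[["chrom_a", "pos_a", "chrom_b", "pos_b"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"malformed breakpoint pair at rows {list(breakpoints.index[bad])}")
    cleav = {g: _cleavages_by_chrom(s) for g, s in sites_by_grna.items()}

    def _pair_key(row):
        a = (row.chrom_a, int(row.pos_a))
        b = (row.chrom_b, int(row.pos_b))
        return (a, b) if a <= b else (b, a)

    pairs_by_grna: dict[str, set] = {}
    for row in breakpoints.itertuples(index=False):
        g = cell_grna.get(row.cell, "control")
        pairs_by_grna.setdefault(g, set()).add(_pair_key(row))

    rows = []
    for row in breakpoints.itertuples(index=False):
        g = cell_grna.get(row.cell, "control")
        if g not in cleav:
            continue
        hits = []
        for chrom, pos in ((row.chrom_a, int(row.pos_a)), (row.chrom_b, int(row.pos_b))):
            near = _nearest_cleavage(chrom, pos, cleav[g])
            if near is None or near[0] > window:
                hits = None
                break
            hits.append(near[1])
        if hits is None:
            continue
        key = _pair_key(row)
        if any(key in ps for og, ps in pairs_by_grna.items() if og != g):
            continue
        rows.append((row.cell, g, row.chrom_a, int(row.pos_a), hits[0],
                     row.chrom_b, int(row.pos_b), hits[1]))
    return pd.DataFrame(rows, columns=[
        "cell", "grna", "chrom_a", "pos_a", "site_a",
        "chrom_b", "pos_b", "site_b",
    ])
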