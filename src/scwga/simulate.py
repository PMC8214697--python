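"""Generative models of single-cell WGA data with recorded ground truth.

Four generators supply every input the evaluation pipeline consumes:

* :func:`simulate_amplification` — a branching-process model of primer
  extension with chain terminators.  The re-priming weight ``rho`` of
  terminated daughter amplicons is the single knob separating quasilinear
  (terminator-suppressed, PTA-like) from exponential (MDA-like) chemistry.
* :func:`simulate_kindred_dataset` — bulk + single-cell call sets from a
  clonal expansion: shared germline variants, founder somatic variants
  absent from bulk, and private false-positive calls.
* :func:`simulate_mutagen_dataset` — dosed cells carrying private mutations
  with a prescribed 6-class base-change spectrum drawn in genomic context.
* :func:`simulate_edited_dataset` — CRISPR-edited cells with planted on/off
  target indels, structural-variant breakpoint pairs, and background
  1-bp insertion artefacts.

All coordinates are 0-based half-open.  Identical seed + config gives
byte-identical output; per-cell/per-stage streams are labeled so adding a
cell never perturbs the draws of other cells.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .coverage import CoverageProfile
from .genome import Genome
from .variants import CallSet, empty_frame

__all__ = [
    "SimConfig",
    "AmpliconPool",
    "TruthTable",
    "KindredDataset",
    "MutagenDataset",
    "EditedDataset",
    "simulate_amplification",
    "pool_to_coverage",
    "allele_depths",
    "error_allele_fractions",
    "error_mass_fractions",
    "simulate_kindred_dataset",
    "simulate_mutagen_dataset",
    "simulate_edited_dataset",
    "DMEM_DESIGN",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# amplification branching process
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the amplification branching process.

    Parameters
    ----------
    mode
        ``"quasilinear"`` (terminated daughters are poor templates) or
        ``"exponential"`` (daughters re-prime as well as the primary).
    priming_rate
        Expected primer bindings per kb of template per round.
    termination_prob
        Per-base probability of incorporating an irreversible terminator
        (``alpha``); extension lengths are geometric with mean 1/alpha.
    reprime_weight
        Relative template weight ``rho`` of a *terminated* daughter
        amplicon.  rho << 1 gives quasilinear amplification dominated by
        the primary template; rho = 1 recovers exponential amplification.
    error_rate
        Per-base polymerase copying error probability; copies inherit their
        template's errors, so errors propagate only through re-priming.
    rounds
        Number of priming/extension rounds (>= 1).
    ploidy
        Number of intact primary haplotypes per chromosome.
    """

    mode: str = "quasilinear"
    priming_rate: float = 0.1
    termination_prob: float | None = None
    reprime_weight: float | None = None
    error_rate: float = 1e-6
    rounds: int = 5
    ploidy: int = 2
    max_amplicons: int = 500_000

    def __post_init__(self):
        if self.mode not in ("quasilinear", "exponential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reprime_weight is None:
            self.reprime_weight = 0.05 if self.mode == "quasilinear" else 1.0
        if self.termination_prob is None:
            # terminators are the quasilinear chemistry's ingredient: mean
            # product ~500 b; without them products run to tens of kb
            self.termination_prob = 0.002 if self.mode == "quasilinear" else 5e-5
        for name in ("priming_rate", "termination_prob", "reprime_weight", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.termination_prob >= 1:
            raise ValueError("termination_prob must be < 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.mode == "quasilinear" and self.termination_prob == 0:
            warnings.warn("termination_prob = 0 in quasilinear mode degenerates to "
                          "untruncated extension (exponential-like products)")


@dataclass
class AmpliconPool:
    """Amplicons produced by :func:`simulate_amplification`.

    Parallel arrays; ``errors[i]`` is a tuple of absolute error positions
    carried by amplicon i.  Generation 0 entries are the intact primary
    haplotypes.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    chrom: np.ndarray          # int index into chrom_names
    start: np.ndarray
    end: np.ndarray
    haplotype: np.ndarray
    generation: np.ndarray
    terminated: np.ndarray
    errors: list[tuple[int, ...]]

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def daughters(self) -> np.ndarray:
        """Indices of non-primary amplicons (the sequencing library mass)."""
        return np.flatnonzero(self.generation > 0)


def simulate_amplification(genome: Genome, config: SimConfig, seed: int = 0) -> AmpliconPool:
    """Run the priming/extension branching process on a genome.

    Each round every template receives Poisson(priming_rate x length/1000 x w)
    primers, where w = 1 for primary templates and unterminated daughters and
    w = rho for terminated daughters.  Each primer extends from a uniform
    position in a uniform direction until a terminator is incorporated
    (geometric, per-base prob alpha) or the template end is reached.  Copies
    inherit the template's error positions inside the copied interval plus
    new errors at the per-base error rate.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    rng = child_rng(seed, "amplify")
    alpha = config.termination_prob
    names = genome.names
    lengths = genome.lengths

    chrom_l, start_l, end_l, hap_l, gen_l, term_l = [], [], [], [], [], []
    errors: list[tuple[int, ...]] = []
    for ci, name in enumerate(names):
        for hap in range(config.ploidy):
            chrom_l.append(ci); start_l.append(0); end_l.append(lengths[name])
            hap_l.append(hap); gen_l.append(0); term_l.append(False)
            errors.append(())

    chrom = np.array(chrom_l, dtype=np.int32)
    start = np.array(start_l, dtype=np.int64)
    end = np.array(end_l, dtype=np.int64)
    hap = np.array(hap_l, dtype=np.int8)
    gen = np.array(gen_l, dtype=np.int16)
    term = np.array(term_l, dtype=bool)

    for _ in range(config.rounds):
        length = (end - start).astype(float)
        weight = np.where((gen > 0) & term, config.reprime_weight, 1.0)
        lam = config.priming_rate * length / 1000.0 * weight
        n_prime = rng.poisson(lam)
        tmpl = np.repeat(np.arange(len(start)), n_prime)
        if len(start) + tmpl.size > config.max_amplicons:
            raise RuntimeError(
                f"amplicon pool would exceed max_amplicons={config.max_amplicons}; "
                "reduce rounds or priming_rate")
        if tmpl.size == 0:
            continue
        t_start, t_end = start[tmpl], end[tmpl]
        pos = t_start + (rng.random(tmpl.size) * (t_end - t_start)).astype(np.int64)
        ext = (rng.geometric(alpha, tmpl.size) if alpha > 0
               else np.full(tmpl.size, np.iinfo(np.int64).max // 2, dtype=np.int64))
        rightward = rng.random(tmpl.size) < 0.5
        new_start = np.where(rightward, pos, np.maximum(t_start, pos - ext + 1))
        new_end = np.where(rightward, np.minimum(t_end, pos + ext), pos + 1)
        hit_end = np.where(rightward, pos + ext > t_end, pos - ext + 1 < t_start)
        new_term = ~hit_end

        new_len = new_end - new_start
        n_err = rng.binomial(new_len, config.error_rate)
        new_errors: list[tuple[int, ...]] = []
        for k in range(tmpl.size):
            inherited = errors[tmpl[k]]
            errs = [e for e in inherited if new_start[k] <= e < new_end[k]]
            if n_err[k]:
                errs.extend(
                    int(new_start[k] + x)
                    for x in rng.integers(0, new_len[k], size=n_err[k])
                )
            new_errors.append(tuple(sorted(set(errs))))

        chrom = np.concatenate([chrom, chrom[tmpl]])
        hap = np.concatenate([hap, hap[tmpl]])
        gen = np.concatenate([gen, gen[tmpl] + 1])
        start = np.concatenate([start, new_start])
        end = np.concatenate([end, new_end])
        term = np.concatenate([term, new_term])
        errors.extend(new_errors)

    return AmpliconPool(
        chrom_names=names, chrom_lengths=lengths, chrom=chrom, start=start,
        end=end, haplotype=hap, generation=gen, terminated=term, errors=errors,
    )


def pool_to_coverage(
    pool: AmpliconPool,
    bin_size: int,
    reads: int,
    seed: int = 0,
    read_length: int = 100,
) -> tuple[CoverageProfile, pd.DataFrame]:
    """Sample reads from a pool and bin them.

    Reads are drawn from non-primary amplicons proportional to amplicon
    length; each read starts uniformly within its amplicon and extends
    ``read_length`` bases (clipped at the amplicon end).  Returns the binned
    profile (counting read starts) and the read table (chrom, start, end,
    haplotype, amplicon index) for allele-depth and error-fraction queries.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if reads < 0:
        raise ValueError("reads must be >= 0")
    rng = child_rng(seed, "reads")
    idx = pool.daughters() if len(pool) else np.array([], dtype=np.int64)
    parts = []
    for ci, name in enumerate(pool.chrom_names):
        L = pool.chrom_lengths[name]
        starts = np.arange(0, L, bin_size, dtype=np.int64)
        parts.append(pd.DataFrame({
            "chrom": name, "start": starts,
            "end": np.minimum(starts + bin_size, L),
            "count": np.zeros(len(starts), dtype=np.int64), "masked": False,
        }))
    prof_df = pd.concat(parts, ignore_index=True)

    if reads == 0 or idx.size == 0:
        profile = CoverageProfile(prof_df, bin_size)
        empty = pd.DataFrame(columns=["chrom", "start", "end", "haplotype", "amplicon"])
        return profile, empty

    lens = pool.lengths[idx].astype(float)
    amp = idx[rng.choice(idx.size, size=reads, p=lens / lens.sum())]
    r_start = pool.start[amp] + (rng.random(reads) * pool.lengths[amp]).astype(np.int64)
    r_end = np.minimum(r_start + read_length, pool.end[amp])
    reads_df = pd.DataFrame({
        "chrom": np.asarray(pool.chrom_names, dtype=object)[pool.chrom[amp]],
        "start": r_start, "end": r_end,
        "haplotype": pool.haplotype[amp], "amplicon": amp,
    })

    offset = 0
    for ci, name in enumerate(pool.chrom_names):
        L = pool.chrom_lengths[name]
        nbins = int(np.ceil(L / bin_size))
        sel = pool.chrom[amp] == ci
        counts = np.bincount(r_start[sel] // bin_size, minlength=nbins)
        prof_df.loc[offset : offset + nbins - 1, "count"] = counts[:nbins]
        offset += nbins
    return CoverageProfile(prof_df, bin_size), reads_df


def allele_depths(reads_df: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site read depth split by source haplotype.

    ``sites`` has columns chrom, pos.  A read covers a site when
    start <= pos < end.  Returns sites with added columns depth_hap0,
    depth_hap1, depth.
    """
    out = sites.copy()
    d0 = np.zeros(len(sites), dtype=np.int64)
    d1 = np.zeros(len(sites), dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        cover = (reads_df["chrom"] == chrom) & (reads_df["start"] <= pos) & (pos < reads_df["end"])
        haps = reads_df.loc[cover, "haplotype"]
        d0[i] = int((haps == 0).sum())
        d1[i] = int((haps == 1).sum())
    out["depth_hap0"], out["depth_hap1"] = d0, d1
    out["depth"] = d0 + d1
    return out


def error_allele_fractions(
    pool: AmpliconPool,
    reads_df: pd.DataFrame,
    min_alt_depth: int = 2,
    min_vaf: float = 0.0,
    max_sites: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed allele fractions of polymerase errors in the read sample.

    For every distinct error position seen in a sampled amplicon, the
    fraction of covering reads that inherited the error.  Only errors
    supported by at least ``min_alt_depth`` reads and at allele fraction
    >= ``min_vaf`` are reported — the errors a variant caller could
    actually call.  Quasilinear
    amplification confines an error to its terminated amplicon, so
    callable errors are rare and dilute; exponential amplification copies
    early errors into a large share of the local mass.
    """
    cols = ["chrom", "pos", "depth", "alt_depth", "vaf"]
    if len(reads_df) == 0:
        return pd.DataFrame(columns=cols)
    # error site -> carrier amplicon ids (across the whole pool)
    sampled = set(int(a) for a in reads_df["amplicon"].unique())
    carriers: dict[tuple[int, int], list[int]] = {}
    for a, errs in enumerate(pool.errors):
        ci = int(pool.chrom[a])
        for e in errs:
            carriers.setdefault((ci, e), []).append(a)
    sites = sorted(k for k, v in carriers.items() if any(a in sampled for a in v))
    if max_sites is not None and len(sites) > max_sites:
        rng = child_rng(seed, "errsites")
        keep = rng.choice(len(sites), size=max_sites, replace=False)
        sites = [sites[i] for i in sorted(keep)]

    name_code = {n: i for i, n in enumerate(pool.chrom_names)}
    chrom_codes = reads_df["chrom"].map(name_code).to_numpy(dtype=np.int64)
    start_arr = reads_df["start"].to_numpy()
    end_arr = reads_df["end"].to_numpy()
    amp_arr = reads_df["amplicon"].to_numpy()

    rows = []
    for ci, pos in sites:
        cover = (chrom_codes == ci) & (start_arr <= pos) & (pos < end_arr)
        depth = int(cover.sum())
        if depth == 0:
            continue
        alt = int((cover & np.isin(amp_arr, carriers[(ci, pos)])).sum())
        if alt < min_alt_depth or alt / depth < min_vaf:
            continue
        rows.append({"chrom": pool.chrom_names[ci], "pos": pos, "depth": depth,
                     "alt_depth": alt, "vaf": alt / depth})
    return pd.DataFrame(rows, columns=cols)


def error_mass_fractions(
    pool: AmpliconPool, max_sites: int | None = 800, seed: int = 0
) -> pd.DataFrame:
    """Amplicon-mass allele fractions of polymerase errors.

    For each distinct error position, ``carriers`` counts the daughter
    amplicons that inherited the error and ``covering`` the daughter
    amplicons overlapping the position; ``vaf`` is their ratio — the
    fraction of the local amplified mass that carries the error, i.e. the
    allele fraction an infinitely deep sequencing experiment would observe.
    Because a sequencing experiment observes an error in proportion to its
    carrier mass, distribution summaries should weight each error by
    ``carriers`` (the error's observation weight).

    Quasilinear amplification leaves almost every error on a single
    terminated amplicon among many independent primary-derived copies;
    exponential amplification lets early errors spread through their
    lineage, shifting the observation-weighted distribution upward.
    """
    cols = ["chrom", "pos", "carriers", "covering", "vaf"]
    d = pool.daughters()
    carr: dict[tuple[int, int], int] = {}
    for a in d:
        ci = int(pool.chrom[a])
        for e in pool.errors[a]:
            carr[(ci, e)] = carr.get((ci, e), 0) + 1
    sites = sorted(carr)
    if max_sites is not None and len(sites) > max_sites:
        rng = child_rng(seed, "errmass")
        keep = rng.choice(len(sites), size=max_sites, replace=False)
        sites = [sites[i] for i in sorted(keep)]
    st, en, ch = pool.start[d], pool.end[d], pool.chrom[d]
    rows = []
    for ci, pos in sites:
        ncov = int(((ch == ci) & (st <= pos) & (pos < en)).sum())
        m = carr[(ci, pos)]
        rows.append({"chrom": pool.chrom_names[ci], "pos": pos,
                     "carriers": m, "covering": ncov, "vaf": m / ncov})
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Planted-variant ground truth.

    ``df`` columns: chrom, pos, ref, alt, label, carrier, planted_af.
    ``carrier`` is a cell id for private variants or ``"*"`` for variants
    carried by every cell (germline/founder somatic).
    """

    df: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.df["label"].value_counts()

    def subset(self, label: str) -> pd.DataFrame:
        return self.df[self.df["label"] == label]


# ---------------------------------------------------------------------------
# kindred-cell dataset
# ---------------------------------------------------------------------------

def _nb_depth(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial depth: mean m, variance m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int32)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size).astype(np.int32)


def _gq_from_ad(ad_alt: np.ndarray) -> np.ndarray:
    """Deterministic genotype quality from alt-supporting reads (cap 99)."""
    return np.minimum(99, 3 * ad_alt).astype(np.int64)


def _random_alleles(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, size=n)]
    alt = _BASES[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=n)) % 4]
    return ref, alt


@dataclass
class KindredDataset:
    """Output of :func:`simulate_kindred_dataset`."""

    bulk: CallSet
    cells: list[CallSet]
    truth: TruthTable
    depths: pd.DataFrame        # chrom, pos, span_bp, bulk, <cell ids...>
    genome_mb: float


def simulate_kindred_dataset(
    n_cells: int = 5,
    genome_mb: float = 3088.0,
    germline_density: float = 1000.0,
    somatic_rate: float = 0.33,
    fp_burden: float = 2785.0,
    detect_prob: float = 0.85,
    depth_mean: float = 30.0,
    depth_dispersion: float = 0.3,
    bulk_depth_mean: float = 40.0,
    hom_fraction: float = 1 / 3,
    fp_beta: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
    chrom: str = "sim1",
) -> KindredDataset:
    """Simulate a kindred-cell experiment: one clone, re-isolated cells.

    Germline variants (density per Mb) are present in the bulk and detected
    per cell with ``detect_prob``.  Founder somatic variants (rate per Mb)
    are absent from the bulk, carried by every kindred cell, and detected
    with the same probability.  False positives are private to one cell,
    Poisson(``fp_burden``) per cell, with allele fractions drawn
    Beta(*fp_beta*) to mimic the low-VAF skew of amplification artefacts.

    Per-site depth is negative binomial (mean ``depth_mean``, variance
    mean + dispersion * mean^2); allele depth is binomial in the planted
    fraction.  The returned depth table covers every truth site for all
    samples with a per-row span weight of genome_bp / n_sites, so the
    callable-site filter yields a consistent callable-Mb estimate.
    """
    if n_cells < 2:
        raise ValueError("kindred classification needs >= 2 cells")
    if detect_prob <= 0 or detect_prob > 1:
        raise ValueError("detect_prob must be in (0, 1]")
    for name, v in (("germline_density", germline_density),
                    ("somatic_rate", somatic_rate), ("fp_burden", fp_burden)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    genome_bp = int(genome_mb * 1e6)
    cell_ids = [f"cell{i}" for i in range(n_cells)]

    rng = child_rng(seed, "kindred", "sites")
    n_germ = rng.poisson(germline_density * genome_mb)
    n_som = rng.poisson(somatic_rate * genome_mb)
    n_fp = rng.poisson(fp_burden, size=n_cells)
    total = n_germ + n_som + int(n_fp.sum())
    # distinct uniform positions without materialising arange(genome_bp):
    # oversample with replacement, dedupe, top up, then shuffle so position
    # is independent of the label assigned by slice below
    uniq = np.unique(rng.integers(0, genome_bp, size=int(total * 1.02) + 16))
    while uniq.size < total:
        extra = rng.integers(0, genome_bp, size=total - uniq.size + 16)
        uniq = np.unique(np.concatenate([uniq, extra]))
    pos = uniq[rng.permutation(uniq.size)[:total]].astype(np.int64)
    ref, alt = _random_alleles(rng, total)
    label = np.empty(total, dtype=object)
    label[:n_germ] = "germline"
    label[n_germ:n_germ + n_som] = "somatic"
    label[n_germ + n_som:] = "false_positive"
    carrier = np.full(total, "*", dtype=object)
    fp_cell = np.repeat(np.arange(n_cells), n_fp)
    carrier[n_germ + n_som:] = np.asarray(cell_ids, dtype=object)[fp_cell]

    planted_af = np.full(total, 0.5)
    is_hom = np.zeros(total, dtype=bool)
    is_hom[:n_germ] = rng.random(n_germ) < hom_fraction
    planted_af[is_hom] = 1.0
    fp_af = rng.beta(fp_beta[0], fp_beta[1], size=int(n_fp.sum()))
    planted_af[n_germ + n_som:] = fp_af

    order = np.argsort(pos, kind="stable")
    pos, ref, alt, label, carrier = pos[order], ref[order], alt[order], label[order], carrier[order]
    planted_af, is_hom = planted_af[order], is_hom[order]
    # recover the FP carrier index after the positional sort
    fp_cell_sorted = np.full(total, -1, dtype=np.int64)
    is_fp = label == "false_positive"
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    fp_cell_sorted[is_fp] = [cell_index[c] for c in carrier[is_fp]]

    truth = TruthTable(pd.DataFrame({
        "chrom": pd.Categorical([chrom]).repeat(total), "pos": pos,
        "ref": pd.Categorical(ref, categories=list("ACGT")),
        "alt": pd.Categorical(alt, categories=list("ACGT")),
        "label": pd.Categorical(label), "carrier": carrier,
        "planted_af": planted_af,
    }))

    # depth table over all truth sites, one stream per sample
    span_bp = genome_bp / total
    depths = pd.DataFrame({
        "chrom": pd.Categorical([chrom]).repeat(total), "pos": pos,
        "span_bp": span_bp,
    })
    bulk_dp = _nb_depth(child_rng(seed, "kindred", "depth", "bulk"),
                        bulk_depth_mean, depth_dispersion, total)
    depths["bulk"] = bulk_dp
    cell_dp = np.empty((total, n_cells), dtype=np.int32)
    for i, cid in enumerate(cell_ids):
        cell_dp[:, i] = _nb_depth(child_rng(seed, "kindred", "depth", cid),
                                  depth_mean, depth_dispersion, total)
        depths[cid] = cell_dp[:, i]

    def _records(mask, dp, af, rng_local):
        dp_v = np.maximum(dp[mask], 1).astype(np.int32)
        ad_alt = rng_local.binomial(dp_v, af[mask])
        ad_alt = np.maximum(ad_alt, 1)  # a call implies >= 1 supporting read
        ad_ref = dp_v - ad_alt
        with np.errstate(invalid="ignore"):
            obs_af = ad_alt / dp_v
        gt = pd.Categorical.from_codes(
            (obs_af > 0.9).astype(np.int8), categories=["0/1", "1/1"])
        return pd.DataFrame({
            "chrom": pd.Categorical([chrom]).repeat(int(mask.sum())),
            "pos": pos[mask],
            "ref": pd.Categorical(ref[mask], categories=list("ACGT")),
            "alt": pd.Categorical(alt[mask], categories=list("ACGT")),
            "dp": dp_v, "gq": _gq_from_ad(ad_alt).astype(np.int32),
            "ad_ref": ad_ref.astype(np.int32), "ad_alt": ad_alt.astype(np.int32),
            "gt": gt,
        })

    is_germ = label == "germline"
    is_som = label == "somatic"
    bulk_df = _records(is_germ, bulk_dp, planted_af, child_rng(seed, "kindred", "bulkcalls"))
    bulk = CallSet(sample="bulk", role="bulk", df=bulk_df)

    cells = []
    for i, cid in enumerate(cell_ids):
        r = child_rng(seed, "kindred", "cell", cid)
        detected = (is_germ | is_som) & (r.random(total) < detect_prob)
        mask = detected | (is_fp & (fp_cell_sorted == i))
        cells.append(CallSet(
            sample=cid, role="cell",
            df=_records(mask, cell_dp[:, i], planted_af, r),
        ))
    return KindredDataset(bulk=bulk, cells=cells, truth=truth,
                          depths=depths, genome_mb=genome_mb)


# ---------------------------------------------------------------------------
# mutagen-exposure dataset
# ---------------------------------------------------------------------------

#: the dose layout of the mutagen study: (compound, dose uM, n cells)
DMEM_DESIGN = [
    ("vehicle", 0.0, 5),
    ("MAN", 1152.8, 5),
    ("MAN", 11528.0, 5),
    ("ENU", 8.54, 5),
    ("ENU", 85.4, 5),
    ("ENU", 854.0, 4),
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 6-class base-change probabilities favouring the alkylator's known
#: T>A / T>C / C>T preference
DEFAULT_MUTAGEN_SPECTRUM = {
    "C>A": 0.1 / 3, "C>G": 0.1 / 3, "C>T": 0.3,
    "T>A": 0.3, "T>C": 0.3, "T>G": 0.1 / 3,
}


@dataclass
class MutagenDataset:
    """Output of :func:`simulate_mutagen_dataset`."""

    bulk: CallSet
    cells: list[CallSet]
    truth: TruthTable
    bulk_depths: pd.DataFrame   # chrom, pos, depth at every truth site


def _context_positions(genome: Genome):
    """Positions usable for planting, keyed by pyrimidine-strand ref base."""
    by_class: dict[str, list[tuple[str, int]]] = {"C": [], "T": []}
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        ok = np.ones(len(arr), dtype=bool)
        ok[[0, -1]] = False
        isn = arr == "N"
        ok &= ~(isn | np.roll(isn, 1) | np.roll(isn, -1))
        for base, pyr in (("C", "C"), ("G", "C"), ("T", "T"), ("A", "T")):
            for p in np.flatnonzero(ok & (arr == base)):
                by_class[pyr].append((name, int(p)))
    return by_class


def simulate_mutagen_dataset(
    genome: Genome,
    doses=DMEM_DESIGN,
    mutations_per_cell=None,
    spectrum_probs: dict[str, float] = None,
    bulk_depth_mean: float = 30.0,
    depth_mean: float = 30.0,
    depth_dispersion: float = 0.3,
    seed: int = 0,
) -> MutagenDataset:
    """Dose cells with private mutations following a 6-class spectrum.

    ``doses`` lists (compound, dose, n_cells) groups; ``mutations_per_cell``
    maps (compound, dose) -> expected mutation count (default: linear in
    dose for the mutagen, small constant background otherwise).  Mutation
    contexts are drawn from the genome so trinucleotide spectra are
    well defined; purine-reference positions plant the complementary change.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    spectrum_probs = dict(spectrum_probs or DEFAULT_MUTAGEN_SPECTRUM)
    total_p = sum(spectrum_probs.values())
    if abs(total_p - 1.0) > 1e-6:
        raise ValueError(f"spectrum_probs must sum to 1, got {total_p}")
    if mutations_per_cell is None:
        def mutations_per_cell(compound, dose):
            return 2.0 + (0.06 * dose if compound == "ENU" else 0.0)

    classes = list(SPECTRUM_CLASSES)
    probs = np.array([spectrum_probs.get(c, 0.0) for c in classes])
    ctx = _context_positions(genome)
    if not ctx["C"] or not ctx["T"]:
        raise ValueError("genome lacks usable C/T context positions")

    rows, cells = [], []
    cell_n = 0
    for compound, dose, n in doses:
        for _ in range(n):
            cid = f"{compound}_{dose:g}_c{cell_n}"
            cell_n += 1
            r = child_rng(seed, "mutagen", cid)
            k = r.poisson(float(mutations_per_cell(compound, dose)))
            recs = []
            for _i in range(k):
                cls = classes[r.choice(len(classes), p=probs)]
                pyr_ref, pyr_alt = cls[0], cls[2]
                name, p = ctx[pyr_ref][r.integers(0, len(ctx[pyr_ref]))]
                base = genome.base(name, p)
                alt = pyr_alt if base == pyr_ref else _COMPLEMENT[pyr_alt]
                recs.append((name, p, base, alt))
            recs = list(dict.fromkeys(recs))  # drop rare same-cell duplicates
            dp = np.maximum(_nb_depth(r, depth_mean, depth_dispersion, len(recs)), 1)
            ad_alt = np.maximum(r.binomial(dp.astype(np.int64), 0.5), 1)
            df = pd.DataFrame({
                "chrom": [x[0] for x in recs], "pos": [x[1] for x in recs],
                "ref": [x[2] for x in recs], "alt": [x[3] for x in recs],
                "dp": dp.astype(np.int64), "gq": _gq_from_ad(ad_alt),
                "ad_ref": dp - ad_alt, "ad_alt": ad_alt, "gt": "0/1",
            }) if recs else empty_frame()
            cells.append(CallSet(sample=cid, role="cell", df=df,
                                 meta={"compound": compound, "dose": dose}))
            for name, p, base, alt in recs:
                rows.append((name, p, base, alt, "mutagen", cid, 0.5))

    truth = TruthTable(pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "label", "carrier", "planted_af"]
    ))
    bulk = CallSet(sample="bulk", role="bulk")
    rb = child_rng(seed, "mutagen", "bulkdepth")
    sites = truth.df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    bulk_depths = sites.assign(
        depth=_nb_depth(rb, bulk_depth_mean, depth_dispersion, len(sites)).astype(np.int64)
    )
    return MutagenDataset(bulk=bulk, cells=cells, truth=truth, bulk_depths=bulk_depths)


# ---------------------------------------------------------------------------
# CRISPR-edited dataset
# ---------------------------------------------------------------------------

@dataclass
class EditedDataset:
    """Output of :func:`simulate_edited_dataset`."""

    cells: list[CallSet]          # indel calls; meta['grna'] is the gRNA or 'control'
    breakpoints: pd.DataFrame     # cell, chrom_a, pos_a, chrom_b, pos_b
    truth: TruthTable
    sites: list                   # validated CandidateSite objects
    grna: str


def simulate_edited_dataset(
    genome: Genome,
    protospacer: str,
    n_cells: int = 5,
    offtarget_sites: list[tuple[str, int, float]] | None = None,
    sv_pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
    sv_prob: float = 0.3,
    n_control: int = 3,
    background_ins_per_cell: float = 1.0,
    background_near_site_frac: float = 0.5,
    grna: str = "gRNA1",
    seed: int = 0,
) -> EditedDataset:
    """Plant CRISPR on/off-target indels, SV breakpoints, and background.

    ``offtarget_sites`` lists (chrom, cleavage coordinate, per-cell indel
    probability); each must coincide with a candidate cleavage site of the
    protospacer (<= 5 mismatches, NGG PAM), otherwise the offending site is
    rejected.  Edited cells carry the site's canonical indel (chosen once
    per site, so true edits recur across cells) with 0-2 bp positional
    jitter.  Background false-positive 1-bp insertions are private to one
    cell; a configurable fraction lands inside attribution windows so the
    non-recurrence filter is exercised.  Control cells receive background
    only — no edits and no SVs.
    """
    from .offtarget import ProtospacerQuery, enumerate_candidate_sites

    query = ProtospacerQuery(protospacer=protospacer)
    candidates = enumerate_candidate_sites(genome, query)
    cleav = {(s.chrom, s.cleavage) for s in candidates}
    offtarget_sites = offtarget_sites or []
    for site in offtarget_sites:
        if (site[0], site[1]) not in cleav:
            raise ValueError(
                f"planted site {site[0]}:{site[1]} does not match the protospacer "
                f"within {query.max_mismatches} mismatches with an NGG PAM")

    sv_pairs = sv_pairs or []
    for (ca, pa), (cb, pb) in sv_pairs:
        if (ca, pa) not in cleav or (cb, pb) not in cleav:
            raise ValueError(f"planted SV pair ({ca}:{pa}, {cb}:{pb}) not anchored "
                             "at candidate cleavage sites")

    # one canonical indel per planted site
    site_indels = {}
    for k, (chrom, pos, p_edit) in enumerate(offtarget_sites):
        r = child_rng(seed, "edit", "site", k)
        seq = genome.sequences[chrom]
        jitter = int(r.integers(-2, 3))
        at = max(1, min(len(seq) - 12, pos + jitter))
        if r.random() < 0.5:  # deletion of 1-8 bp
            d = int(r.integers(1, 9))
            ref_a, alt_a = seq[at - 1 : at + d], seq[at - 1]
        else:  # insertion of 1-3 bp
            ins = "".join(_BASES[r.integers(0, 4, size=int(r.integers(1, 4)))])
            ref_a, alt_a = seq[at - 1], seq[at - 1] + ins
        site_indels[k] = (chrom, at - 1, ref_a, alt_a, p_edit)

    cells, rows, bp_rows = [], [], []
    all_ids = [(f"edit_c{i}", grna) for i in range(n_cells)]
    all_ids += [(f"ctrl_c{i}", "control") for i in range(n_control)]
    cleav_list = sorted(cleav)
    for cid, received in all_ids:
        r = child_rng(seed, "edit", "cell", cid)
        recs = []
        if received != "control":
            for k, (chrom, p0, ref_a, alt_a, p_edit) in site_indels.items():
                if r.random() < p_edit:
                    recs.append((chrom, p0, ref_a, alt_a, "edit_indel"))
            for (ca, pa), (cb, pb) in sv_pairs:
                if r.random() < sv_prob:
                    bp_rows.append((cid, ca, int(pa + r.integers(-20, 21)),
                                    cb, int(pb + r.integers(-20, 21))))
        n_bg = r.poisson(background_ins_per_cell)
        for _ in range(n_bg):
            if cleav_list and r.random() < background_near_site_frac:
                chrom, c = cleav_list[r.integers(0, len(cleav_list))]
                p0 = int(np.clip(c + r.integers(-40, 41), 1, len(genome.sequences[chrom]) - 2))
            else:
                chrom = genome.names[r.integers(0, len(genome.names))]
                p0 = int(r.integers(1, len(genome.sequences[chrom]) - 2))
            ref_a = genome.base(chrom, p0)
            alt_a = ref_a + _BASES[r.integers(0, 4)]
            recs.append((chrom, p0, ref_a, alt_a, "false_positive"))
        recs = list(dict.fromkeys(recs))
        dp = np.maximum(_nb_depth(r, 30.0, 0.3, len(recs)), 1).astype(np.int64)
        ad_alt = np.maximum(r.binomial(dp, 0.5), 1)
        df = pd.DataFrame({
            "chrom": [x[0] for x in recs], "pos": [x[1] for x in recs],
            "ref": [x[2] for x in recs], "alt": [x[3] for x in recs],
            "dp": dp, "gq": _gq_from_ad(ad_alt),
            "ad_ref": dp - ad_alt, "ad_alt": ad_alt, "gt": "0/1",
        }) if recs else empty_frame()
        cells.append(CallSet(sample=cid, role="cell", df=df, meta={"grna": received}))
        for chrom, p0, ref_a, alt_a, lbl in recs:
            rows.append((chrom, p0, ref_a, alt_a, lbl, cid, 0.5))

    for cid, ca, pa, cb, pb in bp_rows:
        rows.append((ca, pa, ".", "<SV>", "edit_sv", cid, np.nan))
    truth = TruthTable(pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "label", "carrier", "planted_af"]
    ))
    breakpoints = pd.DataFrame(
        bp_rows, columns=["cell", "chrom_a", "pos_a", "chrom_b", "pos_b"]
    )
    return EditedDataset(cells=cells, breakpoints=breakpoints, truth=truth,
                         sites=candidates, grna=grna)
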