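"""Binned coverage and uniformity statistics.

The statistics quantify how evenly a whole-genome-amplification reaction
covered the genome:

* **CV** — coefficient of variation sigma(c)/mu(c) of the binned coverage
  vector c, with sample (n-1) standard deviation.
* **MAPD** — median of d_i = |x_{i+1} - x_i| with x_i = log2(c_i + 1),
  computed within each maximal run of consecutive unmasked bins and pooled
  across runs.  Small values mean locally smooth coverage.
* **Lorenz curve / Gini index** — cumulative share of reads vs share of
  bins; departure from the diagonal measures coverage inequality.
* **breadth** — fraction of bins (or bases) at or above a depth threshold.

Masked bins (assembly gaps, segmental duplications) are excluded from every
statistic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, merge_intervals
from ._rng import child_rng

__all__ = [
    "CoverageProfile",
    "bin_coverage",
    "cv",
    "mapd",
    "lorenz_curve",
    "gini",
    "breadth",
    "metric_vs_scale",
    "read_coverage_tsv",
    "write_coverage_tsv",
]

#: default bin width (bases) for whole-genome profiles
DEFAULT_BIN_SIZE = 100_000


@dataclass
class CoverageProfile:
    """Ordered uniform-width genomic bins with read counts.

    ``df`` columns: chrom, start, end, count, masked.  Bins are sorted and
    non-overlapping; width is uniform per chromosome (the last bin of a
    chromosome may be short).
    """

    df: pd.DataFrame
    bin_size: int | None = None

    def __post_init__(self):
        need = {"chrom", "start", "end", "count"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"coverage frame missing columns {sorted(missing)}")
        if "masked" not in self.df.columns:
            self.df = self.df.assign(masked=False)
        if len(self.df) == 0:
            raise ValueError("empty coverage profile")
        if (self.df["count"] < 0).any():
            raise ValueError("negative bin counts")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise ValueError(f"{chrom}: bins not sorted")
            bad = np.flatnonzero(ends[:-1] > starts[1:])
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"{chrom}: overlapping bins "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
        if self.bin_size is None:
            self.bin_size = int((self.df["end"] - self.df["start"]).max())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def counts(self) -> np.ndarray:
        """Counts of unmasked bins, in genomic order."""
        return self.df.loc[~self.df["masked"], "count"].to_numpy(dtype=float)

    def unmasked_runs(self) -> list[np.ndarray]:
        """Count vectors of maximal runs of consecutive unmasked bins.

        A run breaks at masked bins, chromosome boundaries, and gaps between
        non-adjacent bins.
        """
        runs: list[np.ndarray] = []
        cur: list[float] = []
        prev_chrom, prev_end = None, None
        for row in self.df.itertuples(index=False):
            adjacent = row.chrom == prev_chrom and row.start == prev_end
            if row.masked or not adjacent:
                if len(cur) > 0:
                    runs.append(np.asarray(cur, dtype=float))
                cur = []
            if not row.masked:
                cur.append(float(row.count))
            prev_chrom, prev_end = row.chrom, row.end
        if len(cur) > 0:
            runs.append(np.asarray(cur, dtype=float))
        return runs

    def rebinned(self, factor: int) -> "CoverageProfile":
        """Aggregate ``factor`` consecutive bins per chromosome into one.

        A merged bin is masked if any constituent bin is masked.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return CoverageProfile(self.df.copy(), self.bin_size)
        parts = []
        for chrom, sub in self.df.groupby("chrom", sort=False):
            g = np.arange(len(sub)) // factor
            agg = sub.groupby(g).agg(
                start=("start", "first"), end=("end", "last"),
                count=("count", "sum"), masked=("masked", "any"),
            )
            agg.insert(0, "chrom", chrom)
            parts.append(agg)
        df = pd.concat(parts, ignore_index=True)
        return CoverageProfile(df, self.bin_size * factor)

    def thinned(self, fraction: float, seed: int = 0) -> "CoverageProfile":
        """Binomially subsample each bin's count to ``fraction`` (seeded)."""
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must be in [0,1]")
        df = self.df.copy()
        if fraction < 1:
            rng = child_rng(seed, "thin")
            df["count"] = rng.binomial(df["count"].to_numpy(dtype=np.int64), fraction)
        return CoverageProfile(df, self.bin_size)


def bin_coverage(
    reads: pd.DataFrame,
    genome: Genome,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = 40,
) -> CoverageProfile:
    """Bin read start positions into uniform windows.

    ``reads`` needs columns chrom and pos (0-based start); an optional mapq
    column applies the MAPQ >= ``mapq_min`` filter.  Bins overlapping a
    masked genome interval are flagged and excluded from all statistics.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if "mapq" in reads.columns:
        reads = reads[reads["mapq"] >= mapq_min]
    parts = []
    for chrom, length in genome.lengths.items():
        if bin_size > length:
            warnings.warn(f"bin_size {bin_size} exceeds {chrom} length {length}; single bin")
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        sub = reads[reads["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = pos // bin_size
        counts = np.bincount(idx, minlength=len(starts)).astype(np.int64)
        masked = np.zeros(len(starts), dtype=bool)
        for ms, me in merge_intervals(genome.masks.get(chrom, [])):
            masked |= (starts < me) & (ends > ms)
        parts.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "count": counts, "masked": masked}
        ))
    return CoverageProfile(pd.concat(parts, ignore_index=True), bin_size)


def cv(profile: CoverageProfile) -> float:
    """Coefficient of variation sigma(c)/mu(c), sample (n-1) SD."""
    c = profile.counts
    if len(c) < 2:
        raise ValueError("CV needs at least 2 unmasked bins")
    mu = c.mean()
    if mu == 0:
        raise ValueError("CV undefined: mean coverage is zero")
    return float(c.std(ddof=1) / mu)


def mapd(profile: CoverageProfile) -> float:
    """Median absolute pairwise difference of log2(count + 1).

    Differences are taken between consecutive unmasked bins within each
    maximal run; runs broken by masks are computed separately and the d
    values pooled before taking the median (even count -> mean of the
    central pair).  The +1 pseudocount keeps zero-coverage bins finite,
    which preserves the artefactually low MAPD of profiles dominated by
    empty bins.
    """
    ds = []
    for run in profile.unmasked_runs():
        if len(run) >= 2:
            x = np.log2(run + 1.0)
            ds.append(np.abs(np.diff(x)))
    if not ds:
        raise ValueError("MAPD needs a run of >= 2 consecutive unmasked bins")
    return float(np.median(np.concatenate(ds)))


def lorenz_curve(profile: CoverageProfile) -> np.ndarray:
    """Lorenz points (fraction of bins, fraction of reads), bins sorted ascending.

    Returns an (n+1, 2) array from (0,0) to (1,1).  The diagonal is
    perfectly uniform coverage; sag below it is coverage inequality.
    """
    c = np.sort(profile.counts, kind="stable")
    total = c.sum()
    if total == 0:
        raise ValueError("Lorenz curve undefined: zero total reads")
    n = len(c)
    xs = np.arange(n + 1) / n
    ys = np.concatenate([[0.0], np.cumsum(c) / total])
    return np.column_stack([xs, ys])


def gini(profile: CoverageProfile) -> float:
    """Gini index: 1 - 2 * trapezoidal area under the Lorenz curve."""
    pts = lorenz_curve(profile)
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return 1.0 - 2.0 * area


def breadth(profile: CoverageProfile, min_depth: int = 1) -> float:
    """Fraction of unmasked bins with count >= min_depth."""
    c = profile.counts
    if len(c) == 0:
        raise ValueError("no unmasked bins")
    return float((c >= min_depth).mean())


def metric_vs_scale(
    profile: CoverageProfile,
    metric,
    bin_factors=(1, 2, 5, 10),
    thin_fractions=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Recompute a metric across bin sizes and/or subsampling fractions.

    ``metric`` is a callable CoverageProfile -> float (e.g. :func:`cv` or
    :func:`mapd`).  Thinning is seeded binomial subsampling of bin counts.
    Returns a tidy frame (bin_size, thin_fraction, value).
    """
    rows = []
    fractions = [1.0] if thin_fractions is None else list(thin_fractions)
    for factor in bin_factors:
        re = profile.rebinned(int(factor))
        for frac in fractions:
            p = re.thinned(frac, seed=seed) if frac < 1.0 else re
            rows.append({
                "bin_size": re.bin_size,
                "thin_fraction": frac,
                "value": metric(p),
            })
    return pd.DataFrame(rows)


def read_coverage_tsv(path) -> CoverageProfile:
    """Read a coverage TSV (chrom, start, end, count[, masked])."""
    df = pd.read_csv(path, sep="\t")
    if "masked" in df.columns:
        df["masked"] = df["masked"].astype(bool)
    return CoverageProfile(df)


def write_coverage_tsv(profile: CoverageProfile, path) -> None:
    profile.df.to_csv(path, sep="\t", index=False)
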