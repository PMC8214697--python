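# Methods

This note documents the models behind `scwga`: what the simulators
generate, what the estimators assume, the numerical conventions that pin
down every statistic, and what the package's validation does and does not
establish about real data.

## The amplification branching process

`simulate.simulate_amplification` models isothermal WGA as discrete rounds
of priming and extension on a pool of templates. Each round, template *i*
of length *Lᵢ* receives Poisson(priming_rate · Lᵢ/1000 · wᵢ) primers, where
the template weight *wᵢ* is 1 for the primary haplotypes and for
unterminated products, and `reprime_weight` ρ for terminated products.
Each primer starts at a uniform position, extends in a uniform random
direction, and stops after a geometric number of bases (per-base
termination probability α, mean product 1/α) or at the template end.
Copies inherit the template's error positions falling inside the copied
interval and add new errors at `error_rate` ε per base.

ρ is the single knob separating the chemistries: terminator-capped
products that cannot be extended or efficiently re-primed (ρ ≪ 1) give
quasilinear accumulation of copies made directly from the primary
template; ρ = 1 recovers exponential amplification in which products
template further products. Defaults:

| parameter | quasilinear | exponential | rationale |
|---|---|---|---|
| ρ | 0.05 | 1.0 | terminated ends are poor priming substrates |
| α | 2·10⁻³ | 5·10⁻⁵ | ~500 b products with terminators, tens of kb without |
| priming_rate | 0.1 /kb/round | 0.1 /kb/round | sparse random priming |
| ε | 10⁻⁶ | 10⁻⁶ | proofreading phi29-class polymerase |

No kinetic constants for the real reaction are available; this
parameterisation is a stand-in validated by qualitative ordering
properties (below), not a fit to chemistry.

**What the simulator does not model:** read-level artefacts (FASTQ,
sequencing error, mapping), chimera formation between amplicons, GC bias,
and real priming sequence preferences.

### Read sampling and error observables

`pool_to_coverage` draws reads from non-primary amplicons with probability
proportional to amplicon length (the two intact input molecules are
negligible library mass and are excluded), placing each read uniformly
within its amplicon. Binned counts tally read starts, matching how the
coverage statistics are computed on real data.

Two views of polymerase errors are provided. `error_allele_fractions`
measures, in a finite read sample, the allele fraction of each error that
reaches a caller-like support threshold. `error_mass_fractions` computes
the infinite-depth limit directly from the pool: for each error, the
fraction of covering amplicons that carry it, with the error's carrier
count as its observation weight (a sequencing experiment sees an error in
proportion to its carrier mass). The package's ordering property — that
quasilinear amplification gives lower observation-weighted median error
allele fractions than exponential amplification — uses the mass-level
statistic, because at tractable simulation scale the read-sampled median
is pinned at the 1/depth floor in both modes and discriminates structure
poorly. The comparison is run at matched priming rate, error rate, read
budget and total yield; matching yield means the quasilinear process runs
many more rounds (50 vs 3 by default in the validation), which is the
chemistry's nature — a linear process needs more cycles to reach the same
mass.

## Kindred-cell analysis

Kindred cells — single cells re-isolated from a 5-day clone grown from one
founder — are nearly genetically identical, so the clone's bulk sample
separates three classes of single-cell calls: germline (in the bulk),
somatic (absent from the bulk but recurrent in ≥ 2 cells, since a founder
mutation is inherited by the whole clone), and false positive (absent from
the bulk, private to one cell). The recurrence rule is the default;
`include_private_hq=True` additionally admits private high-quality calls
as somatic, for the looser reading under which the rate is an upper
bound.

Callable sites require bulk depth ≥ 15 and ≥ ⌈0.5 · n_cells⌉ cells at
depth ≥ 5. The depth table may carry a `span_bp` column giving the bases
of genome each row represents (1 for a per-base track); the callable span
in Mb is the summed span of passing rows. The site-sparse simulator emits
its truth-site depth table with span = genome_bp / n_sites, making
callable_Mb a consistent plug-in estimate of the callable fraction times
genome size.

The somatic rate estimator corrects for incomplete detection:

    rate = somatic_HQ / (sensitivity_HQ × callable_Mb)

with HQ = {DP ≥ 10, GQ ≥ 20, allele fraction ≥ 0.35}. sensitivity_HQ is
estimated per cell as the HQ recovery of germline variants that are
*bulk-heterozygous and bulk-HQ* — heterozygous, because somatic variants
are single-allele events and homozygous germline sites pass the allele-
fraction filter more easily, which would bias the correction; bulk-HQ, so
the same filters apply to numerator and denominator. Remaining known
biases are small: founder somatics detected in ≤ 1 cell are misclassified
(≪ 1 % at detection ≥ 0.8 with 5 cells), and false-positive collisions
across cells are negligible at genome scale.

`KindredModel.fit()` packages filter → classify → summarise → estimate and
returns a results object whose `summary()` prints per-cell rates with the
cross-cell mean ± SE.

### The kindred generator's study conditions

Defaults encode the hematopoietic single-cell study design: 5 cells,
3,088 Mb genome (GRCh38 primary assembly), 1,000 germline variants per Mb
(≈ 3.1 M variants, 1/3 homozygous), founder somatic rate 0.33 per Mb,
private false-positive burden Poisson(2,785) per cell with Beta(2, 6)
allele fractions (the low-VAF skew of amplification artefacts), and
per-variant detection probability 0.85 applied independently per cell.
Per-site depth is negative binomial with mean 30 (bulk 40) and variance
m + 0.3 m²; allele depth is binomial in the planted fraction; GQ is
deterministic, min(99, 3 · alt reads). These choices reproduce
overdispersed depth and filter behaviour without modelling reads.

## Mutagen-exposure analysis

A variant is mutagen-attributed only if called in exactly one cell, absent
from the bulk call set, at a site the bulk covers at ≥ 15× (absence is
only assertable where the bulk had power). Per-cell sets are therefore
pairwise disjoint. The dose design default mirrors a two-compound layout
(vehicle; two mannitol doses; three mutagen doses with n = 5,5,4). The
generator draws each mutation's 6-class change from a spectrum
(default weighted to T>A, T>C, C>T — the alkylator preference) and its
position from genome positions with the matching pyrimidine-strand base,
so trinucleotide contexts are well defined.

DNase-hypersensitive-site enrichment extends DHS intervals by two
nucleosomes (340 b) each side, merges overlaps, computes the fraction of
the ≥ 10×-covered genome inside extended DHS and the fraction of variants
(at covered positions) inside them; their ratio is 1 under positional
independence. Variant containment uses the single base position,
half-open intervals.

## Spectra and signature reconstruction

Substitutions are collapsed to the pyrimidine-reference convention (G>A
becomes C>T with reverse-complemented context). The 96 channels are keyed
5'base[class]3'base in the canonical class-then-context order. Variants at
sequence edges or with N in the context are skipped and counted.
Reconstruction solves min‖s − M e‖₂, e ≥ 0 by non-negative least squares
against a user-supplied reference-signature matrix (columns sum to 1) and
reports the cosine similarity between the observed spectrum and M e. No
signature catalogue is bundled; tests use synthetic matrices.

## CRISPR off-target attribution

Candidate sites are every 23-mer on either strand whose last two bases are
GG (the N of NGG is free) and whose first 20 bases differ from the
protospacer at ≤ 5 positions; windows containing N are skipped. The
cleavage coordinate is the blunt cut between protospacer positions 17 and
18 (3 bp 5' of the PAM): forward-strand boundary start+17 on plus sites,
start+6 on minus sites (both in forward coordinates).

Indels are attributed when the leftmost coordinate lies within ± 50 bp of
a cleavage site of the cell's own guide (`span_overlap=True` instead
admits any overlap of the indel span with the window — the leftmost-
coordinate rule is the default because long deletions otherwise make the
window unbounded on one side), are absent from the bulk, and absent from
every cell that received a different guide. Kept indels attach to the
nearest cleavage site, ties to the lower coordinate. Indels in control or
other-guide cells that land in some guide's windows are reported
separately as presumed false positives. The recurrence filter then removes
1-bp insertions seen at their site in exactly one cell — the dominant
artefact class — keeping deletions, longer insertions and recurrent 1-bp
insertions. Structural variants require both breakpoints within ± 200 bp
of (possibly different) cleavage sites and exclusion from control and
other-guide cells.

The edited-cell generator chooses one canonical repair product per planted
site (real repair outcomes recur), applies it with the site's edit
probability and ≤ 2 bp jitter, and plants private background 1-bp
insertions, a configurable fraction inside attribution windows so the
recurrence filter is exercised end to end.

## Numerical conventions

* Coordinates 0-based half-open internally; VCF positions converted at the
  pysam boundary; BED is already half-open.
* CV uses the sample (n−1) standard deviation; MAPD uses the log₂(c+1)
  pseudocount (which preserves the artefactually low MAPD of profiles
  dominated by empty bins); medians of even-length vectors average the
  central pair; the Lorenz AUC is trapezoidal on ascending-sorted bins
  with stable ties.
* Allele fraction is always recomputed as alt/(ref+alt) from allele
  depths, never read from an AF tag; a missing genotype is "not called"
  in all set logic; variant identity is (chrom, pos, alt) — genotype
  mismatches still count as detected.
* All generators derive their streams from one root seed via labeled
  child seeds (CRC-coded labels), so outputs are byte-identical across
  runs and adding a cell does not perturb other cells' draws.
* ⌈50 %⌉ (ceiling) convention for "at least half the cells".

## Problem sizes used in validation

The test suite and acceptance script run entirely on synthetic data: the
kindred recovery experiment at full study scale (5 cells × 3,088 Mb,
site-sparse, ~3.1 M sites; 3 seeds in the suite, 10 in the acceptance
script), precision at 3.2 M germline variants, coverage/ordering
properties on 20–150 kb toy genomes with 100 paired seeds, and off-target
enumeration against a brute-force oracle on 200 random genomes of
≤ 1 kb. Passing these establishes internal correctness of the statistics,
filters and estimators under the generators' assumptions — not
performance on real sequencing data, whose artefact structure (mapping
error, chimeras, context-dependent FP hotspots near centromeres and
telomeres) the generators deliberately do not emulate.

## Known limitations

* The branching-process parameters are qualitative stand-ins; absolute
  coverage statistics from the simulator should not be compared to real
  libraries, only orderings between modes.
* The somatic-rate correction assumes somatic variants share the
  bulk-heterozygous germline detection distribution; copy-number-variable
  or tetraploid regions violate this and are not modelled.
* No positional model of false positives (real artefacts cluster near
  centromeres/telomeres); no signature-aware false-positive rescue.
* The VCF dialect is minimal: biallelic records with GT:DP:GQ:AD, no
  phasing, no symbolic alleles (breakpoints travel in TSV tables).
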