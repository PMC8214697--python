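"""Generative simulators: branching process, read sampling, dataset builders."""
import numpy as np
import pandas as pd
import pytest

from scwga.genome import Genome
from scwga.simulate import (
    DMEM_DESIGN,
    SimConfig,
    allele_depths,
    error_mass_fractions,
    pool_to_coverage,
    simulate_amplification,
    simulate_edited_dataset,
    simulate_kindred_dataset,
    simulate_mutagen_dataset,
)
from scwga.variants import variant_keys


def _flat_genome(length, name="chr1"):
    return Genome({name: "A" * length})


class TestSimConfig:
    def test_mode_defaults(self):
        q = SimConfig(mode="quasilinear")
        e = SimConfig(mode="exponential")
        assert q.reprime_weight < e.reprime_weight == 1.0
        assert q.termination_prob > e.termination_prob

    def test_zero_rounds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(rounds=0)

    def test_zero_termination_in_quasilinear_warns(self):
        with pytest.warns(UserWarning):
            SimConfig(mode="quasilinear", termination_prob=0.0)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(priming_rate=1.5)


class TestAmplification:
    def test_deterministic_given_seed(self, random_genome):
        cfg = SimConfig(rounds=4, priming_rate=0.5, error_rate=1e-3)
        a = simulate_amplification(random_genome, cfg, seed=3)
        b = simulate_amplification(random_genome, cfg, seed=3)
        assert np.array_equal(a.start, b.start)
        assert np.array_equal(a.end, b.end)
        assert a.errors == b.errors
        c = simulate_amplification(random_genome, cfg, seed=4)
        assert not (len(a) == len(c) and np.array_equal(a.start, c.start))

    def test_mean_amplicon_length_matches_geometric_expectation(self):
        """One round at termination prob 0.001 gives mean length ~1000 b."""
        genome = _flat_genome(6_000_000)
        cfg = SimConfig(rounds=1, priming_rate=1.0, termination_prob=1e-3,
                        max_amplicons=50_000)
        pool = simulate_amplification(genome, cfg, seed=1)
        lens = pool.lengths[pool.daughters()]
        assert len(lens) >= 10_000
        assert lens.mean() == pytest.approx(1000.0, rel=0.05)

    def test_exponential_count_growth_matches_independent_recurrence(self):
        """Amplicon counts in exponential mode track a stripped-down
        branching process simulated independently, and grow geometrically."""
        glen = 50_000
        genome = _flat_genome(glen)
        rate, rounds = 0.05, 6
        counts = []
        for r in range(1, rounds + 1):
            cfg = SimConfig(mode="exponential", priming_rate=rate, rounds=r,
                            termination_prob=0.0, max_amplicons=400_000)
            pools = [simulate_amplification(genome, cfg, seed=s) for s in range(25)]
            counts.append(np.mean([len(p.daughters()) for p in pools]))

        # independent oracle: lengths-only branching process, own RNG
        rng = np.random.default_rng(777)
        oracle = []
        for _ in range(200):
            lengths = [float(glen), float(glen)]
            traj = []
            for _r in range(rounds):
                new = []
                for L in lengths:
                    for _k in range(rng.poisson(rate * L / 1000.0)):
                        pos = rng.uniform(0, L)
                        new.append(L - pos if rng.random() < 0.5 else pos)
                lengths.extend(new)
                traj.append(len(lengths) - 2)
            oracle.append(traj)
        oracle = np.mean(oracle, axis=0)
        assert np.allclose(counts, oracle, rtol=0.25)
        ratios = np.array(counts[2:]) / np.array(counts[1:-1])
        assert (ratios > 1.2).all()  # supralinear growth round over round

    def test_quasilinear_amplicons_shorter_than_exponential(self, random_genome):
        for seed in range(5):
            q = simulate_amplification(
                random_genome, SimConfig(mode="quasilinear", rounds=3), seed=seed)
            e = simulate_amplification(
                random_genome, SimConfig(mode="exponential", rounds=3), seed=seed)
            assert q.lengths[q.daughters()].mean() < e.lengths[e.daughters()].mean()

    def test_errors_lie_inside_their_amplicons(self, random_genome):
        cfg = SimConfig(rounds=4, priming_rate=0.5, error_rate=5e-3)
        pool = simulate_amplification(random_genome, cfg, seed=9)
        for i in range(len(pool)):
            for e in pool.errors[i]:
                assert pool.start[i] <= e < pool.end[i]

    def test_generation_zero_is_intact_haplotypes(self, random_genome):
        pool = simulate_amplification(random_genome, SimConfig(rounds=1), seed=0)
        prim = np.flatnonzero(pool.generation == 0)
        assert len(prim) == 2
        assert (pool.start[prim] == 0).all()
        assert (pool.end[prim] == 50_000).all()


class TestPoolToCoverage:
    def test_zero_reads_all_bins_zero(self, random_genome):
        pool = simulate_amplification(random_genome, SimConfig(rounds=2), seed=0)
        prof, reads = pool_to_coverage(pool, bin_size=5000, reads=0, seed=0)
        assert prof.df["count"].sum() == 0 and len(reads) == 0

    def test_counts_sum_to_reads(self, random_genome):
        pool = simulate_amplification(
            random_genome, SimConfig(rounds=3, priming_rate=0.5), seed=1)
        prof, reads = pool_to_coverage(pool, bin_size=5000, reads=500, seed=1)
        assert prof.df["count"].sum() == 500 == len(reads)

    def test_single_amplicon_concentrates_one_bin(self):
        genome = _flat_genome(10_000)
        # force exactly one daughter by manual pool surgery
        pool = simulate_amplification(
            genome, SimConfig(rounds=1, priming_rate=0.001), seed=0)
        from scwga.simulate import AmpliconPool
        single = AmpliconPool(
            chrom_names=pool.chrom_names, chrom_lengths=pool.chrom_lengths,
            chrom=np.array([0, 0, 0], dtype=np.int32),
            start=np.array([0, 0, 2_100], dtype=np.int64),
            end=np.array([10_000, 10_000, 2_900], dtype=np.int64),
            haplotype=np.array([0, 1, 0], dtype=np.int8),
            generation=np.array([0, 0, 1], dtype=np.int16),
            terminated=np.array([False, False, True]),
            errors=[(), (), ()],
        )
        prof, _ = pool_to_coverage(single, bin_size=1000, reads=100, seed=2)
        assert prof.df["count"].iloc[2] == 100
        assert prof.df["count"].sum() == 100

    def test_allele_depths_split_by_haplotype(self, random_genome):
        pool = simulate_amplification(
            random_genome, SimConfig(rounds=3, priming_rate=0.8), seed=5)
        _, reads = pool_to_coverage(pool, bin_size=5000, reads=2000, seed=5)
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10_000, 25_000, 40_000]})
        depths = allele_depths(reads, sites)
        assert (depths["depth"] == depths["depth_hap0"] + depths["depth_hap1"]).all()
        assert depths["depth"].sum() > 0

    def test_error_mass_fractions_bounded(self, random_genome):
        pool = simulate_amplification(
            random_genome,
            SimConfig(rounds=3, priming_rate=0.5, error_rate=1e-3), seed=6)
        _, reads = pool_to_coverage(pool, bin_size=5000, reads=1000, seed=6)
        ev = error_mass_fractions(pool)
        assert ((ev["vaf"] > 0) & (ev["vaf"] <= 1)).all()
        assert (ev["carriers"] <= ev["covering"]).all()


class TestKindredDataset:
    def test_perfect_detection_reproduces_bulk_union_founders(self):
        d = simulate_kindred_dataset(
            n_cells=3, genome_mb=2.0, germline_density=50, somatic_rate=5,
            fp_burden=0.0, detect_prob=1.0, seed=11)
        truth_keys = set(zip(d.truth.df["chrom"], d.truth.df["pos"], d.truth.df["alt"]))
        bulk_keys = set(map(tuple, variant_keys(d.bulk.df)))
        for cell in d.cells:
            cell_keys = set(map(tuple, variant_keys(cell.df)))
            assert cell_keys == truth_keys
            assert bulk_keys < cell_keys  # bulk germline plus founder somatics

    def test_germline_het_allele_fraction_near_half(self):
        d = simulate_kindred_dataset(
            n_cells=2, genome_mb=5.0, germline_density=1000, somatic_rate=0,
            fp_burden=0, detect_prob=1.0, hom_fraction=0.0, seed=12)
        cell = d.cells[0]
        assert cell.vaf.mean() == pytest.approx(0.5, abs=0.01)

    def test_truth_bookkeeping_matches_emitted_calls(self):
        d = simulate_kindred_dataset(
            n_cells=3, genome_mb=2.0, germline_density=100, somatic_rate=10,
            fp_burden=20, detect_prob=1.0, seed=13)
        counts = d.truth.counts()
        assert counts.get("germline", 0) == len(d.bulk)
        fp = d.truth.subset("false_positive")
        for cell in d.cells:
            mine = fp[fp["carrier"] == cell.sample]
            cell_keys = set(map(tuple, variant_keys(cell.df)))
            assert all(
                (r.chrom, r.pos, r.alt) in cell_keys for r in mine.itertuples()
            )

    def test_fp_allele_fractions_skew_low(self):
        d = simulate_kindred_dataset(
            n_cells=2, genome_mb=1.0, germline_density=0, somatic_rate=0,
            fp_burden=500, detect_prob=1.0, seed=14)
        vafs = d.cells[0].vaf
        assert vafs.median() < 0.35  # Beta(2,6) artefact skew

    def test_deterministic_and_stable_per_cell_streams(self):
        a = simulate_kindred_dataset(n_cells=3, genome_mb=1.0, seed=15)
        b = simulate_kindred_dataset(n_cells=3, genome_mb=1.0, seed=15)
        for ca, cb in zip(a.cells, b.cells):
            pd.testing.assert_frame_equal(ca.df, cb.df)
        pd.testing.assert_frame_equal(a.depths, b.depths)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_kindred_dataset(n_cells=1, genome_mb=1.0)


class TestMutagenDataset:
    def test_zero_dose_function_gives_no_variants(self, random_genome):
        d = simulate_mutagen_dataset(
            random_genome, doses=[("vehicle", 0.0, 3)],
            mutations_per_cell=lambda c, dose: 0.0, seed=21)
        assert all(len(c) == 0 for c in d.cells)
        assert len(d.truth.df) == 0

    def test_spectrum_recovered_within_multinomial_ci(self, random_genome):
        """Observed 6-class proportions sit inside the 99% envelope at n=10,000."""
        from scwga.varianteval import base_change_spectrum

        probs = {"C>A": 0.1 / 3, "C>G": 0.1 / 3, "C>T": 0.3,
                 "T>A": 0.3, "T>C": 0.3, "T>G": 0.1 / 3}
        d = simulate_mutagen_dataset(
            random_genome, doses=[("ENU", 100.0, 2)],
            mutations_per_cell=lambda c, dose: 5000.0,
            spectrum_probs=probs, seed=22)
        counts = base_change_spectrum(d.truth.df[["chrom", "pos", "ref", "alt"]])
        n = counts.sum()
        assert n >= 9500
        for cls, p in probs.items():
            half_width = 2.576 * np.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - n * p) <= half_width + 1

    def test_linear_dose_response_scales_tenfold(self, random_genome):
        d = simulate_mutagen_dataset(
            random_genome, doses=[("ENU", 10.0, 20), ("ENU", 100.0, 20)],
            mutations_per_cell=lambda c, dose: 0.2 * dose, seed=23)
        lo = np.mean([len(c) for c in d.cells if c.meta["dose"] == 10.0])
        hi = np.mean([len(c) for c in d.cells if c.meta["dose"] == 100.0])
        assert hi / lo == pytest.approx(10.0, rel=0.3)

    def test_default_design_layout(self, random_genome):
        d = simulate_mutagen_dataset(random_genome, seed=24)
        sizes = pd.Series(
            [(c.meta["compound"], c.meta["dose"]) for c in d.cells]
        ).value_counts()
        assert sizes[("ENU", 854.0)] == 4  # top mutagen dose has one fewer cell
        assert sizes[("vehicle", 0.0)] == 5
        assert len(d.cells) == sum(n for _, _, n in DMEM_DESIGN)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_mutagen_dataset(Genome({}), seed=0)


PROTO = "GATTACAGATTACAGATTAC"


def _edited_genome():
    rng = np.random.default_rng(31)
    seq = list("".join(rng.choice(list("ACGT"), size=6000)))
    # on-target: exact protospacer + AGG PAM at 1000
    seq[1000:1023] = PROTO + "AGG"
    # off-target: two mismatches + TGG PAM at 3000
    off = "GATTAGAGATTACAGATAAC"
    seq[3000:3023] = off + "TGG"
    return Genome({"chr1": "".join(seq)})


class TestEditedDataset:
    def test_control_cells_without_background_have_no_indels(self):
        g = _edited_genome()
        d = simulate_edited_dataset(
            g, PROTO, n_cells=2, offtarget_sites=[("chr1", 1017, 1.0)],
            n_control=2, background_ins_per_cell=0.0, seed=41)
        controls = [c for c in d.cells if c.meta["grna"] == "control"]
        assert all(len(c) == 0 for c in controls)

    def test_planted_site_must_match_protospacer(self):
        g = _edited_genome()
        with pytest.raises(ValueError, match="chr1:42"):
            simulate_edited_dataset(
                g, PROTO, offtarget_sites=[("chr1", 42, 0.5)], seed=42)

    def test_edits_recur_across_cells_at_same_site(self):
        g = _edited_genome()
        d = simulate_edited_dataset(
            g, PROTO, n_cells=6, offtarget_sites=[("chr1", 1017, 1.0)],
            n_control=0, background_ins_per_cell=0.0, seed=43)
        edits = d.truth.subset("edit_indel")
        keys = set(zip(edits["pos"], edits["ref"], edits["alt"]))
        assert len(keys) == 1  # one canonical repair product, carried by all
        assert len(edits) == 6

    def test_sv_breakpoints_land_near_cleavage_sites(self):
        g = _edited_genome()
        d = simulate_edited_dataset(
            g, PROTO, n_cells=5,
            sv_pairs=[(("chr1", 1017), ("chr1", 3017))], sv_prob=1.0,
            n_control=2, background_ins_per_cell=0.0, seed=44)
        assert len(d.breakpoints) == 5
        assert (abs(d.breakpoints["pos_a"] - 1017) <= 20).all()
        assert (abs(d.breakpoints["pos_b"] - 3017) <= 20).all()
        assert not d.breakpoints["cell"].str.startswith("ctrl").any()
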