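"""CRISPR candidate-site enumeration and indel/SV attribution rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scwga.genome import Genome
from scwga.offtarget import (
    CandidateSite,
    ProtospacerQuery,
    attribute_indels,
    attribute_svs,
    enumerate_candidate_sites,
    recurrence_filter,
)
from scwga.variants import CallSet, VariantRecord

PROTO = "GATTACAGATTACAGATTAC"
COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_sites(genome, proto, max_mm):
    """Naive double-strand scan used as the enumeration oracle."""
    hits = []
    for chrom, seq in genome.sequences.items():
        rc = seq.translate(COMP)[::-1]
        L = len(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(L - 22):
                w = s[i : i + 23]
                if "N" in w or w[21:23] != "GG":
                    continue
                mm = sum(a != b for a, b in zip(w[:20], proto))
                if mm <= max_mm:
                    if strand == "+":
                        hits.append((chrom, i, "+", mm, i + 17))
                    else:
                        fwd = L - 23 - i
                        hits.append((chrom, fwd, "-", mm, fwd + 6))
    return sorted(hits)


def _genome_with(inserts, length=3000, seed=0):
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    for pos, s in inserts:
        seq[pos : pos + len(s)] = s
    return Genome({"chr1": "".join(seq)})


class TestEnumeration:
    def test_exact_plus_strand_embedding(self):
        g = _genome_with([(500, PROTO + "AGG")])
        sites = [s for s in enumerate_candidate_sites(g, ProtospacerQuery(PROTO))
                 if s.mismatches == 0]
        assert any(s.start == 500 and s.strand == "+" and s.cleavage == 517
                   for s in sites)

    def test_reverse_complement_embedding_maps_to_forward(self):
        payload = (PROTO + "CGG").translate(COMP)[::-1]
        g = _genome_with([(800, payload)])
        sites = [s for s in enumerate_candidate_sites(g, ProtospacerQuery(PROTO))
                 if s.mismatches == 0 and s.strand == "-"]
        assert any(s.start == 800 and s.cleavage == 806 for s in sites)
        oracle = brute_force_sites(g, PROTO, 5)
        mine = sorted((s.chrom, s.start, s.strand, s.mismatches, s.cleavage)
                      for s in enumerate_candidate_sites(g, ProtospacerQuery(PROTO)))
        assert mine == oracle

    def test_six_mismatches_not_reported(self):
        mutated = "CCAATGAGATTACAGATTAC"  # 6 mismatches vs PROTO
        assert sum(a != b for a, b in zip(mutated, PROTO)) == 6
        g = _genome_with([(500, mutated + "AGG")])
        sites = enumerate_candidate_sites(g, ProtospacerQuery(PROTO))
        assert not any(s.start == 500 and s.strand == "+" for s in sites)

    def test_nag_pam_not_reported(self):
        g = _genome_with([(500, PROTO + "AAG")])
        sites = enumerate_candidate_sites(g, ProtospacerQuery(PROTO))
        assert not any(s.start == 500 and s.strand == "+" and s.mismatches == 0
                       for s in sites)

    def test_n_window_skipped(self):
        g = Genome({"c": "N" * 10 + PROTO + "AGG" + "N" * 10})
        weird = Genome({"c": ("N" + PROTO[1:]) + "AGG"})
        assert enumerate_candidate_sites(weird, ProtospacerQuery(PROTO)) == []
        hits = enumerate_candidate_sites(g, ProtospacerQuery(PROTO))
        assert any(s.mismatches == 0 for s in hits)

    def test_bad_protospacer_rejected(self):
        with pytest.raises(ValueError):
            ProtospacerQuery("ACGT")

    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 5))
    @settings(max_examples=30)
    def test_matches_brute_force_on_random_genomes(self, seed, max_mm):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=400, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        proto = "".join(rng.choice(list("ACGT"), size=20))
        g = Genome({"c": seq})
        q = ProtospacerQuery(proto, max_mismatches=max_mm)
        mine = sorted((s.chrom, s.start, s.strand, s.mismatches, s.cleavage)
                      for s in enumerate_candidate_sites(g, q))
        assert mine == brute_force_sites(g, proto, max_mm)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20)
    def test_count_monotone_in_mismatch_budget(self, seed):
        rng = np.random.default_rng(seed)
        g = Genome({"c": "".join(rng.choice(list("ACGT"), size=600))})
        proto = "".join(rng.choice(list("ACGT"), size=20))
        counts = [
            len(enumerate_candidate_sites(g, ProtospacerQuery(proto, max_mismatches=m)))
            for m in range(6)
        ]
        assert counts == sorted(counts)


def _indel_cs(sample, rows, grna):
    recs = [VariantRecord("chr1", p, r, a, 30, 60, 15, 15, "0/1") for p, r, a in rows]
    cs = CallSet.from_records(sample, recs)
    cs.meta["grna"] = grna
    return cs


def _sites(*cleavages):
    return [
        CandidateSite("chr1", c - 17, c + 6, "+", 2, c) for c in cleavages
    ]


EMPTY_BULK = CallSet(sample="bulk", role="bulk")


class TestIndelAttribution:
    def test_window_rule(self):
        sites = {"g1": _sites(1000)}
        cells = [
            _indel_cs("e1", [(1010, "A", "AT")], "g1"),   # 10 bp away
            _indel_cs("e2", [(1060, "A", "AT")], "g1"),   # 60 bp away
        ]
        att = attribute_indels(cells, sites, EMPTY_BULK, window=50)
        assert att.attributed["cell"].tolist() == ["e1"]
        assert att.attributed["distance"].tolist() == [10]

    def test_bulk_indels_excluded(self):
        sites = {"g1": _sites(1000)}
        bulk = CallSet.from_records(
            "bulk", [VariantRecord("chr1", 1010, "A", "AT", 60, 99, 30, 30, "0/1")],
            role="bulk")
        cells = [_indel_cs("e1", [(1010, "A", "AT")], "g1")]
        att = attribute_indels(cells, sites, bulk)
        assert len(att.attributed) == 0

    def test_other_grna_cells_exclude_shared_indels(self):
        sites = {"g1": _sites(1000), "g2": _sites(5000)}
        cells = [
            _indel_cs("e1", [(1010, "A", "AT")], "g1"),
            _indel_cs("e2", [(1010, "A", "AT")], "g2"),  # same indel, other gRNA
        ]
        att = attribute_indels(cells, sites, EMPTY_BULK)
        assert len(att.attributed) == 0

    def test_control_cell_hits_reported_as_presumed_fp(self):
        sites = {"g1": _sites(1000)}
        cells = [
            _indel_cs("ctrl", [(1005, "A", "AT")], "control"),
        ]
        att = attribute_indels(cells, sites, EMPTY_BULK)
        assert len(att.attributed) == 0
        assert att.presumed_fp["cell"].tolist() == ["ctrl"]

    def test_nearest_site_tie_breaks_to_lower_coordinate(self):
        sites = {"g1": _sites(1000, 1040)}
        cells = [_indel_cs("e1", [(1020, "A", "AT")], "g1")]
        att = attribute_indels(cells, sites, EMPTY_BULK)
        assert att.attributed["site_cleavage"].tolist() == [1000]

    def test_span_overlap_mode_admits_long_deletion(self):
        sites = {"g1": _sites(1000)}
        # deletion starting 80 bp upstream whose span reaches the window
        rows = [(920, "A" * 40, "A")]
        cells = [_indel_cs("e1", rows, "g1")]
        strict = attribute_indels(cells, sites, EMPTY_BULK, window=50)
        loose = attribute_indels(cells, sites, EMPTY_BULK, window=50, span_overlap=True)
        assert len(strict.attributed) == 0
        assert len(loose.attributed) == 1

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            attribute_indels([], {}, EMPTY_BULK)

    def test_snvs_ignored(self):
        sites = {"g1": _sites(1000)}
        cells = [_indel_cs("e1", [(1005, "A", "G")], "g1")]
        att = attribute_indels(cells, sites, EMPTY_BULK)
        assert len(att.attributed) == 0


class TestRecurrenceFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["cell", "chrom", "pos", "ref", "alt",
                           "site_cleavage", "distance"]
        )

    def test_single_cell_one_bp_insertion_removed(self):
        t = self._table([("e1", "chr1", 10, "A", "AT", 20, 10)])
        kept, removed = recurrence_filter(t)
        assert len(kept) == 0 and removed == 1

    def test_recurrent_one_bp_insertion_kept(self):
        t = self._table([
            ("e1", "chr1", 10, "A", "AT", 20, 10),
            ("e2", "chr1", 10, "A", "AT", 20, 10),
        ])
        kept, removed = recurrence_filter(t)
        assert len(kept) == 2 and removed == 0

    def test_deletion_and_long_insertion_kept(self):
        t = self._table([
            ("e1", "chr1", 10, "ACGT", "A", 20, 10),
            ("e1", "chr1", 50, "A", "ATTT", 60, 10),
        ])
        kept, removed = recurrence_filter(t)
        assert len(kept) == 2 and removed == 0


class TestSvAttribution:
    def _bp(self, rows):
        return pd.DataFrame(
            rows, columns=["cell", "chrom_a", "pos_a", "chrom_b", "pos_b"]
        )

    def test_dual_window_rule(self):
        sites = {"g1": _sites(1000, 8000)}
        bp = self._bp([
            ("e1", "chr1", 1050, "chr1", 7950),   # both within 200
            ("e2", "chr1", 1500, "chr1", 8000),   # one end 500 away
        ])
        out = attribute_svs(bp, sites, {"e1": "g1", "e2": "g1"})
        assert out["cell"].tolist() == ["e1"]
        assert out[["site_a", "site_b"]].iloc[0].tolist() == [1000, 8000]

    def test_event_in_control_cell_excludes_everywhere(self):
        sites = {"g1": _sites(1000, 8000)}
        bp = self._bp([
            ("e1", "chr1", 1050, "chr1", 7950),
            ("ctrl", "chr1", 1050, "chr1", 7950),
        ])
        out = attribute_svs(bp, sites, {"e1": "g1", "ctrl": "control"})
        assert len(out) == 0

    def test_malformed_pair_rejected(self):
        sites = {"g1": _sites(1000)}
        bp = self._bp([("e1", "chr1", 1050, None, np.nan)])
        with pytest.raises(ValueError, match="0"):
            attribute_svs(bp, sites, {"e1": "g1"})
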