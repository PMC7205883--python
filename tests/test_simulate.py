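"""Population simulator: telomere construction, events, reads, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linearends import simulate, struct
from linearends._seq import revcomp


@given(st.text(alphabet="ACGT", max_size=200))
@settings(max_examples=50, deadline=None)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


class TestBuildTelomere:
    def test_single_stem_exact_arm(self):
        telo = simulate.build_telomere("CTTG", 1, stem_range=(5, 5),
                                       spacer_range=(0, 0), seed=2)
        assert len(telo) == 180
        arm5 = [h for h in struct.find_hairpins(telo, max_stem_mismatch=0)
                if h.arm_len == 5 and h.loop_seq == "CTTG"]
        assert len(arm5) == 1

    def test_zero_stems_gives_unstructured_sequence(self):
        telo = simulate.build_telomere("GGA", 0, seed=5)
        assert len(telo) == 180
        assert struct.fold_telomere(telo).hairpins == []

    def test_overflow_raises(self):
        with pytest.raises(simulate.ConstructionOverflow):
            simulate.build_telomere("CTTG", 12, stem_range=(8, 8),
                                    spacer_range=(6, 6), seed=0)

    def test_deterministic(self):
        a = simulate.build_telomere("GGA", 6, seed=9)
        b = simulate.build_telomere("GGA", 6, seed=9)
        assert a == b

    def test_stems_abut_terminus(self):
        telo = simulate.build_telomere("GGA", 6, seed=1)
        st_ = struct.fold_telomere(telo)
        assert max(h.end for h in st_.hairpins) == 180


class TestSimulatePopulation:
    def test_zero_rate_identity(self):
        cfg = simulate.PopulationConfig(n_strains=3, chromosome_length=10_000,
                                        tir_length=1_000,
                                        substitution_rate=0.0, seed=4)
        reps = simulate.simulate_population(cfg)
        assert len({r.sequence for r in reps}) == 1
        assert all(r.truth.tir_interval_left == (0, 1000) for r in reps)

    def test_tirs_are_exact_reverse_complements(self, small_replicon):
        s = small_replicon.sequence
        T = small_replicon.truth.tir_length_left
        assert s[:T] == revcomp(s[-T:])

    def test_telomere_swap_matches_donor(self):
        cfg = simulate.PopulationConfig(
            n_strains=2, chromosome_length=10_000, tir_length=1_000,
            substitution_rate=0.0, seed=6,
            plasmids=[{"id": "p1", "length": 5_000, "tir_length": 500,
                       "telomere_motif": "GCA"}],
            event_list=[simulate.EvolutionEvent(
                "telomere_swap", "strain01", payload=("p1", "right"))])
        reps = simulate.simulate_population(cfg)
        s1, s2, p1 = reps
        assert s1.truth.telomere_right == p1.truth.telomere_right
        # non-terminal sequence unchanged relative to the sister strain
        assert s1.sequence[:-180] == s2.sequence[:-180]

    def test_bir_homogenize_grows_tirs(self):
        cfg = simulate.PopulationConfig(
            n_strains=1, chromosome_length=50_000, tir_length=5_000,
            substitution_rate=0.0, seed=7)
        (rep,) = simulate.simulate_population(cfg)
        before = rep.sequence
        simulate._apply_event({rep.id: rep}, simulate.EvolutionEvent(
            "bir_homogenize", rep.id, length=7_000, payload="right"))
        after = rep.sequence
        assert len(after) == len(before)
        assert rep.truth.tir_interval_left == (0, 7_000)
        assert after[:7_000] == revcomp(after[-7_000:])
        # right arm (donor) untouched; left arm recopied from it
        assert after[7_000:] == before[7_000:]
        assert after[:7_000] == revcomp(before[-7_000:])

    def test_hgt_replace_copies_donor_segment(self):
        cfg = simulate.PopulationConfig(
            n_strains=2, chromosome_length=10_000, tir_length=1_000,
            substitution_rate=1e-2, seed=8,
            event_list=[simulate.EvolutionEvent(
                "hgt_insert", "strain01", position=3_000, length=500,
                payload=("replace", "strain02"))])
        s1, s2 = simulate.simulate_population(cfg)
        assert s1.sequence[3_000:3_500] == s2.sequence[3_000:3_500]

    def test_event_out_of_bounds_rejected(self):
        cfg = simulate.PopulationConfig(
            n_strains=1, chromosome_length=10_000, tir_length=1_000,
            seed=9, event_list=[simulate.EvolutionEvent(
                "inversion", "strain01", position=9_500, length=1_000)])
        with pytest.raises(ValueError):
            simulate.simulate_population(cfg)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            simulate.PopulationConfig(n_strains=0)
        with pytest.raises(ValueError):
            simulate.PopulationConfig(chromosome_length=10_000,
                                      tir_length=6_000)


class TestCollapse:
    def test_arithmetic(self):
        cfg = simulate.PopulationConfig(n_strains=1, chromosome_length=100_000,
                                        tir_length=10_000, seed=3)
        (rep,) = simulate.simulate_population(cfg)
        asm = simulate.collapse_assembly(rep)
        assert len(asm.sequence) == 90_000
        assert asm.truth.collapsed_end == "right"

    def test_no_tir_is_identity(self):
        cfg = simulate.PopulationConfig(n_strains=1, chromosome_length=10_000,
                                        tir_length=0, seed=3)
        (rep,) = simulate.simulate_population(cfg)
        asm = simulate.collapse_assembly(rep)
        assert asm.sequence == rep.sequence

    def test_missing_truth_fails(self):
        rep = simulate.Replicon(id="x", sequence="ACGT" * 100)
        with pytest.raises(ValueError):
            simulate.collapse_assembly(rep)


class TestSimulateReads:
    def test_read_count_near_expectation(self, small_replicon):
        rs = simulate.simulate_reads(small_replicon, coverage=50,
                                     read_length=300, error_rate=0, seed=1)
        expected = 50 * len(small_replicon.sequence) / 300
        assert abs(len(rs) - expected) < 5 * np.sqrt(expected)

    def test_error_free_reads_are_substrings(self, small_replicon):
        rs = simulate.simulate_reads(small_replicon, coverage=2,
                                     read_length=200, error_rate=0, seed=2)
        s = small_replicon.sequence
        for _, rseq in rs.reads[:50]:
            assert rseq in s or revcomp(rseq) in s

    def test_deterministic_fastq(self, small_replicon, tmp_path):
        out1, out2 = tmp_path / "a.fq", tmp_path / "b.fq"
        for out in (out1, out2):
            rs = simulate.simulate_reads(small_replicon, coverage=2,
                                         read_length=150, error_rate=1e-2,
                                         seed=5)
            simulate.write_fastq(rs, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_read_length_exceeding_replicon_fails(self, small_replicon):
        with pytest.raises(ValueError):
            simulate.simulate_reads(small_replicon, coverage=1,
                                    read_length=10**6, seed=0)

    def test_fastq_roundtrip(self, small_replicon, tmp_path):
        rs = simulate.simulate_reads(small_replicon, coverage=1,
                                     read_length=150, error_rate=0, seed=6)
        p = tmp_path / "r.fq"
        simulate.write_fastq(rs, p)
        back = simulate.read_fastq(p)
        assert back.reads == rs.reads

    def test_terminal_coverage_not_depleted(self, small_replicon):
        # reads clip at molecule ends, so the physical terminus stays covered
        rs = simulate.simulate_reads(small_replicon, coverage=50,
                                     read_length=300, error_rate=0, seed=7)
        # count reads covering the last base via exact suffix match
        n_last = 0
        s = small_replicon.sequence
        for _, rseq in rs.reads:
            if s.endswith(rseq) or s.endswith(revcomp(rseq)):
                n_last += 1
        assert n_last >= 10


def test_fasta_roundtrip(tmp_path, small_replicon):
    p = tmp_path / "x.fa"
    simulate.write_fasta([small_replicon], p)
    (back,) = simulate.read_fasta(p)
    assert back.sequence == small_replicon.sequence
    assert back.id == small_replicon.id


def test_truth_json_and_bed(tmp_path, small_replicon):
    simulate.write_truth([small_replicon], tmp_path / "t.json",
                         tmp_path / "t.bed")
    import json

    obj = json.loads((tmp_path / "t.json").read_text())
    assert obj[small_replicon.id]["tir_interval_left"] == [0, 2000]
    bed = (tmp_path / "t.bed").read_text().splitlines()
    assert len(bed) == 2 and bed[0].split("\t")[1] == "0"
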