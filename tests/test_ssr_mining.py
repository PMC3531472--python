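import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cicermark.core_io import RunConfig, Transcript
from cicermark.ssr_mining import (
    Ineligible,
    canonical_motif,
    class_label,
    design_primer_pair,
    find_ssrs,
    is_primitive,
    max_mono_run,
    merge_compound,
    primer_gc,
    primer_tm,
    revcomp,
    ssr_stats,
)
from .conftest import random_dna, repeat_rich_dna
from .oracles import oracle_find_ssrs

motifs = st.text(alphabet="ACGT", min_size=2, max_size=6).filter(is_primitive)


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("CT", "AG"), ("TTC", "AAG"), ("AT", "AT"), ("GA", "AG"), ("CTT", "AAG")],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    @given(motifs)
    @settings(max_examples=300, derandomize=True)
    def test_idempotent_and_invariant(self, motif):
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon
        assert canonical_motif(revcomp(motif)) == canon
        for i in range(len(motif)):
            assert canonical_motif(motif[i:] + motif[:i]) == canon

    def test_class_label_pairs_canon_with_revcomp(self):
        assert class_label("CT") == "AG/CT"
        assert class_label("TTC") == "AAG/CTT"

    def test_non_primitive_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")


class TestFindSSRs:
    def find(self, seq):
        return find_ssrs(Transcript("t", seq))

    def test_no_qualifying_repeat(self):
        assert self.find("GATTACACCGTTAGCAT") == []

    def test_dinucleotide_at_threshold(self):
        (l,) = self.find("TTTTT" + "AG" * 6 + "CCCCC")
        assert (l.start, l.end, l.motif, l.canonical_class, l.unit_count) == (
            6, 17, "AG", "AG/CT", 6,
        )

    def test_trinucleotide_below_length_minimum(self):
        assert self.find("AAG" * 4) == []  # 12 nt < 15 nt minimum

    def test_partial_trailing_unit_not_counted(self):
        (l,) = self.find("C" + "AG" * 6 + "A" + "T")
        assert (l.unit_count, l.tract_length) == (6, 12)

    def test_n_breaks_tract(self):
        assert self.find("AG" * 5 + "N" + "AG" * 5) == []

    def test_mononucleotide_runs_excluded(self):
        assert self.find("A" * 40) == []

    def test_oracle_equivalence_random(self, rng):
        for _ in range(300):
            seq = repeat_rich_dna(rng, int(rng.integers(30, 250)))
            ours = [
                (l.start, l.end, l.motif, l.unit_count)
                for l in self.find(seq)
            ]
            assert sorted(ours) == oracle_find_ssrs(seq), seq

    def test_loci_maximal_and_nonoverlapping(self, rng):
        for _ in range(100):
            seq = repeat_rich_dna(rng, 300)
            loci = self.find(seq)
            for a, b in zip(loci, loci[1:]):
                assert a.end < b.start
            for l in loci:
                k = l.k
                left = seq[l.start - 1 - k : l.start - 1]
                right = seq[l.end : l.end + k]
                assert left != l.motif or l.start - 1 - k < 0
                assert right != l.motif

    def test_revcomp_mirrors_isolated_tracts(self, rng):
        # exact mirror symmetry holds for isolated tracts (partial-unit
        # boundaries between adjacent repeat regions are orientation-
        # dependent under any complete-unit convention)
        spacer = "GATTACA" * 10
        for motif, units in [("AG", 7), ("AAG", 6), ("ACGT", 5), ("AACGG", 4)]:
            seq = spacer + motif * units + spacer
            (fwd,) = self.find(seq)
            (rev,) = self.find(revcomp(seq))
            assert fwd.canonical_class == rev.canonical_class
            assert fwd.unit_count == rev.unit_count == units
            n = len(seq)
            assert (rev.start, rev.end) == (n - fwd.end + 1, n - fwd.start + 1)


class TestMergeCompound:
    def loci(self, seq):
        return find_ssrs(Transcript("t", seq))

    def test_adjacent_tracts_form_group(self):
        loci = self.loci("GATTACA" * 3 + "AG" * 6 + "CTT" * 5 + "GATTACA" * 3)
        merged = merge_compound(loci, max_gap=100)
        assert len(merged) == 2
        assert merged[0].compound_group == merged[1].compound_group == 1

    def test_single_locus_has_no_group(self):
        merged = merge_compound(self.loci("TTGTT" + "AG" * 6 + "GTTGT"))
        assert merged[0].compound_group is None

    def test_gap_boundary(self):
        spacer = ("GATTACA" * 15)[:100] + "G"  # 101 nt between tracts
        loci = self.loci("AG" * 6 + spacer + "CTT" * 5)
        assert loci[1].start - loci[0].end - 1 == 101
        merged = merge_compound(loci, max_gap=100)
        assert all(l.compound_group is None for l in merged)
        merged = merge_compound(loci, max_gap=101)
        assert all(l.compound_group == 1 for l in merged)

    def test_overlapping_input_raises(self):
        from cicermark.ssr_mining import SSRLocus

        a = SSRLocus("t", 1, 12, "AG", "AG/CT", 6)
        b = SSRLocus("t", 10, 24, "AAG", "AAG/CTT", 5)
        with pytest.raises(ValueError):
            merge_compound([a, b])


class TestSSRStats:
    def test_density_both_ways(self):
        loci = find_ssrs(Transcript("t", "TT" + "AG" * 6 + "TT"))
        s = ssr_stats(loci, transcriptome_kb=10.0)
        assert s.kb_per_ssr == 10.0 and s.ssr_per_kb == 0.1

    def test_per_unit_size_means(self):
        loci = find_ssrs(Transcript("t", "AG" * 6 + "GATTACA" * 6 + "CT" * 9))
        s = ssr_stats(loci, 1.0)
        assert s.mean_tract_length[2] == 15.0  # (12 + 18) / 2
        assert s.mean_unit_count[2] == 7.5

    def test_zero_loci(self):
        s = ssr_stats([], 5.0)
        assert s.kb_per_ssr is None and s.n_loci == 0

    def test_long_tract_and_transcript_counts(self):
        t1 = find_ssrs(Transcript("t1", "AG" * 10 + "GATTACA" * 18 + "AAG" * 5))
        t2 = find_ssrs(Transcript("t2", "CT" * 6))
        s = ssr_stats(t1 + t2, 1.0)
        assert s.n_long == 1  # only the 20 nt AG tract
        assert s.transcripts_with_ssr == 2 and s.transcripts_with_2plus == 1


class TestPrimerDesign:
    def balanced_flank(self, rng, n):
        # alternating-ish composition that satisfies GC/run constraints
        return "".join(
            ("ACTG" if i % 2 else "TGCA")[int(rng.integers(0, 4))] for i in range(n)
        )

    def test_short_flank_ineligible(self, rng):
        seq = ("GATTACA" * 7)[:48] + "AG" * 6 + self.balanced_flank(rng, 150)
        t = Transcript("t", seq)
        locus = next(l for l in find_ssrs(t) if l.canonical_class == "AG/CT")
        assert locus.start == 49
        result = design_primer_pair(t, locus)
        assert isinstance(result, Ineligible) and "flank" in result.reason

    def test_valid_pair_excludes_tract(self, rng):
        flank = self.balanced_flank(rng, 400)
        seq = flank + "AG" * 8 + self.balanced_flank(rng, 400)
        t = Transcript("t", seq)
        loci = [l for l in find_ssrs(t) if l.motif in ("AG", "GA", "CT", "TC")]
        locus = next(l for l in loci if l.unit_count == 8)
        pair = design_primer_pair(t, locus)
        assert not isinstance(pair, Ineligible)
        assert pair.f_start + len(pair.forward_seq) - 1 < locus.start
        assert pair.r_end - len(pair.reverse_seq) + 1 > locus.end
        assert pair.product_size >= locus.tract_length + 36
        for p in (pair.forward_seq, pair.reverse_seq):
            assert 18 <= len(p) <= 24
            assert 40 <= primer_gc(p) <= 60
            assert 55 <= primer_tm(p) <= 62
            assert max_mono_run(p) <= 4

    def test_unsatisfiable_flanks_report_reason(self):
        seq = "A" * 150 + "AG" * 8 + "A" * 150
        t = Transcript("t", seq)
        locus = next(l for l in find_ssrs(t) if l.canonical_class == "AG/CT")
        result = design_primer_pair(t, locus)
        assert isinstance(result, Ineligible)

    def test_locus_outside_transcript_raises(self):
        from cicermark.ssr_mining import SSRLocus

        t = Transcript("t", "ACGT" * 10)
        bad = SSRLocus("t", 30, 60, "AG", "AG/CT", 6)
        with pytest.raises(ValueError):
            design_primer_pair(t, bad)

    def test_tm_formula(self):
        # 20-mer with 10 GC: 64.9 + 41*(10-16.4)/20
        assert primer_tm("ACGT" * 5) == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)
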