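import math
import random
import warnings

import pytest

from cicermark.core_io import HitRecord, RunConfig
from cicermark.divergence import (
    STOP_CODONS,
    CodonAlignmentError,
    codon_align,
    divergence_time,
    jukes_cantor,
    ks_peak,
    ng86_kaks,
    reciprocal_best_hits,
    selection_summary,
)
from .oracles import oracle_ng86

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def hit(q, s, evalue=1e-50, bitscore=500.0, length=400):
    return HitRecord(q, s, 98.0, length, 2, 0, 1, length, 1, length, evalue, bitscore)


class TestRBH:
    def test_mutual_best_included_with_min_length(self):
        ab = [hit("a", "b", 1e-50, length=400)]
        ba = [hit("b", "a", 1e-48, length=390)]
        (pair,) = reciprocal_best_hits(ab, ba)
        assert (pair.id_a, pair.id_b, pair.aln_length) == ("a", "b", 390)

    def test_non_reciprocal_excluded(self):
        ab = [hit("a", "b")]
        ba = [hit("b", "a2", 1e-60), hit("b", "a", 1e-50)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_short_alignment_excluded(self):
        ab = [hit("a", "b", length=250)]
        ba = [hit("b", "a", length=400)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_weak_evalue_excluded(self):
        ab = [hit("a", "b", evalue=1e-10)]
        ba = [hit("b", "a", evalue=1e-50)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_best_hit_tie_breaking(self):
        ab = [hit("a", "b", 1e-50, bitscore=400), hit("a", "c", 1e-50, bitscore=500)]
        ba = [hit("c", "a", 1e-50)]
        (pair,) = reciprocal_best_hits(ab, ba)
        assert pair.id_b == "c"

    def test_symmetry_under_table_swap(self, rng):
        ab, ba = [], []
        for i in range(30):
            e = 10.0 ** -float(rng.integers(25, 80))
            ab.append(hit(f"a{i}", f"b{i % 20}", e))
            ba.append(hit(f"b{i % 20}", f"a{i}", e * 10))
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert sorted((p.id_a, p.id_b) for p in fwd) == sorted(
            (p.id_b, p.id_a) for p in rev
        )


class TestCodonAlign:
    def coding(self, n=150, seed=0):
        rnd = random.Random(seed)
        return "ATG" + "".join(rnd.choice(SENSE_CODONS) for _ in range(n))

    def test_identical_sequences_align_fully(self):
        seq = self.coding(120)
        pairs = codon_align(seq, seq)
        assert len(pairs) == len(seq) // 3
        assert all(a == b for a, b in pairs)

    def test_three_nt_insertion_drops_one_codon(self):
        seq = self.coding(120)
        insertion = seq[:150] + "GCA" + seq[150:]
        pairs = codon_align(seq, insertion)
        assert len(pairs) == len(seq) // 3

    def test_no_stop_codons_in_output(self):
        seq = self.coding(120, seed=1)
        mutated = seq[:90] + "TAA" + seq[93:]  # internal stop in frame 1
        pairs = codon_align(seq, mutated)
        assert all(a not in STOP_CODONS and b not in STOP_CODONS for a, b in pairs)

    def test_too_short_alignment_raises(self):
        seq = self.coding(30)
        with pytest.raises(CodonAlignmentError):
            codon_align(seq, seq, min_codons=100)

    def test_reverse_complement_of_b_recovered(self):
        from cicermark.ssr_mining import revcomp

        seq = self.coding(120, seed=2)
        pairs = codon_align(seq, revcomp(seq))
        assert len(pairs) == len(seq) // 3
        assert all(a == b for a, b in pairs)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_kaks([("GAT", "GAT")] * 10)
        assert r.Ks == 0 and r.Ka == 0 and r.omega is None
        assert r.selection_class == "undefined"

    def test_single_synonymous_difference(self):
        # GAT third position has exactly 1 synonymous fate of 3
        r = ng86_kaks([("GAT", "GAT")] * 9 + [("GAT", "GAC")])
        assert r.S == pytest.approx(10 / 3)
        assert r.Sd == 1 and r.Nd == 0
        assert r.ps == pytest.approx(0.3)
        assert r.Ks == pytest.approx(-0.75 * math.log(0.6))
        assert r.Ka == 0

    def test_single_nonsynonymous_difference(self):
        # sites averaged over both sequences: s(GCT)=1, s(GAT)=1/3
        r = ng86_kaks([("GAT", "GAT")] * 9 + [("GAT", "GCT")])
        assert r.S == pytest.approx(9 * (1 / 3) + (1 / 3 + 1) / 2)
        assert r.N == pytest.approx(30 - r.S)
        assert r.Nd == 1 and r.Sd == 0
        assert r.Ks == 0 and r.Ka == pytest.approx(jukes_cantor(1 / r.N))

    def test_sites_sum_to_three_per_codon(self, rng):
        for _ in range(50):
            pairs = [
                (SENSE_CODONS[int(rng.integers(0, 61))], SENSE_CODONS[int(rng.integers(0, 61))])
                for _ in range(30)
            ]
            r = ng86_kaks(pairs)
            assert r.S + r.N == pytest.approx(90)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(100):
            pairs = []
            for _ in range(30):
                ca = SENSE_CODONS[int(rng.integers(0, 61))]
                cb = ca if rng.random() < 0.6 else SENSE_CODONS[int(rng.integers(0, 61))]
                pairs.append((ca, cb))
            r = ng86_kaks(pairs)
            S, N, Sd, Nd, Ks, Ka = oracle_ng86(pairs)
            assert r.S == pytest.approx(S, abs=1e-9)
            assert r.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            if Ks is None:
                assert r.Ks is None
            else:
                assert r.Ks == pytest.approx(Ks, abs=1e-9)
            if Ka is None:
                assert r.Ka is None
            else:
                assert r.Ka == pytest.approx(Ka, abs=1e-9)

    def test_agrees_with_biopython_on_single_hit_codons(self, rng):
        # restricted to codon pairs differing at <=1 position, where the
        # stop-pathway conventions of both implementations coincide
        from Bio.Align import Alignment, analysis
        from Bio.Seq import Seq

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(20):
                pairs = []
                for _ in range(60):
                    ca = SENSE_CODONS[int(rng.integers(0, 61))]
                    cb = ca
                    if rng.random() < 0.3:
                        pos = int(rng.integers(0, 3))
                        for b in "ACGT":
                            alt = ca[:pos] + b + ca[pos + 1 :]
                            if alt != ca and alt not in STOP_CODONS:
                                cb = alt
                                break
                    pairs.append((ca, cb))
                r = ng86_kaks(pairs)
                aln = Alignment([
                    Seq("".join(p[0] for p in pairs)),
                    Seq("".join(p[1] for p in pairs)),
                ])
                dn, ds = analysis.calculate_dn_ds(aln, method="NG86")
                assert r.Ka == pytest.approx(dn, abs=1e-9)
                assert r.Ks == pytest.approx(ds, abs=1e-9)

    def test_saturation_returns_undefined(self):
        r = ng86_kaks([("GAT", "GAC")] * 10)  # every codon differs synonymously
        assert r.ps >= 0.75 and r.Ks is None

    def test_ks_monotone_in_planted_synonymous_changes(self):
        base = [("GAT", "GAT")] * 60
        prev = -1.0
        for k in range(0, 13, 3):  # stay below ps = 0.75 saturation
            pairs = [("GAT", "GAC")] * k + base[k:]
            ks = ng86_kaks(pairs).Ks
            assert ks > prev
            prev = ks


class TestKsPeakAndTime:
    def test_peak_at_mode_bin(self, rng):
        values = list(rng.normal(0.008, 0.0008, 500))
        assert ks_peak(values) == pytest.approx(0.008)

    def test_all_zero_is_non_detectable(self):
        assert ks_peak([0.0, 0.0, None]) is None

    def test_tie_takes_smaller_ks(self):
        values = [0.004, 0.004, 0.010, 0.010]
        assert ks_peak(values) == pytest.approx(0.004)

    def test_zero_mass_excluded(self):
        values = [0.0] * 100 + [0.008] * 3
        assert ks_peak(values) == pytest.approx(0.008)

    def test_time_conventions(self):
        cfg = RunConfig()
        assert divergence_time(0.008, cfg) == pytest.approx(533_333.333)
        assert divergence_time(0.0, cfg) == 0
        assert divergence_time(0.006, cfg) == pytest.approx(400_000)
        cfg2 = RunConfig(time_convention="ks_over_2r")
        assert divergence_time(0.008, cfg2) == pytest.approx(266_666.667)


class TestSelectionSummary:
    def result(self, ks, ka):
        r = ng86_kaks([("GAT", "GAT")])
        r.Ks, r.Ka = ks, ka
        return r

    def test_mean_and_counts(self):
        results = [self.result(1.0, w) for w in (0.2, 0.5, 1.5)]
        s = selection_summary(results)
        assert s.mean_omega == pytest.approx(0.7333, abs=1e-4)
        assert (s.n_purifying, s.n_diversifying) == (2, 1)

    def test_ks_window_exclusions(self):
        results = [self.result(0.0, 0.0), self.result(2.4, 1.2), self.result(1.0, 0.5)]
        s = selection_summary(results)
        assert s.n_in_window == 1 and s.n_excluded == 2
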