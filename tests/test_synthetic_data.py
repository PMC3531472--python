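import numpy as np
import pytest

from cicermark.core_io import Transcript
from cicermark.divergence import STOP_CODONS
from cicermark.snp_discovery import call_candidates, filter_snps, site_posterior
from cicermark.ssr_mining import find_ssrs
from cicermark.synthetic_data import (
    SimParams,
    SSRSpec,
    evolve_pair,
    generate_ancestor,
    generate_dataset,
    plant_snps,
    plant_ssr,
    simulate_pileups,
)


class TestAncestor:
    def test_deterministic_under_seed(self):
        p = SimParams(n_transcripts=10, seed=7)
        a = generate_ancestor(p)
        b = generate_ancestor(p)
        assert [(t.id, t.seq) for t in a] == [(t.id, t.seq) for t in b]

    def test_gc_concentrates_on_target(self):
        p = SimParams(n_transcripts=3, length_min=3000, length_max=3000, gc_target=50.0, seed=1)
        for t in generate_ancestor(p):
            gc = 100 * (t.seq.count("G") + t.seq.count("C")) / t.length
            assert abs(gc - 50.0) < 3.0

    def test_fixed_length(self):
        p = SimParams(n_transcripts=5, length_min=300, length_max=300, seed=2)
        assert {t.length for t in generate_ancestor(p)} == {300}

    def test_codon_structure(self):
        p = SimParams(n_transcripts=5, seed=3)
        for t in generate_ancestor(p):
            assert t.seq.startswith("ATG")
            codons = [t.seq[i : i + 3] for i in range(0, t.length, 3)]
            assert not any(c in STOP_CODONS for c in codons)


class TestEvolvePair:
    def test_zero_divergence_identity(self):
        p = SimParams(n_transcripts=1, synonymous_divergence=0.0, seed=4)
        anc = generate_ancestor(p)[0]
        rng = np.random.default_rng(4)
        sa, sb, pair, snps = evolve_pair(anc, p, rng)
        assert sa == sb == anc.seq and snps == [] and pair.n_syn == 0

    def test_truth_records_match_sequences(self):
        p = SimParams(n_transcripts=1, length_min=3000, length_max=3000,
                      synonymous_divergence=0.02, seed=5)
        anc = generate_ancestor(p)[0]
        sa, sb, pair, snps = evolve_pair(anc, p, np.random.default_rng(5))
        diffs = {i + 1 for i in range(len(sa)) if sa[i] != sb[i]}
        assert {s.pos for s in snps} == diffs
        for s in snps:
            assert sa[s.pos - 1] == s.base_a and sb[s.pos - 1] == s.base_b

    def test_realized_divergence_near_target(self):
        p = SimParams(n_transcripts=1, length_min=6000, length_max=6000,
                      synonymous_divergence=0.02, seed=6)
        anc = generate_ancestor(p)[0]
        _, _, pair, _ = evolve_pair(anc, p, np.random.default_rng(6))
        assert pair.realized_ks == pytest.approx(0.02, abs=0.004)

    def test_kappa_transition_fraction(self):
        # with kappa=2 a transition is twice as likely as each of the two
        # transversion types: expected Ts fraction 0.5. The unconstrained
        # planter realizes it exactly (3-sigma binomial band); the
        # quota-accepted evolver only approximately (acceptance conditions
        # on the synonymous/nonsynonymous split, which covaries with Ts).
        p = SimParams(n_transcripts=12, length_min=3000, length_max=3000,
                      kappa=2.0, seed=7)
        rng = np.random.default_rng(7)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = n = 0
        for anc in generate_ancestor(p, rng):
            _, _, snps = plant_snps(anc.seq, anc.seq, anc.id, 900, p, rng)
            for s in snps:
                n += 1
                ts += (s.base_a, s.base_b) in transitions
        assert n > 10_000
        assert abs(ts / n - 0.5) < 3 * (0.25 / n) ** 0.5

    def test_evolver_transition_fraction_near_kappa_expectation(self):
        p = SimParams(n_transcripts=20, length_min=3000, length_max=3000,
                      synonymous_divergence=0.1, omega=0.6, kappa=2.0, seed=7)
        rng = np.random.default_rng(7)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = n = 0
        for anc in generate_ancestor(p, rng):
            _, _, _, snps = evolve_pair(anc, p, rng)
            for s in snps:
                n += 1
                ts += (s.base_a, s.base_b) in transitions
        assert abs(ts / n - 0.5) < 0.05


class TestPlanting:
    def test_planted_ssr_recovered_exactly(self):
        p = SimParams(n_transcripts=1, length_min=1200, length_max=1200, seed=8)
        anc = generate_ancestor(p)[0]
        rng = np.random.default_rng(8)
        sa, sb, truth = plant_ssr(anc.seq, anc.seq, anc.id, SSRSpec("AG", 8, 6), rng)
        loci_a = [l for l in find_ssrs(Transcript("a", sa)) if l.canonical_class == "AG/CT"]
        loci_b = [l for l in find_ssrs(Transcript("b", sb)) if l.canonical_class == "AG/CT"]
        assert [(l.start, l.unit_count) for l in loci_a] == [(truth.start_a, 8)]
        assert [(l.start, l.unit_count) for l in loci_b] == [(truth.start_b, 6)]

    def test_below_threshold_tract_absent(self):
        # AAG x4 = 12 nt < 15 nt minimum: genotype B locus must not be mined
        p = SimParams(n_transcripts=1, length_min=1200, length_max=1200, seed=9)
        anc = generate_ancestor(p)[0]
        sa, sb, truth = plant_ssr(
            anc.seq, anc.seq, anc.id, SSRSpec("AAG", 5, 4), np.random.default_rng(9)
        )
        assert any(l.canonical_class == "AAG/CTT" for l in find_ssrs(Transcript("a", sa)))
        assert not any(l.canonical_class == "AAG/CTT" for l in find_ssrs(Transcript("b", sb)))

    def test_insufficient_room_raises(self):
        with pytest.raises(ValueError):
            plant_ssr("ACGT" * 20, "ACGT" * 20, "t", SSRSpec("AG", 8, 6, flank=100),
                      np.random.default_rng(0))

    def test_plant_snps_differ_and_truth_consistent(self):
        p = SimParams(n_transcripts=1, seed=10)
        anc = generate_ancestor(p)[0]
        sa, sb, snps = plant_snps(anc.seq, anc.seq, anc.id, 25, p, np.random.default_rng(10))
        assert len(snps) == 25
        for s in snps:
            assert sa[s.pos - 1] == s.base_a != s.base_b == sb[s.pos - 1]


class TestPileups:
    def test_error_free_pileup_copies_sequences(self):
        p = SimParams(n_transcripts=1, length_min=300, length_max=300,
                      error_rate=0.0, depth_mean=5.0, seed=11)
        anc = generate_ancestor(p)[0]
        cols = simulate_pileups(anc.seq, anc.seq, anc.id, p, np.random.default_rng(11))
        for c in cols:
            base = anc.seq[c.pos - 1]
            assert set(c.bases_a) <= {base} and set(c.bases_b) <= {base}

    def test_planted_fixed_difference_called(self):
        p = SimParams(n_transcripts=1, length_min=300, length_max=300,
                      depth_mean=10.0, seed=12)
        anc = generate_ancestor(p)[0]
        sa, sb, snps = plant_snps(anc.seq, anc.seq, anc.id, 1, p, np.random.default_rng(12))
        cols = simulate_pileups(sa, sb, anc.id, p, np.random.default_rng(13))
        target = next(c for c in cols if c.pos == snps[0].pos)
        a, b, post = site_posterior(target)
        assert (a, b) == (snps[0].base_a, snps[0].base_b)
        assert post > 0.99

    def test_het_site_rejected_as_not_fixed(self):
        p = SimParams(n_transcripts=3, length_min=300, length_max=600,
                      synonymous_divergence=0.0, n_het_sites=6, depth_mean=10.0, seed=13)
        ds = generate_dataset(p)
        cands = call_candidates(ds.pileup)
        accepted, rejected, _ = filter_snps(cands, ds.pileup)
        het = {(s.transcript_id, s.pos) for s in ds.truth.snps if s.kind == "het"}
        assert not {(c.transcript_id, c.pos) for c in accepted} & het


class TestDataset:
    def test_full_determinism(self):
        p = SimParams(n_transcripts=6, seed=14, n_fixed_snps=10, n_het_sites=2,
                      ssr_specs=[SSRSpec("AG", 8, 6)])
        d1 = generate_dataset(p)
        d2 = generate_dataset(p)
        assert [t.seq for t in d1.genotype_a] == [t.seq for t in d2.genotype_a]
        assert [t.seq for t in d1.genotype_b] == [t.seq for t in d2.genotype_b]
        assert [
            (c.transcript_id, c.pos, c.bases_a, c.quals_a, c.bases_b, c.quals_b)
            for c in d1.pileup
        ] == [
            (c.transcript_id, c.pos, c.bases_a, c.quals_a, c.bases_b, c.quals_b)
            for c in d2.pileup
        ]

    def test_truth_consistency(self):
        p = SimParams(n_transcripts=8, seed=15, n_fixed_snps=40,
                      ssr_specs=[SSRSpec("AG", 8, 6)])
        ds = generate_dataset(p, with_pileups=False)
        ia = {t.id: t for t in ds.genotype_a}
        ib = {t.id: t for t in ds.genotype_b}
        for s in ds.truth.snps:
            if s.kind != "fixed":
                continue
            assert ia[s.transcript_id].seq[s.pos - 1] == s.base_a
            assert ib[s.transcript_id].seq[s.pos - 1] == s.base_b
            assert s.base_a != s.base_b
        for t in ds.truth.ssrs:
            k = len(t.motif)
            assert ia[t.transcript_id].seq[t.start_a - 1 : t.start_a - 1 + k * t.units_a] == t.motif * t.units_a
            assert ib[t.transcript_id].seq[t.start_b - 1 : t.start_b - 1 + k * t.units_b] == t.motif * t.units_b
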