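"""Planted-truth recovery experiments.

Each experiment generates a seeded two-genotype fixture with known
ground truth, runs the corresponding pipeline stage end to end, and
scores recovery. They are the package's calibration/validation suite:
SNP recall under the full filter chain at realistic depth and quality,
polymorphic-SSR recall through ortholog anchoring and flank matching,
and recovery of the synonymous-divergence peak through codon alignment
and NG86 counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import divergence, snp_discovery, ssr_mining, ssr_polymorphism
from .core_io import RunConfig, transcript_index
from .synthetic_data import SimParams, SSRSpec, generate_dataset

log = logging.getLogger("cicermark")

_SSR_MOTIFS = ["AG", "AC", "AT", "AAG", "AAT", "ACG", "AGG", "AAAG", "AACG"]


@dataclass(frozen=True)
class SNPRecovery:
    n_planted: int
    n_recovered: int
    n_accepted: int
    n_false: int
    n_het_accepted: int
    transition_fraction: float

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted


def snp_recovery_experiment(
    seed: int,
    n_snps: int = 1000,
    n_transcripts: int = 200,
    depth: float = 10.0,
    qual: float = 37.0,
    error_rate: float = 1e-3,
    config: RunConfig | None = None,
) -> SNPRecovery:
    """Plant fixed differences and heterozygous sites, simulate pileups,
    and run the caller plus filter chain against the truth."""
    config = config or RunConfig()
    params = SimParams(
        n_transcripts=n_transcripts,
        length_min=600,
        length_max=900,
        synonymous_divergence=0.0,
        n_fixed_snps=n_snps,
        n_het_sites=max(1, n_snps // 10),
        n_indel_columns=max(1, n_snps // 20),
        depth_mean=depth,
        qual_mean=qual,
        error_rate=error_rate,
        seed=seed,
    )
    dataset = generate_dataset(params)
    candidates = snp_discovery.call_candidates(dataset.pileup)
    accepted, _, _ = snp_discovery.filter_snps(candidates, dataset.pileup, config)
    accepted_set = {(c.transcript_id, c.pos) for c in accepted}
    fixed = {
        (s.transcript_id, s.pos)
        for s in dataset.truth.snps
        if s.kind == "fixed"
    }
    het = {
        (s.transcript_id, s.pos) for s in dataset.truth.snps if s.kind == "het"
    }
    subs = snp_discovery.classify_substitutions(accepted)
    return SNPRecovery(
        n_planted=len(fixed),
        n_recovered=len(accepted_set & fixed),
        n_accepted=len(accepted),
        n_false=len(accepted_set - fixed),
        n_het_accepted=len(accepted_set & het),
        transition_fraction=subs.transition_fraction,
    )


@dataclass(frozen=True)
class SSRRecovery:
    n_planted_polymorphic: int  # eligible planted loci with unit_diff >= 1
    n_recovered: int  # reported with the correct class and unit_diff
    n_false_pairs: int  # reported polymorphic pairs not in the truth

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted_polymorphic


def ssr_recovery_experiment(
    seed: int,
    n_loci: int = 200,
    config: RunConfig | None = None,
) -> SSRRecovery:
    """Plant SSR loci with per-genotype unit counts, mine both genotypes,
    anchor on blastn reciprocal best hits, and score polymorphic-SSR
    detection against the truth.

    Planted unit counts cycle through differences 0-4; eligibility
    requires both planted tracts to meet the mining length minima.
    """
    config = config or RunConfig()
    specs = []
    for i in range(n_loci):
        motif = _SSR_MOTIFS[i % len(_SSR_MOTIFS)]
        base = 6 + (i % 4)
        diff = i % 5
        specs.append(SSRSpec(motif=motif, units_a=base + diff, units_b=base))
    params = SimParams(
        n_transcripts=n_loci + 10,
        length_min=800,
        length_max=1500,
        ssr_specs=specs,
        seed=seed,
    )
    dataset = generate_dataset(params, with_pileups=False)
    index_a = transcript_index(dataset.genotype_a)
    index_b = transcript_index(dataset.genotype_b)
    loci_a = ssr_mining.find_all_ssrs(dataset.genotype_a, config)
    loci_b = ssr_mining.find_all_ssrs(dataset.genotype_b, config)
    hits_ab = divergence.compute_hits(dataset.genotype_a, dataset.genotype_b)
    hits_ba = divergence.compute_hits(dataset.genotype_b, dataset.genotype_a)
    pairs = divergence.reciprocal_best_hits(hits_ab, hits_ba, config)
    matched = ssr_polymorphism.match_ssr_loci(
        loci_a, loci_b, pairs, index_a, index_b, config
    )
    poly, _ = ssr_polymorphism.classify_polymorphic(matched)

    def eligible(truth) -> bool:
        k = len(truth.motif)
        need = config.min_unit_count(k)
        return truth.units_a >= need and truth.units_b >= need

    planted = {
        (t.transcript_id, t.canonical_class, t.unit_diff)
        for t in dataset.truth.ssrs
        if eligible(t) and t.unit_diff >= 1
    }
    reported = {
        (p.match.locus_a.transcript_id, p.canonical_class, p.unit_diff)
        for p in poly
    }
    return SSRRecovery(
        n_planted_polymorphic=len(planted),
        n_recovered=len(planted & reported),
        n_false_pairs=len(reported - planted),
    )


@dataclass(frozen=True)
class KsPeakRecovery:
    n_pairs: int
    n_estimated: int
    peak: float | None
    divergence_years: float | None
    mean_omega: float | None
    n_purifying: int
    n_diversifying: int


def ks_peak_experiment(
    seed: int,
    n_pairs: int = 2000,
    divergence_target: float = 0.008,
    config: RunConfig | None = None,
) -> KsPeakRecovery:
    """Evolve ortholog pairs at a target synonymous divergence and recover
    the Ks-distribution peak through codon alignment and NG86.

    Transcripts are 2.1-3.0 kb so the per-pair Ks granularity (one
    synonymous substitution over ~500-700 synonymous sites) resolves the
    histogram bin width.
    """
    config = config or RunConfig()
    params = SimParams(
        n_transcripts=n_pairs,
        length_min=2100,
        length_max=3000,
        synonymous_divergence=divergence_target,
        seed=seed,
    )
    dataset = generate_dataset(params, with_pileups=False)
    results = []
    for a, b in zip(dataset.genotype_a, dataset.genotype_b):
        try:
            codons = divergence.codon_align(a.seq, b.seq, config.min_aligned_codons)
        except divergence.CodonAlignmentError as exc:
            log.info("pair %s skipped: %s", a.id, exc)
            continue
        results.append(divergence.ng86_kaks(codons, a.id, b.id))
    peak = divergence.ks_peak([r.Ks for r in results], config.ks_bin_width)
    years = divergence.divergence_time(peak, config) if peak is not None else None
    sel = divergence.selection_summary(results, config)
    return KsPeakRecovery(
        n_pairs=n_pairs,
        n_estimated=len(results),
        peak=peak,
        divergence_years=years,
        mean_omega=sel.mean_omega,
        n_purifying=sel.n_purifying,
        n_diversifying=sel.n_diversifying,
    )
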