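"""End-to-end orchestration, marker-report assembly, and allele-specific
PCR assay design.

``run_pipeline`` chains the stages (assembly stats -> SSR mining ->
ortholog/divergence -> polymorphic SSRs -> SNP calling -> report) over
two genotype transcriptomes, writing every intermediate as TSV plus a
plain-text summary. ``design_allele_primers`` builds the three-primer
genotyping assay for an accepted SNP: two outer flanking primers and
one allele-specific primer whose 3' end sits on the SNP, so the two
PCR products differ in length enough to separate on an agarose gel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import assembly_metrics, divergence, snp_discovery, ssr_mining, ssr_polymorphism
from .core_io import (
    RunConfig,
    Transcript,
    read_annotation_table,
    read_fasta,
    read_hits,
    read_pileup,
    transcript_index,
    write_fasta,
    write_pileup,
    write_tsv,
)
from .snp_discovery import SNPCall
from .ssr_mining import Ineligible, primer_gc, primer_ok, primer_tm, revcomp
from .synthetic_data import SimParams, generate_dataset

log = logging.getLogger("cicermark")


def percent(x: float, n: float, digits: int = 1) -> float:
    """x out of n as a percentage at report precision (77.3 for 17/22)."""
    if n == 0:
        raise ValueError("percentage of an empty denominator")
    return round(100.0 * x / n, digits)


def per_locus(n_items: int, n_loci: int, digits: int = 1) -> float:
    """Mean items per locus at report precision (2.1 for 29/14)."""
    if n_loci == 0:
        raise ValueError("no loci")
    return round(n_items / n_loci, digits)


def kb_per_marker(n_markers: int, transcriptome_kb: float, digits: int = 2) -> float:
    """kb of transcriptome per marker at report precision (8.54 for
    5409 markers over 46,210 kb)."""
    if n_markers == 0:
        raise ValueError("no markers")
    return round(transcriptome_kb / n_markers, digits)


def markers_per_kb(n_markers: int, transcriptome_kb: float, digits: int = 3) -> float:
    if transcriptome_kb <= 0:
        raise ValueError("transcriptome_kb must be positive")
    return round(n_markers / transcriptome_kb, digits)


# ---------------------------------------------------------------------------
# allele-specific PCR trio


@dataclass(frozen=True)
class AllelePrimerTrio:
    transcript_id: str
    snp_pos: int
    outer_forward: str
    outer_reverse: str
    allele_specific: str
    allele: str  # the allele the AS primer discriminates
    as_orientation: str  # "forward" | "reverse"
    f_start: int
    r_end: int
    outer_product: int
    allele_product: int


def _scan_window_forward(
    seq: str, lo: int, hi: int, config: RunConfig
) -> Optional[tuple[int, str]]:
    """Rightmost acceptable forward primer fully inside 0-based [lo, hi)."""
    for right in range(hi, lo + config.primer_len_min - 1, -1):
        for length in range(config.primer_len_min, config.primer_len_max + 1):
            if right - length < lo:
                continue
            cand = seq[right - length : right]
            if primer_ok(cand, config):
                return right - length, cand
    return None


def _scan_window_reverse(
    seq: str, lo: int, hi: int, config: RunConfig
) -> Optional[tuple[int, str]]:
    """Leftmost acceptable reverse primer fully inside 0-based [lo, hi);
    returns (inclusive 0-based end, primer on the reverse strand)."""
    for left in range(lo, hi - config.primer_len_min + 1):
        for length in range(config.primer_len_min, config.primer_len_max + 1):
            if left + length > hi:
                continue
            cand = revcomp(seq[left : left + length])
            if primer_ok(cand, config):
                return left + length - 1, cand
    return None


def design_allele_primers(
    transcript: Transcript, snp: SNPCall, config: RunConfig | None = None
) -> AllelePrimerTrio | Ineligible:
    """Three-primer allele-specific genotyping assay for an accepted SNP.

    Outer primers are picked by the standard primer rules from windows
    100-150 nt away on each side of the SNP. The allele-specific primer
    ends exactly on the SNP (preferred length 20 nt, any primer length
    allowed; forward orientation first, reverse-strand fallback); its 3'
    base sits on the SNP and carries the targeted allele on its strand.
    The outer-outer and allele-specific products must differ by at least
    ``min_product_diff`` bp to resolve on a gel.
    """
    config = config or RunConfig()
    seq = transcript.seq
    pos = snp.pos
    if pos - 1 < 150 or len(seq) - pos < 150:
        return Ineligible(
            f"flank too short around position {pos} (need 150 nt each side)"
        )
    off_lo, off_hi = config.outer_primer_offset_min, config.outer_primer_offset_max
    fwd = _scan_window_forward(seq, pos - 1 - off_hi, pos - off_lo, config)
    if fwd is None:
        return Ineligible("no acceptable outer forward primer")
    rev = _scan_window_reverse(seq, pos - 1 + off_lo, pos + off_hi, config)
    if rev is None:
        return Ineligible("no acceptable outer reverse primer")
    f_start0, f_seq = fwd
    r_end0, r_seq = rev

    allele = snp.allele_a  # the base this transcript carries
    preferred = config.allele_primer_len
    lengths = [preferred] + [
        n
        for n in range(config.primer_len_min, config.primer_len_max + 1)
        if n != preferred
    ]
    orientation = as_seq = None
    allele_product = 0
    for n in lengths:
        as_fwd = seq[pos - n : pos]
        if len(as_fwd) == n and primer_ok(as_fwd, config):
            orientation, as_seq = "forward", as_fwd
            allele_product = r_end0 - (pos - n) + 1
            break
        as_rev = revcomp(seq[pos - 1 : pos - 1 + n])
        if len(as_rev) == n and primer_ok(as_rev, config):
            orientation, as_seq = "reverse", as_rev
            allele_product = (pos - 1 + n - 1) - f_start0 + 1
            break
    if orientation is None:
        return Ineligible("no acceptable allele-specific primer")
    outer_product = r_end0 - f_start0 + 1
    if abs(outer_product - allele_product) < config.min_product_diff:
        return Ineligible(
            f"product sizes {outer_product} and {allele_product} too close"
        )
    return AllelePrimerTrio(
        transcript_id=transcript.id,
        snp_pos=pos,
        outer_forward=f_seq,
        outer_reverse=r_seq,
        allele_specific=as_seq,
        allele=allele,
        as_orientation=orientation,
        f_start=f_start0 + 1,
        r_end=r_end0 + 1,
        outer_product=outer_product,
        allele_product=allele_product,
    )


# ---------------------------------------------------------------------------
# marker report


@dataclass
class MarkerReport:
    assembly: Optional[assembly_metrics.AssemblyStats] = None
    ssr_a: Optional[ssr_mining.SSRStats] = None
    ssr_b: Optional[ssr_mining.SSRStats] = None
    polymorphism: Optional[ssr_polymorphism.PolymorphismSummary] = None
    snp_total: int = 0
    snp_transcripts: int = 0
    snp_per_kb: Optional[float] = None
    kb_per_snp: Optional[float] = None
    substitutions: Optional[snp_discovery.SubstitutionSummary] = None
    n_orthologs: int = 0
    ks_peak: Optional[float] = None
    divergence_years: Optional[float] = None
    selection: Optional[divergence.SelectionSummary] = None
    annotation_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def lines(self) -> list[str]:
        out = ["# marker report"]
        if self.assembly:
            a = self.assembly
            out += [
                "[assembly]",
                f"contigs\t{a.n_contigs}",
                f"large_contigs\t{a.n_large}",
                f"total_size_bp\t{a.total_size}",
                f"max_len_bp\t{a.max_len}",
                f"mean_len_bp\t{a.mean_len}",
                f"n50_bp\t{a.n50}",
                f"gc_pct\t{round(a.mean_gc, 1)}",
            ]
        for tag, stats in (("ssr_a", self.ssr_a), ("ssr_b", self.ssr_b)):
            if stats is None:
                continue
            out += [
                f"[{tag}]",
                f"n_loci\t{stats.n_loci}",
                f"kb_per_ssr\t{round(stats.kb_per_ssr, 2) if stats.kb_per_ssr else 'NA'}",
                f"n_compound\t{stats.n_compound}",
                f"n_long\t{stats.n_long}",
                f"transcripts_with_ssr\t{stats.transcripts_with_ssr}",
                f"transcripts_with_2plus\t{stats.transcripts_with_2plus}",
            ]
            for k in sorted(stats.unit_size_histogram):
                out.append(
                    f"unit{k}\t{stats.unit_size_histogram[k]}"
                    f"\tmean_len={round(stats.mean_tract_length[k], 2)}"
                    f"\tmean_units={round(stats.mean_unit_count[k], 2)}"
                )
        if self.polymorphism:
            p = self.polymorphism
            out += [
                "[polymorphic_ssrs]",
                f"n_polymorphic\t{p.n_polymorphic}",
                f"n_diff_ge3\t{p.n_diff_ge3}",
                f"n_diff_ge10\t{p.n_diff_ge10}",
            ]
        out += [
            "[snps]",
            f"n_snps\t{self.snp_total}",
            f"n_transcripts\t{self.snp_transcripts}",
            f"snp_per_kb\t{self.snp_per_kb if self.snp_per_kb is not None else 'NA'}",
            f"kb_per_snp\t{self.kb_per_snp if self.kb_per_snp is not None else 'NA'}",
        ]
        if self.substitutions and self.substitutions.n_total:
            s = self.substitutions
            ratio = s.ts_tv_ratio
            out += [
                f"transitions_pct\t{percent(s.n_transitions, s.n_total)}",
                f"transversions_pct\t{percent(s.n_transversions, s.n_total)}",
                f"ts_tv_ratio\t{round(ratio, 2) if ratio is not None else 'NA'}",
            ]
        out += [
            "[divergence]",
            f"n_orthologs\t{self.n_orthologs}",
            f"ks_peak\t{self.ks_peak if self.ks_peak is not None else 'NA'}",
        ]
        if self.divergence_years is not None:
            out.append(f"divergence_my\t{round(self.divergence_years / 1e6, 2)}")
        if self.selection:
            sel = self.selection
            out += [
                f"pairs_in_ks_window\t{sel.n_in_window}",
                f"mean_omega\t{round(sel.mean_omega, 2) if sel.mean_omega is not None else 'NA'}",
                f"n_purifying\t{sel.n_purifying}",
                f"n_diversifying\t{sel.n_diversifying}",
            ]
        for key, table in sorted(self.annotation_counts.items()):
            out.append(f"[annotation:{key}]")
            out += [f"{label}\t{count}" for label, count in sorted(table.items())]
        return out

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.lines()) + "\n")


def summarize(
    *,
    transcripts_a: Sequence[Transcript],
    ssr_loci_a: Sequence[ssr_mining.SSRLocus],
    ssr_loci_b: Sequence[ssr_mining.SSRLocus] = (),
    transcripts_b: Sequence[Transcript] = (),
    poly_summary: Optional[ssr_polymorphism.PolymorphismSummary] = None,
    accepted_snps: Sequence[SNPCall] = (),
    kaks: Sequence[divergence.KaKsResult] = (),
    n_orthologs: int = 0,
    annotation_counts: Optional[Mapping[str, dict[str, int]]] = None,
    config: RunConfig | None = None,
) -> MarkerReport:
    """Assemble the marker report from upstream stage outputs.

    Every number is a pure function of the inputs; densities and
    percentages use the report precisions (2-3 decimals for densities,
    1 for percentages).
    """
    config = config or RunConfig()
    kb = sum(t.length for t in transcripts_a) / 1000.0
    report = MarkerReport()
    report.assembly = assembly_metrics.assembly_summary(transcripts_a, min_len=1)
    report.ssr_a = ssr_mining.ssr_stats(ssr_loci_a, kb)
    if transcripts_b and ssr_loci_b:
        kb_b = sum(t.length for t in transcripts_b) / 1000.0
        report.ssr_b = ssr_mining.ssr_stats(ssr_loci_b, kb_b)
    report.polymorphism = poly_summary
    report.snp_total = len(accepted_snps)
    report.snp_transcripts = len(snp_discovery.per_transcript_counts(accepted_snps))
    spk, kps = snp_discovery.snp_density(len(accepted_snps), kb)
    report.snp_per_kb = round(spk, 3)
    report.kb_per_snp = round(kps, 2) if kps is not None else None
    report.substitutions = snp_discovery.classify_substitutions(accepted_snps)
    report.n_orthologs = n_orthologs
    report.ks_peak = divergence.ks_peak(
        [r.Ks for r in kaks], config.ks_bin_width
    )
    if report.ks_peak is not None:
        report.divergence_years = divergence.divergence_time(report.ks_peak, config)
    report.selection = divergence.selection_summary(kaks, config)
    if annotation_counts:
        report.annotation_counts = dict(annotation_counts)
    return report


# ---------------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    out_dir: str | Path,
    config: RunConfig | None = None,
    *,
    fasta_a: str | Path | None = None,
    fasta_b: str | Path | None = None,
    pileup_path: str | Path | None = None,
    hits_ab: str | Path | None = None,
    hits_ba: str | Path | None = None,
    annotation_path: str | Path | None = None,
    sim_params: SimParams | None = None,
) -> MarkerReport:
    """Run all stages in order and write report files under ``out_dir``.

    Inputs are either two genotype FASTAs (plus optional pileup, hit
    tables and annotations) or a simulation parameter set that generates
    them. Missing inputs for a stage are a pre-flight error; repeated
    runs with the same inputs and seed are byte-identical.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # pre-flight
    if sim_params is None and (fasta_a is None or fasta_b is None):
        raise PipelineError("pre-flight", "need two genotype FASTAs or a simulate block")

    pileup = None
    if sim_params is not None:
        log.info("simulate: seed %d", sim_params.seed)
        dataset = generate_dataset(sim_params)
        transcripts_a = dataset.genotype_a
        transcripts_b = dataset.genotype_b
        pileup = dataset.pileup
        write_fasta(transcripts_a, out / "genotype_a.fasta")
        write_fasta(transcripts_b, out / "genotype_b.fasta")
        write_pileup(pileup, out / "pileup.tsv")
        write_tsv(
            out / "truth_snps.tsv",
            ["transcript_id", "pos", "base_a", "base_b", "kind"],
            ((s.transcript_id, s.pos, s.base_a, s.base_b, s.kind) for s in dataset.truth.snps),
        )
        write_tsv(
            out / "truth_ssrs.tsv",
            ["transcript_id", "motif", "class", "start_a", "start_b", "units_a", "units_b"],
            (
                (t.transcript_id, t.motif, t.canonical_class, t.start_a, t.start_b, t.units_a, t.units_b)
                for t in dataset.truth.ssrs
            ),
        )
    else:
        transcripts_a = read_fasta(fasta_a)
        transcripts_b = read_fasta(fasta_b)
        if pileup_path is not None:
            pileup = read_pileup(pileup_path)

    index_a = transcript_index(transcripts_a)
    index_b = transcript_index(transcripts_b)

    # stage: ssr
    try:
        loci_a = ssr_mining.find_all_ssrs(transcripts_a, config)
        loci_b = ssr_mining.find_all_ssrs(transcripts_b, config)
        write_tsv(
            out / "ssr_a.tsv",
            ["transcript_id", "start", "end", "motif", "class", "unit_count", "tract_length", "compound_group"],
            (
                (l.transcript_id, l.start, l.end, l.motif, l.canonical_class, l.unit_count, l.tract_length, l.compound_group or "")
                for l in loci_a
            ),
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("ssr", str(exc)) from exc

    # stage: diverge
    try:
        if hits_ab is not None and hits_ba is not None:
            hab, hba = read_hits(hits_ab), read_hits(hits_ba)
        else:
            hab = divergence.compute_hits(transcripts_a, transcripts_b)
            hba = divergence.compute_hits(transcripts_b, transcripts_a)
        pairs = divergence.reciprocal_best_hits(hab, hba, config)
        kaks: list[divergence.KaKsResult] = []
        for p in pairs:
            try:
                codons = divergence.codon_align(
                    index_a[p.id_a].seq, index_b[p.id_b].seq, config.min_aligned_codons
                )
            except divergence.CodonAlignmentError as exc:
                log.info("pair %s/%s skipped: %s", p.id_a, p.id_b, exc)
                continue
            kaks.append(divergence.ng86_kaks(codons, p.id_a, p.id_b))
        write_tsv(
            out / "kaks.tsv",
            ["id_a", "id_b", "S", "N", "Sd", "Nd", "Ks", "Ka", "omega", "class"],
            (
                (
                    r.id_a, r.id_b, round(r.S, 2), round(r.N, 2), round(r.Sd, 2), round(r.Nd, 2),
                    "NA" if r.Ks is None else round(r.Ks, 6),
                    "NA" if r.Ka is None else round(r.Ka, 6),
                    "NA" if r.omega is None else round(r.omega, 4),
                    r.selection_class,
                )
                for r in kaks
            ),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diverge", str(exc)) from exc

    # stage: ssr-poly
    try:
        matched = ssr_polymorphism.match_ssr_loci(
            loci_a, loci_b, pairs, index_a, index_b, config
        )
        poly, poly_summary = ssr_polymorphism.classify_polymorphic(matched)
        write_tsv(
            out / "polymorphic_ssrs.tsv",
            ["transcript_a", "transcript_b", "class", "units_a", "units_b", "unit_diff"],
            (
                (
                    p.match.locus_a.transcript_id,
                    p.match.locus_b.transcript_id,
                    p.canonical_class,
                    p.match.locus_a.unit_count,
                    p.match.locus_b.unit_count,
                    p.unit_diff,
                )
                for p in poly
            ),
        )
    except Exception as exc:
        raise PipelineError("ssr-poly", str(exc)) from exc

    # stage: snp
    accepted: list[SNPCall] = []
    annotation_counts: dict[str, dict[str, int]] = {}
    if pileup is not None:
        try:
            candidates = snp_discovery.call_candidates(pileup)
            accepted, rejected, attrition = snp_discovery.filter_snps(
                candidates, pileup, config
            )
            write_tsv(
                out / "snps.tsv",
                ["transcript_id", "pos", "allele_a", "allele_b", "posterior", "depth_a", "depth_b", "subst_type"],
                (
                    (c.transcript_id, c.pos, c.allele_a, c.allele_b, round(c.posterior, 6), c.depth_a, c.depth_b, c.subst_type)
                    for c in accepted
                ),
            )
            write_tsv(
                out / "snp_attrition.tsv",
                ["filter", "n_removed"],
                sorted(attrition.items()),
            )
        except Exception as exc:
            raise PipelineError("snp", str(exc)) from exc

    if annotation_path is not None:
        table = read_annotation_table(annotation_path)
        annotation_counts = ssr_polymorphism.annotate_markers(poly, table)

    report = summarize(
        transcripts_a=transcripts_a,
        ssr_loci_a=loci_a,
        ssr_loci_b=loci_b,
        transcripts_b=transcripts_b,
        poly_summary=poly_summary,
        accepted_snps=accepted,
        kaks=kaks,
        n_orthologs=len(pairs),
        annotation_counts=annotation_counts,
        config=config,
    )
    report.write(out / "report.txt")
    return report
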