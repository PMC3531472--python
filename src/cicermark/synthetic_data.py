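"""Two-genotype transcriptome simulator with planted ground truth.

Emulates the statistical structure the comparative-marker pipeline
assumes: a codon-structured ancestral transcriptome, two descendant
genotypes separated by a configurable synonymous divergence (with
transition/transversion ratio kappa and a Ka/Ks constraint omega),
planted SSR tracts with per-genotype unit counts, planted fixed and
heterozygous single-nucleotide differences, and per-site dual-genotype
pileups with a Phred error model. Every planted feature is returned as
an explicit truth record so recovery can be scored exactly.

Defaults mirror the chickpea study conditions: GC ~38%, synonymous
divergence on the 0.008 scale of the cultivated/wild split, transition
excess near 2, and read evidence at depth ~10 with Phred ~37.

All generators are deterministic under ``SimParams.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import PileupColumn, Transcript
from .divergence import STOP_CODONS, _CODON_TO_AA, _syn_sites
from .ssr_mining import revcomp

log = logging.getLogger("cicermark")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SSRSpec:
    """One SSR locus to plant: motif plus per-genotype unit counts."""

    motif: str
    units_a: int
    units_b: int
    flank: int = 150  # non-repeat sequence to preserve on both sides


@dataclass
class SimParams:
    n_transcripts: int = 200
    length_min: int = 600
    length_max: int = 1500  # mean ~1 kb, the scale of assembled transcripts
    gc_target: float = 38.0
    synonymous_divergence: float = 0.008  # pairwise Ks target
    omega: float = 0.3  # Ka/Ks target
    kappa: float = 3.8  # transition/transversion rate ratio (~66% transitions)
    ssr_specs: list[SSRSpec] = field(default_factory=list)
    n_fixed_snps: int = 0  # extra fixed differences beyond codon evolution
    n_het_sites: int = 0  # pileup-level heterozygous sites
    n_indel_columns: int = 0  # pileup columns flagged with indel evidence
    depth_mean: float = 10.0
    qual_mean: float = 37.0
    qual_sd: float = 2.0
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.synonymous_divergence):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.length_min < 9 or self.length_max < self.length_min:
            raise ValueError("invalid length range")


@dataclass
class SNPTruth:
    transcript_id: str
    pos: int  # 1-based
    base_a: str
    base_b: str
    kind: str  # "fixed" | "het"
    het_genotype: Optional[str] = None  # "A" or "B" for het sites
    het_alt: Optional[str] = None


@dataclass
class SSRTruth:
    transcript_id: str
    motif: str
    canonical_class: str
    start_a: int  # 1-based tract starts
    start_b: int
    units_a: int
    units_b: int

    @property
    def unit_diff(self) -> int:
        return abs(self.units_a - self.units_b)


@dataclass
class PairTruth:
    transcript_id: str
    n_syn: int
    n_nonsyn: int
    syn_sites: float
    nonsyn_sites: float

    @property
    def realized_ks(self) -> float:
        return self.n_syn / self.syn_sites if self.syn_sites else 0.0

    @property
    def realized_ka(self) -> float:
        return self.n_nonsyn / self.nonsyn_sites if self.nonsyn_sites else 0.0


@dataclass
class SyntheticTruth:
    snps: list[SNPTruth] = field(default_factory=list)
    ssrs: list[SSRTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)
    indel_columns: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    params: SimParams
    ancestors: list[Transcript]
    genotype_a: list[Transcript]
    genotype_b: list[Transcript]
    truth: SyntheticTruth
    pileup: list[PileupColumn] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ancestor generation


def _random_codon(rng: np.random.Generator, p: np.ndarray) -> str:
    while True:
        codon = "".join(_BASES[i] for i in rng.choice(4, size=3, p=p))
        if codon not in STOP_CODONS:
            return codon


def generate_ancestor(params: SimParams, rng: np.random.Generator | None = None) -> list[Transcript]:
    """Codon-structured ancestral transcripts at the target GC content.

    Each transcript is a start codon followed by a stop-free body; codon
    bases are drawn independently with P(G) = P(C) = GC/2 (stop codons
    rejected and redrawn, which perturbs realized GC only slightly).
    """
    rng = rng or np.random.default_rng(params.seed)
    gc = params.gc_target / 100.0
    if not 0.0 < gc < 1.0:
        raise ValueError("GC target must be strictly between 0 and 100%")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    transcripts = []
    for i in range(params.n_transcripts):
        length = int(rng.integers(params.length_min, params.length_max + 1))
        n_codons = max(3, length // 3)
        body = "".join(
            _random_codon(rng, p) for _ in range(n_codons - 1)
        )
        transcripts.append(Transcript(id=f"TC{i + 1:05d}", seq="ATG" + body))
    return transcripts


# ---------------------------------------------------------------------------
# pair evolution


def _draw_substitution(
    codon: str, pos: int, rng: np.random.Generator, kappa: float
) -> str:
    """Random alternative base at codon position, transition-weighted."""
    ref = codon[pos]
    ts = _TRANSITION[ref]
    tvs = [b for b in _BASES if b != ref and b != ts]
    weights = np.array([kappa, 1.0, 1.0])
    weights /= weights.sum()
    return str(rng.choice([ts] + tvs, p=weights))


def evolve_pair(
    ancestor: Transcript,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[str, str, PairTruth, list[SNPTruth]]:
    """Evolve two descendant sequences from one ancestor.

    Substitutions are placed by acceptance resampling: candidate sites
    are drawn with transition probability weighted by kappa, classified
    as synonymous or nonsynonymous against the current codon, and
    accepted while the corresponding quota (synonymous target d/2 per
    lineage over NG86 synonymous sites; nonsynonymous target omega*d/2
    over nonsynonymous sites) is unfilled. Each nucleotide site is hit
    at most once across both lineages, so every substitution is a fixed
    difference between the descendants.
    """
    codons_a = [ancestor.seq[i : i + 3] for i in range(0, len(ancestor.seq) - len(ancestor.seq) % 3, 3)]
    codons_b = list(codons_a)
    S0 = sum(_syn_sites(c) for c in codons_a)
    N0 = 3.0 * len(codons_a) - S0
    d = params.synonymous_divergence
    quota = {
        "A": {
            True: int(round(S0 * d / 2.0)),
            False: int(round(N0 * params.omega * d / 2.0)),
        },
    }
    quota["B"] = dict(quota["A"])
    total_target = sum(sum(q.values()) for q in quota.values())
    used_sites: set[int] = set()
    snps: list[SNPTruth] = []
    n_syn = n_nonsyn = 0
    attempts = 0
    max_attempts = 1000 * (total_target + 10)
    while total_target > 0:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"substitution targets unreachable on {ancestor.id}"
            )
        lineage = "A" if rng.random() < 0.5 else "B"
        codons = codons_a if lineage == "A" else codons_b
        ci = int(rng.integers(1, len(codons)))  # keep the start codon intact
        pos = int(rng.integers(0, 3))
        site = 3 * ci + pos
        if site in used_sites:
            continue
        cur = codons[ci]
        alt_base = _draw_substitution(cur, pos, rng, params.kappa)
        alt = cur[:pos] + alt_base + cur[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        synonymous = _CODON_TO_AA[alt] == _CODON_TO_AA[cur]
        if quota[lineage][synonymous] <= 0:
            continue
        quota[lineage][synonymous] -= 1
        total_target -= 1
        used_sites.add(site)
        codons[ci] = alt
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
        ref_base = cur[pos]
        snps.append(
            SNPTruth(
                transcript_id=ancestor.id,
                pos=site + 1,
                base_a=alt_base if lineage == "A" else ref_base,
                base_b=alt_base if lineage == "B" else ref_base,
                kind="fixed",
            )
        )
    seq_a = "".join(codons_a)
    seq_b = "".join(codons_b)
    pair = PairTruth(
        transcript_id=ancestor.id,
        n_syn=n_syn,
        n_nonsyn=n_nonsyn,
        syn_sites=S0,
        nonsyn_sites=N0,
    )
    return seq_a, seq_b, pair, snps


def plant_snps(
    seq_a: str,
    seq_b: str,
    transcript_id: str,
    n: int,
    params: SimParams,
    rng: np.random.Generator,
    forbidden: set[int] | None = None,
) -> tuple[str, str, list[SNPTruth]]:
    """Plant n extra fixed differences at distinct positions (0-based
    ``forbidden`` positions are avoided); genotype B carries the
    alternative base, transition-weighted by kappa."""
    forbidden = set(forbidden or ())
    length = min(len(seq_a), len(seq_b))
    free = [i for i in range(length) if i not in forbidden and seq_a[i] == seq_b[i]]
    if n > len(free):
        raise ValueError(f"not enough free sites on {transcript_id} to plant {n} SNPs")
    sites = rng.choice(len(free), size=n, replace=False)
    b = list(seq_b)
    snps = []
    for si in sorted(int(s) for s in sites):
        i = free[si]
        ref = seq_a[i]
        ts = _TRANSITION[ref]
        tvs = [x for x in _BASES if x != ref and x != ts]
        w = np.array([params.kappa, 1.0, 1.0])
        alt = str(rng.choice([ts] + tvs, p=w / w.sum()))
        b[i] = alt
        snps.append(
            SNPTruth(
                transcript_id=transcript_id,
                pos=i + 1,
                base_a=ref,
                base_b=alt,
                kind="fixed",
            )
        )
    return seq_a, "".join(b), snps


# ---------------------------------------------------------------------------
# SSR planting


def plant_ssr(
    seq_a: str,
    seq_b: str,
    transcript_id: str,
    spec: SSRSpec,
    rng: np.random.Generator,
) -> tuple[str, str, SSRTruth]:
    """Insert one SSR tract at a homologous position in both genotypes.

    The same motif is inserted at the same ancestral offset with
    per-genotype unit counts. The single bases adjacent to the insert
    are forced (identically in both genotypes) to break the repeat
    period, so the mined tract is exactly the planted one.
    """
    from .ssr_mining import class_label

    k = len(spec.motif)
    length = min(len(seq_a), len(seq_b))
    lo, hi = spec.flank, length - spec.flank
    if hi <= lo:
        raise ValueError(
            f"{transcript_id}: too short for flank {spec.flank} on both sides"
        )
    p = int(rng.integers(lo, hi))
    tract_a = spec.motif * spec.units_a
    tract_b = spec.motif * spec.units_b

    def insert(seq: str, tract: str) -> str:
        left, right = seq[:p], seq[p:]
        # break the period at both boundaries
        left_break = next(b for b in _BASES if b != spec.motif[-1] and b != left[-1:])
        right_break = next(b for b in _BASES if b != spec.motif[0] and b != right[:1])
        return left[:-1] + left_break + tract + right_break + right[1:]

    return (
        insert(seq_a, tract_a),
        insert(seq_b, tract_b),
        SSRTruth(
            transcript_id=transcript_id,
            motif=spec.motif,
            canonical_class=class_label(spec.motif),
            start_a=p + 1,
            start_b=p + 1,
            units_a=spec.units_a,
            units_b=spec.units_b,
        ),
    )


# ---------------------------------------------------------------------------
# pileup simulation


def _read_bases(
    true_base: str, depth: int, error_rate: float, rng: np.random.Generator
) -> str:
    bases = []
    for _ in range(depth):
        if rng.random() < error_rate:
            alts = [b for b in _BASES if b != true_base]
            bases.append(alts[int(rng.integers(0, 3))])
        else:
            bases.append(true_base)
    return "".join(bases)


def simulate_pileups(
    seq_a: str,
    seq_b: str,
    transcript_id: str,
    params: SimParams,
    rng: np.random.Generator,
    het_sites: Sequence[SNPTruth] = (),
    indel_positions: Sequence[int] = (),
) -> list[PileupColumn]:
    """Per-position dual-genotype pileup columns with a Phred error model.

    Depth is Poisson(depth_mean) per genotype; bases are copied from the
    genotype sequence and flipped to a uniform wrong base at the error
    rate; qualities are normal(qual_mean, qual_sd) rounded and clipped.
    Heterozygous truth sites emit a 50/50 base mixture in the designated
    genotype; indel columns carry indel_evidence counts.
    """
    het_by_pos = {h.pos: h for h in het_sites}
    indel_set = set(indel_positions)
    length = min(len(seq_a), len(seq_b))
    columns = []
    for i in range(length):
        pos = i + 1
        depth_a = int(rng.poisson(params.depth_mean))
        depth_b = int(rng.poisson(params.depth_mean))
        het = het_by_pos.get(pos)

        def draw(base: str, depth: int, genotype: str) -> str:
            if het is not None and het.het_genotype == genotype:
                # exact 50/50 allele mixture (even sampling of a diploid site)
                trues = [base] * (depth - depth // 2) + [het.het_alt] * (depth // 2)
                rng.shuffle(trues)
                return "".join(
                    _read_bases(t, 1, params.error_rate, rng) for t in trues
                )
            return _read_bases(base, depth, params.error_rate, rng)

        bases_a = draw(seq_a[i], depth_a, "A")
        bases_b = draw(seq_b[i], depth_b, "B")
        quals_a = np.clip(
            np.rint(rng.normal(params.qual_mean, params.qual_sd, depth_a)), 2, 60
        ).astype(int)
        quals_b = np.clip(
            np.rint(rng.normal(params.qual_mean, params.qual_sd, depth_b)), 2, 60
        ).astype(int)
        columns.append(
            PileupColumn(
                transcript_id=transcript_id,
                pos=pos,
                bases_a=bases_a,
                quals_a=[int(q) for q in quals_a],
                bases_b=bases_b,
                quals_b=[int(q) for q in quals_b],
                indel_a=int(pos in indel_set),
                indel_b=0,
            )
        )
    return columns


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(params: SimParams, with_pileups: bool = True) -> SyntheticDataset:
    """Full two-genotype fixture.

    Transcripts carrying planted SSRs (the first ``len(ssr_specs)``) are
    excluded from SNP planting and pileup simulation, because unequal
    SSR insertions shift homologous coordinates; all other transcripts
    evolve under the divergence model, then receive extra planted fixed
    differences and heterozygous sites spread round-robin.
    """
    rng = np.random.default_rng(params.seed)
    ancestors = generate_ancestor(params, rng)
    n_ssr = len(params.ssr_specs)
    if n_ssr > params.n_transcripts:
        raise ValueError("more SSR specs than transcripts")
    truth = SyntheticTruth()
    genotype_a: list[Transcript] = []
    genotype_b: list[Transcript] = []
    pileup: list[PileupColumn] = []

    snp_transcripts = ancestors[n_ssr:]
    extra_per = np.zeros(len(snp_transcripts), dtype=int)
    if params.n_fixed_snps:
        if not snp_transcripts:
            raise ValueError("no transcripts left for SNP planting")
        extra_per += params.n_fixed_snps // len(snp_transcripts)
        extra_per[: params.n_fixed_snps % len(snp_transcripts)] += 1
    het_per = np.zeros(len(snp_transcripts), dtype=int)
    if params.n_het_sites:
        het_per += params.n_het_sites // len(snp_transcripts)
        het_per[: params.n_het_sites % len(snp_transcripts)] += 1
    indel_per = np.zeros(len(snp_transcripts), dtype=int)
    if params.n_indel_columns:
        indel_per += params.n_indel_columns // len(snp_transcripts)
        indel_per[: params.n_indel_columns % len(snp_transcripts)] += 1

    for idx, anc in enumerate(ancestors):
        seq_a, seq_b, pair, snps = evolve_pair(anc, params, rng)
        if idx < n_ssr:
            seq_a, seq_b, ssr = plant_ssr(
                seq_a, seq_b, anc.id, params.ssr_specs[idx], rng
            )
            truth.ssrs.append(ssr)
            # coordinates shifted by the insert; evolved-substitution SNP
            # truth on SSR transcripts is dropped rather than remapped
        else:
            truth.pairs.append(pair)
            truth.snps.extend(snps)
            j = idx - n_ssr
            occupied = {s.pos - 1 for s in snps}
            if extra_per[j]:
                seq_a, seq_b, extra = plant_snps(
                    seq_a, seq_b, anc.id, int(extra_per[j]), params, rng, occupied
                )
                truth.snps.extend(extra)
                occupied |= {s.pos - 1 for s in extra}
            het_sites: list[SNPTruth] = []
            for _ in range(int(het_per[j])):
                free = [
                    i for i in range(len(seq_a)) if i not in occupied
                ]
                i = free[int(rng.integers(0, len(free)))]
                occupied.add(i)
                ref = seq_a[i]
                alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
                het_sites.append(
                    SNPTruth(
                        transcript_id=anc.id,
                        pos=i + 1,
                        base_a=ref,
                        base_b=seq_b[i],
                        kind="het",
                        het_genotype="A",
                        het_alt=alt,
                    )
                )
            truth.snps.extend(het_sites)
            indel_positions = []
            for _ in range(int(indel_per[j])):
                free = [i for i in range(len(seq_a)) if i not in occupied]
                i = free[int(rng.integers(0, len(free)))]
                occupied.add(i)
                indel_positions.append(i + 1)
            truth.indel_columns.extend((anc.id, p) for p in indel_positions)
            if with_pileups:
                pileup.extend(
                    simulate_pileups(
                        seq_a,
                        seq_b,
                        anc.id,
                        params,
                        rng,
                        het_sites=het_sites,
                        indel_positions=indel_positions,
                    )
                )
        genotype_a.append(Transcript(id=anc.id, seq=seq_a))
        genotype_b.append(Transcript(id=anc.id, seq=seq_b))

    return SyntheticDataset(
        params=params,
        ancestors=ancestors,
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        truth=truth,
        pileup=pileup,
    )
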