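"""Fixed-difference SNP calling between two genotypes from dual pileups.

A site is a candidate when a Bayesian model over fixed alleles favours
different bases in the two genotypes: per genotype g and allele x the
likelihood is the product over reads of (1-e_i) for matches and e_i/3
for mismatches, with e_i = 10^(-q_i/10) capped at 3/4 (a quality-0 base
is uninformative). With a uniform prior over the 16 ordered allele
pairs, the reported posterior is the total probability of all pairs
whose alleles differ.

Candidates then pass a fixed filter chain: posterior >= 0.95, per-site
mean Phred >= 30 in each genotype, read depth >= 3 in each genotype,
consensus base ratio of 1 in each genotype (all reads agree), removal
of clustered candidates (three or more in any 10 bp window) and of
candidates within 3 bp of a column with indel evidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core_io import PileupColumn, RunConfig

log = logging.getLogger("cicermark")

BASES = "ACGT"
TRANSITIONS = ({"A", "G"}, {"C", "T"})

# filter flags in application order
FLAG_ORDER = (
    "low_posterior",
    "low_quality",
    "low_depth",
    "not_fixed",
    "clustered",
    "near_indel",
)


@dataclass
class SNPCall:
    transcript_id: str
    pos: int
    allele_a: str
    allele_b: str
    posterior: float
    depth_a: int
    depth_b: int
    mean_qual_a: float
    mean_qual_b: float
    consensus_ratio_a: float
    consensus_ratio_b: float
    filter_flags: set[str] = field(default_factory=set)

    @property
    def subst_type(self) -> str:
        return (
            "transition"
            if {self.allele_a, self.allele_b} in TRANSITIONS
            else "transversion"
        )

    @property
    def accepted(self) -> bool:
        return not self.filter_flags


def _log_likelihoods(bases: str, quals: Sequence[int]) -> list[float]:
    """log L(x) for x in ACGT under the fixed-allele read-error model."""
    out = []
    errors = [min(10.0 ** (-q / 10.0), 0.75) for q in quals]
    for x in BASES:
        ll = 0.0
        for b, e in zip(bases, errors):
            ll += math.log1p(-e) if b == x else math.log(e / 3.0)
        out.append(ll)
    return out


def site_posterior(column: PileupColumn) -> tuple[str, str, float]:
    """Most probable ordered allele pair and the posterior that the two
    genotypes carry different fixed alleles.

    N bases are dropped before evaluation; an empty genotype column is an
    error. The allele pair is the argmax over all 16 ordered pairs (it
    may have equal alleles when the site is not a difference).
    """
    bases_a = [
        (b, q) for b, q in zip(column.bases_a, column.quals_a) if b in BASES
    ]
    bases_b = [
        (b, q) for b, q in zip(column.bases_b, column.quals_b) if b in BASES
    ]
    if not bases_a or not bases_b:
        raise ValueError(
            f"{column.transcript_id}:{column.pos}: empty genotype column"
        )
    lla = _log_likelihoods(
        "".join(b for b, _ in bases_a), [q for _, q in bases_a]
    )
    llb = _log_likelihoods(
        "".join(b for b, _ in bases_b), [q for _, q in bases_b]
    )
    joint = [
        (lla[i] + llb[j], BASES[i], BASES[j])
        for i in range(4)
        for j in range(4)
    ]
    m = max(ll for ll, _, _ in joint)
    weights = [(math.exp(ll - m), xa, xb) for ll, xa, xb in joint]
    total = sum(w for w, _, _ in weights)
    p_diff = sum(w for w, xa, xb in weights if xa != xb) / total
    _, best_a, best_b = max(weights, key=lambda t: t[0])
    return best_a, best_b, p_diff


def _consensus(bases: Iterable[str], allele: str) -> float:
    """Fraction of (non-N) reads supporting the given allele."""
    kept = [b for b in bases if b in BASES]
    if not kept:
        return 0.0
    return sum(1 for b in kept if b == allele) / len(kept)


def call_candidates(
    columns: Iterable[PileupColumn],
) -> list[SNPCall]:
    """Evaluate the site model on every usable column and keep candidates
    whose argmax allele pair differs between genotypes.

    Columns with an empty genotype (after N removal) are skipped and
    counted, not raised, so whole-pileup scans are total.
    """
    calls: list[SNPCall] = []
    skipped = 0
    for col in columns:
        bases_a = [b for b in col.bases_a if b in BASES]
        bases_b = [b for b in col.bases_b if b in BASES]
        if not bases_a or not bases_b:
            skipped += 1
            continue
        # cheap prescreen: if the two genotypes share an identical base
        # multiset composed of one base each, no differing pair can win
        if set(bases_a) == set(bases_b) and len(set(bases_a)) == 1:
            continue
        allele_a, allele_b, posterior = site_posterior(col)
        if allele_a == allele_b:
            continue
        quals_a = [q for b, q in zip(col.bases_a, col.quals_a) if b in BASES]
        quals_b = [q for b, q in zip(col.bases_b, col.quals_b) if b in BASES]
        calls.append(
            SNPCall(
                transcript_id=col.transcript_id,
                pos=col.pos,
                allele_a=allele_a,
                allele_b=allele_b,
                posterior=posterior,
                depth_a=len(bases_a),
                depth_b=len(bases_b),
                mean_qual_a=sum(quals_a) / len(quals_a),
                mean_qual_b=sum(quals_b) / len(quals_b),
                consensus_ratio_a=_consensus(col.bases_a, allele_a),
                consensus_ratio_b=_consensus(col.bases_b, allele_b),
            )
        )
    if skipped:
        log.info("call_candidates: %d columns skipped (no usable reads)", skipped)
    return calls


def filter_snps(
    candidates: Sequence[SNPCall],
    columns: Iterable[PileupColumn],
    config: RunConfig | None = None,
) -> tuple[list[SNPCall], list[SNPCall], dict[str, int]]:
    """Apply the fixed-difference filter chain.

    Order: posterior, mean base quality, depth, consensus ratio; then the
    cluster rule (every candidate in any 10 bp window holding three or
    more survivors is removed); then proximity to indel evidence (within
    3 bp of a column with indel_evidence > 0 in either genotype). Each
    reject carries its first failing flag. Returns (accepted, rejected,
    per-filter attrition counts).
    """
    config = config or RunConfig()
    attrition = {flag: 0 for flag in FLAG_ORDER}

    indel_positions: dict[str, list[int]] = {}
    for col in columns:
        if col.has_indel:
            indel_positions.setdefault(col.transcript_id, []).append(col.pos)

    survivors: list[SNPCall] = []
    rejected: list[SNPCall] = []
    for c in candidates:
        flag = None
        if c.posterior < config.snp_min_posterior:
            flag = "low_posterior"
        elif min(c.mean_qual_a, c.mean_qual_b) < config.snp_min_mean_qual:
            flag = "low_quality"
        elif min(c.depth_a, c.depth_b) < config.snp_min_depth:
            flag = "low_depth"
        elif c.consensus_ratio_a < 1.0 or c.consensus_ratio_b < 1.0:
            flag = "not_fixed"
        if flag:
            c.filter_flags.add(flag)
            attrition[flag] += 1
            rejected.append(c)
        else:
            survivors.append(c)

    # cluster rule on survivors, per transcript
    by_transcript: dict[str, list[SNPCall]] = {}
    for c in survivors:
        by_transcript.setdefault(c.transcript_id, []).append(c)
    clustered: set[int] = set()
    for calls in by_transcript.values():
        calls.sort(key=lambda c: c.pos)
        positions = [c.pos for c in calls]
        n = len(positions)
        for i in range(n):
            j = i
            while j + 1 < n and positions[j + 1] <= positions[i] + (
                config.snp_cluster_window - 1
            ):
                j += 1
            if j - i + 1 >= config.snp_cluster_count:
                for t in range(i, j + 1):
                    clustered.add(id(calls[t]))
    after_cluster: list[SNPCall] = []
    for c in survivors:
        if id(c) in clustered:
            c.filter_flags.add("clustered")
            attrition["clustered"] += 1
            rejected.append(c)
        else:
            after_cluster.append(c)

    accepted: list[SNPCall] = []
    for c in after_cluster:
        near = any(
            abs(c.pos - p) <= config.snp_indel_flank
            for p in indel_positions.get(c.transcript_id, ())
        )
        if near:
            c.filter_flags.add("near_indel")
            attrition["near_indel"] += 1
            rejected.append(c)
        else:
            accepted.append(c)

    log.info(
        "filter_snps: %d candidates -> %d accepted; attrition %s",
        len(candidates),
        len(accepted),
        attrition,
    )
    accepted.sort(key=lambda c: (c.transcript_id, c.pos))
    rejected.sort(key=lambda c: (c.transcript_id, c.pos))
    return accepted, rejected, attrition


@dataclass(frozen=True)
class SubstitutionSummary:
    n_total: int
    n_transitions: int
    n_transversions: int
    type_counts: dict[str, int]  # unordered pairs, e.g. "A/G"

    @property
    def transition_fraction(self) -> float:
        return self.n_transitions / self.n_total if self.n_total else 0.0

    @property
    def ts_tv_ratio(self) -> Optional[float]:
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions


def classify_substitutions(calls: Iterable[SNPCall]) -> SubstitutionSummary:
    """Transition/transversion counts and the six unordered substitution
    types over a set of SNP calls."""
    ts = tv = 0
    types: dict[str, int] = {}
    n = 0
    for c in calls:
        n += 1
        if c.subst_type == "transition":
            ts += 1
        else:
            tv += 1
        key = "/".join(sorted((c.allele_a, c.allele_b)))
        types[key] = types.get(key, 0) + 1
    return SubstitutionSummary(
        n_total=n, n_transitions=ts, n_transversions=tv, type_counts=types
    )


def snp_density(
    n_snps: int, transcriptome_kb: float
) -> tuple[float, Optional[float]]:
    """(SNPs per kb, kb of transcriptome per SNP); kb-per-SNP is None for
    an empty call set."""
    if transcriptome_kb <= 0:
        raise ValueError("transcriptome_kb must be positive")
    snp_per_kb = n_snps / transcriptome_kb
    kb_per_snp = transcriptome_kb / n_snps if n_snps else None
    return snp_per_kb, kb_per_snp


def per_transcript_counts(calls: Iterable[SNPCall]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.transcript_id] = counts.get(c.transcript_id, 0) + 1
    return counts
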