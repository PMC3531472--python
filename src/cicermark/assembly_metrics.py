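"""Assembly-assessment statistics used to rank transcriptome assemblies.

Covers the standard contig statistics (counts, sizes, N50, GC) and
reference-proteome coverage from tabular protein hits: the fraction of
reference proteins with any significant hit and the fraction whose length
is covered to at least 80% by the union of HSP intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import HitRecord, Transcript


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    n_large: int
    total_size: int
    max_len: int
    mean_len: float
    n50: int
    mean_gc: float


@dataclass(frozen=True)
class CoverageSummary:
    n_ref_proteins: int
    n_hit: int
    n_covered80: int

    @property
    def frac_hit(self) -> float:
        return self.n_hit / self.n_ref_proteins if self.n_ref_proteins else 0.0

    @property
    def frac_covered80(self) -> float:
        return (
            self.n_covered80 / self.n_ref_proteins if self.n_ref_proteins else 0.0
        )


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs of length >= L hold half the bases.

    Ties use the conventional >= T/2 threshold and the contig meeting the
    threshold is included.
    """
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("all contig lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def gc_percent(seq: str) -> float:
    """GC percentage over non-N bases (0.0 for an all-N sequence)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / acgt


def assembly_summary(
    transcripts: Iterable[Transcript],
    large_cutoff: int = 1000,
    min_len: int = 100,
) -> AssemblyStats:
    """Contig statistics over contigs of at least ``min_len`` bp.

    Contigs below ``min_len`` are excluded from every statistic; the mean
    is reported to 0.1 bp; GC is computed over non-N bases, weighted by
    contig length.
    """
    kept = [t for t in transcripts if t.length >= min_len]
    if not kept:
        raise ValueError(f"no contigs of length >= {min_len}")
    lengths = [t.length for t in kept]
    total = sum(lengths)
    gc = sum(t.seq.count("G") + t.seq.count("C") for t in kept)
    acgt = sum(sum(t.seq.count(b) for b in "ACGT") for t in kept)
    return AssemblyStats(
        n_contigs=len(kept),
        n_large=sum(1 for l in lengths if l >= large_cutoff),
        total_size=total,
        max_len=max(lengths),
        mean_len=round(total / len(kept), 1),
        n50=n50(lengths),
        mean_gc=100.0 * gc / acgt if acgt else 0.0,
    )


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based closed intervals."""
    covered = 0
    end = 0  # rightmost covered coordinate so far
    for lo, hi in sorted(intervals):
        if hi <= end:
            continue
        covered += hi - max(end + 1, lo) + 1
        end = hi
    return covered


def proteome_coverage(
    hits: Iterable[HitRecord],
    protein_lengths: Mapping[str, int],
    e_max: float = 1e-5,
    cov_threshold: float = 80.0,
) -> CoverageSummary:
    """Reference-proteome representation from tabular hits.

    Per protein, coverage is the union of subject-coordinate HSP intervals
    across all hits with E-value <= ``e_max``, divided by protein length.
    Reverse-orientation hits are normalized before merging.
    """
    by_protein: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.subject_id not in protein_lengths:
            raise ValueError(f"hit references unknown protein {h.subject_id!r}")
        if h.evalue > e_max:
            continue
        by_protein.setdefault(h.subject_id, []).append(h.subject_interval())
    n_covered80 = 0
    for pid, intervals in by_protein.items():
        coverage = 100.0 * _union_length(intervals) / protein_lengths[pid]
        if coverage >= cov_threshold:
            n_covered80 += 1
    return CoverageSummary(
        n_ref_proteins=len(protein_lengths),
        n_hit=len(by_protein),
        n_covered80=n_covered80,
    )
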