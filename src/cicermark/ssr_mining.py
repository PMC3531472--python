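"""Perfect-microsatellite (SSR) detection and EST-SSR marker support.

Detects maximal perfect tandem repeats of primitive 2–6 nt units subject
to tract-length minima (12 nt for dinucleotides, 15 nt for tri- to
hexa-nucleotides), normalizes motifs to their canonical class under
cyclic rotation and reverse complement (reported as "motif/revcomp",
e.g. "AG/CT"), groups nearby tracts into compound repeats, summarizes
density and class composition, and picks flanking PCR primer pairs for
loci with at least 100 bp of flank on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .core_io import RunConfig, Transcript

log = logging.getLogger("cicermark")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number power of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Smallest string among all cyclic rotations of the motif and of its
    reverse complement; the class representative (idempotent)."""
    k = len(motif)
    if not (2 <= k <= 6):
        raise ValueError(f"motif length must be 2-6, got {k}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} has non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    candidates = []
    for m in (motif, revcomp(motif)):
        candidates.extend(m[i:] + m[:i] for i in range(k))
    return min(candidates)


def class_label(motif: str) -> str:
    """Canonical class label in "canonical/revcomp" form, e.g. "AG/CT"."""
    canon = canonical_motif(motif)
    return f"{canon}/{revcomp(canon)}"


@dataclass
class SSRLocus:
    """A perfect microsatellite tract (1-based inclusive coordinates)."""

    transcript_id: str
    start: int
    end: int
    motif: str
    canonical_class: str
    unit_count: int
    compound_group: Optional[int] = None

    @property
    def k(self) -> int:
        return len(self.motif)

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class PrimerPair:
    transcript_id: str
    locus_start: int
    locus_end: int
    forward_seq: str
    reverse_seq: str
    f_start: int
    r_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float

    @property
    def product_size(self) -> int:
        return self.r_end - self.f_start + 1


@dataclass(frozen=True)
class Ineligible:
    """Marker for a locus no primer pair can serve, with the reason."""

    reason: str


def find_ssrs(transcript: Transcript, config: RunConfig | None = None) -> list[SSRLocus]:
    """All maximal perfect SSR tracts of primitive units k=2..6.

    A tract is the leading complete-unit run of a maximal period-k region
    (a stretch where every base equals the base k positions earlier);
    partial trailing units are not counted. N terminates regions. When
    tracts of different unit sizes overlap, the longer tract wins and the
    other is dropped (equal lengths keep the smaller unit, then the
    leftmost). Output is sorted by start and pairwise non-overlapping.
    """
    config = config or RunConfig()
    seq = transcript.seq
    n = len(seq)
    loci: list[SSRLocus] = []
    for k in range(2, 7):
        min_units = config.min_unit_count(k)
        i = 0
        while i + k * min_units <= n:
            motif = seq[i : i + k]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            units = (j - i) // k
            if units >= min_units:
                loci.append(
                    SSRLocus(
                        transcript_id=transcript.id,
                        start=i + 1,
                        end=i + units * k,
                        motif=motif,
                        canonical_class=class_label(motif),
                        unit_count=units,
                    )
                )
                i = j - k + 1  # next window that could open a new region
            else:
                i += 1
    # overlap resolution across unit sizes: keep longer tracts first and
    # drop anything overlapping a kept locus (subsumes the containment
    # case); equal-length ties prefer the smaller unit size, then the
    # leftmost start
    loci.sort(key=lambda l: (-l.tract_length, l.k, l.start, l.motif))
    kept: list[SSRLocus] = []
    for locus in loci:
        if all(locus.end < o.start or o.end < locus.start for o in kept):
            kept.append(locus)
    kept.sort(key=lambda l: l.start)
    return kept


def find_all_ssrs(
    transcripts: Iterable[Transcript], config: RunConfig | None = None
) -> list[SSRLocus]:
    config = config or RunConfig()
    out: list[SSRLocus] = []
    for t in transcripts:
        out.extend(merge_compound(find_ssrs(t, config), config.compound_max_gap))
    return out


def merge_compound(loci: Sequence[SSRLocus], max_gap: int = 100) -> list[SSRLocus]:
    """Assign compound-group ids to runs of tracts separated by <= max_gap nt.

    Input must be sorted, non-overlapping loci from one transcript.
    Singleton groups get no compound_group.
    """
    loci = list(loci)
    for prev, cur in zip(loci, loci[1:]):
        if prev.transcript_id != cur.transcript_id:
            raise ValueError("merge_compound expects loci from one transcript")
        if cur.start <= prev.end:
            raise ValueError(
                f"overlapping loci at {prev.transcript_id}:{prev.start}-{prev.end}"
                f" and {cur.start}-{cur.end}"
            )
        if cur.start < prev.start:
            raise ValueError("loci must be sorted by start")
    out: list[SSRLocus] = []
    group: list[SSRLocus] = []
    next_gid = 1

    def flush() -> int:
        nonlocal next_gid
        if len(group) >= 2:
            gid = next_gid
            next_gid += 1
            out.extend(replace(l, compound_group=gid) for l in group)
        else:
            out.extend(replace(l, compound_group=None) for l in group)
        group.clear()
        return next_gid

    for locus in loci:
        if group and locus.start - group[-1].end - 1 <= max_gap:
            group.append(locus)
        else:
            flush()
            group.append(locus)
    flush()
    return out


@dataclass
class SSRStats:
    n_loci: int
    kb_per_ssr: Optional[float]
    ssr_per_kb: float
    class_frequencies: dict[str, int]
    unit_size_histogram: dict[int, int]
    mean_tract_length: dict[int, float]  # per unit size k
    mean_unit_count: dict[int, float]  # per unit size k
    n_long: int  # tracts >= long_cutoff nt
    n_compound: int
    transcripts_with_ssr: int
    transcripts_with_2plus: int


def ssr_stats(
    loci: Sequence[SSRLocus], transcriptome_kb: float, long_cutoff: int = 20
) -> SSRStats:
    """Density and composition summary over a set of SSR loci.

    Density is reported both ways (kb of transcriptome per SSR, and SSRs
    per kb); per-unit-size means follow marker-table semantics (mean
    tract length in nt and mean number of repeat units).
    """
    if transcriptome_kb <= 0:
        raise ValueError("transcriptome_kb must be positive")
    classes: dict[str, int] = {}
    sizes: dict[int, int] = {}
    tract_sums: dict[int, int] = {}
    unit_sums: dict[int, int] = {}
    per_transcript: dict[str, int] = {}
    for l in loci:
        classes[l.canonical_class] = classes.get(l.canonical_class, 0) + 1
        sizes[l.k] = sizes.get(l.k, 0) + 1
        tract_sums[l.k] = tract_sums.get(l.k, 0) + l.tract_length
        unit_sums[l.k] = unit_sums.get(l.k, 0) + l.unit_count
        per_transcript[l.transcript_id] = per_transcript.get(l.transcript_id, 0) + 1
    n = len(loci)
    return SSRStats(
        n_loci=n,
        kb_per_ssr=(transcriptome_kb / n) if n else None,
        ssr_per_kb=n / transcriptome_kb,
        class_frequencies=classes,
        unit_size_histogram=sizes,
        mean_tract_length={k: tract_sums[k] / sizes[k] for k in sizes},
        mean_unit_count={k: unit_sums[k] / sizes[k] for k in sizes},
        n_long=sum(1 for l in loci if l.tract_length >= long_cutoff),
        n_compound=sum(1 for l in loci if l.compound_group is not None),
        transcripts_with_ssr=len(per_transcript),
        transcripts_with_2plus=sum(1 for c in per_transcript.values() if c >= 2),
    )


# ---------------------------------------------------------------------------
# primer design


def primer_gc(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def primer_tm(seq: str) -> float:
    """Approximate melting temperature, Tm = 64.9 + 41*(GC - 16.4)/len."""
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def max_mono_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def primer_ok(seq: str, config: RunConfig) -> bool:
    if "N" in seq:
        return False
    return (
        config.primer_gc_min <= primer_gc(seq) <= config.primer_gc_max
        and config.primer_tm_min <= primer_tm(seq) <= config.primer_tm_max
        and max_mono_run(seq) <= config.primer_max_mono_run
    )


def _scan_forward(flank: str, config: RunConfig) -> Optional[tuple[int, str]]:
    """Best forward-primer window in the left flank: closest to the tract.

    Returns (0-based start within flank, primer sequence)."""
    n = len(flank)
    for right in range(n, config.primer_len_min - 1, -1):  # 3' end near tract
        for length in range(config.primer_len_min, config.primer_len_max + 1):
            if right - length < 0:
                continue
            cand = flank[right - length : right]
            if primer_ok(cand, config):
                return right - length, cand
    return None


def _scan_reverse(flank: str, config: RunConfig) -> Optional[tuple[int, str]]:
    """Best reverse-primer window in the right flank (closest to the tract).

    Returns (0-based end within flank, inclusive, primer sequence on the
    reverse strand)."""
    n = len(flank)
    for left in range(0, n - config.primer_len_min + 1):
        for length in range(config.primer_len_min, config.primer_len_max + 1):
            if left + length > n:
                continue
            cand = revcomp(flank[left : left + length])
            if primer_ok(cand, config):
                return left + length - 1, cand
    return None


def design_primer_pair(
    transcript: Transcript, locus: SSRLocus, config: RunConfig | None = None
) -> PrimerPair | Ineligible:
    """Pick a flanking primer pair for an SSR locus, or explain why not.

    Eligibility requires >= ``primer_flank_min`` nt of flank on both sides.
    Each flank is scanned from the tract outward for the first window of
    18-24 nt satisfying GC 40-60%, Tm 55-62 C and no mononucleotide run
    of 5+. Primers exclude the tract itself.
    """
    config = config or RunConfig()
    seq = transcript.seq
    if locus.start < 1 or locus.end > len(seq):
        raise ValueError(
            f"locus {locus.start}-{locus.end} outside transcript {transcript.id}"
        )
    left = seq[: locus.start - 1]
    right = seq[locus.end :]
    if len(left) < config.primer_flank_min or len(right) < config.primer_flank_min:
        return Ineligible(
            f"flank too short: left {len(left)} nt, right {len(right)} nt"
            f" (minimum {config.primer_flank_min})"
        )
    fwd = _scan_forward(left, config)
    if fwd is None:
        return Ineligible("no acceptable forward primer in left flank")
    rev = _scan_reverse(right, config)
    if rev is None:
        return Ineligible("no acceptable reverse primer in right flank")
    f_off, f_seq = fwd
    r_off, r_seq = rev
    return PrimerPair(
        transcript_id=transcript.id,
        locus_start=locus.start,
        locus_end=locus.end,
        forward_seq=f_seq,
        reverse_seq=r_seq,
        f_start=f_off + 1,
        r_end=locus.end + r_off + 1,
        tm_f=primer_tm(f_seq),
        tm_r=primer_tm(r_seq),
        gc_f=primer_gc(f_seq),
        gc_r=primer_gc(r_seq),
    )
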