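"""Cross-genotype polymorphic SSR detection.

SSR loci mined independently from two genotypes' transcriptomes are
anchored on ortholog pairs: within each ortholog pair, loci of the same
canonical class are matched when the sequence immediately flanking the
two tracts agrees (ungapped identity over a configurable window,
default 20 nt at >= 90%). A matched pair whose unit counts differ is a
candidate polymorphic SSR; the difference in repeat units times the
unit size is the expected fragment-length polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_io import Transcript, RunConfig
from .divergence import OrthologPair
from .ssr_mining import SSRLocus

log = logging.getLogger("cicermark")


@dataclass
class MatchedSSR:
    locus_a: SSRLocus
    locus_b: SSRLocus
    flank_identity_left: float
    flank_identity_right: float

    @property
    def canonical_class(self) -> str:
        return self.locus_a.canonical_class

    @property
    def unit_diff(self) -> int:
        return abs(self.locus_a.unit_count - self.locus_b.unit_count)


@dataclass
class PolymorphicSSR:
    match: MatchedSSR
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def canonical_class(self) -> str:
        return self.match.canonical_class

    @property
    def unit_diff(self) -> int:
        return self.match.unit_diff


def _identity(x: str, y: str) -> float:
    """Ungapped percent identity over the shorter of the two strings
    (0.0 when either window is empty)."""
    n = min(len(x), len(y))
    if n == 0:
        return 0.0
    return 100.0 * sum(1 for a, b in zip(x[:n], y[:n]) if a == b) / n


def _flank_identities(
    ta: Transcript, la: SSRLocus, tb: Transcript, lb: SSRLocus, window: int
) -> tuple[float, float]:
    """Identity of the window nt immediately left (right-aligned at the
    tract edge) and right (left-aligned) of the two tracts."""
    left_a = ta.seq[max(0, la.start - 1 - window) : la.start - 1]
    left_b = tb.seq[max(0, lb.start - 1 - window) : lb.start - 1]
    right_a = ta.seq[la.end : la.end + window]
    right_b = tb.seq[lb.end : lb.end + window]
    # right-align the left flanks at the tract edge
    n_left = min(len(left_a), len(left_b))
    left = _identity(left_a[-n_left:], left_b[-n_left:]) if n_left else 0.0
    right = _identity(right_a, right_b)
    return left, right


def match_ssr_loci(
    loci_a: Sequence[SSRLocus],
    loci_b: Sequence[SSRLocus],
    ortholog_pairs: Sequence[OrthologPair],
    transcripts_a: Mapping[str, Transcript],
    transcripts_b: Mapping[str, Transcript],
    config: RunConfig | None = None,
) -> list[MatchedSSR]:
    """Match SSR loci across genotypes within ortholog pairs.

    For each ortholog pair, loci with identical canonical class are
    matched when both flank identities meet ``min_flank_identity`` over
    ``flank_window`` nt. Each locus is matched at most once; the best
    mean flank identity wins, ties going to the leftmost A-locus then
    leftmost B-locus. Matches with unit_diff 0 are included. Loci on
    transcripts absent from the ortholog set are counted and skipped.
    """
    config = config or RunConfig()
    by_ta: dict[str, list[SSRLocus]] = {}
    for l in loci_a:
        by_ta.setdefault(l.transcript_id, []).append(l)
    by_tb: dict[str, list[SSRLocus]] = {}
    for l in loci_b:
        by_tb.setdefault(l.transcript_id, []).append(l)

    ortho_a = {p.id_a for p in ortholog_pairs}
    ortho_b = {p.id_b for p in ortholog_pairs}
    unanchored_a = sum(len(v) for k, v in by_ta.items() if k not in ortho_a)
    unanchored_b = sum(len(v) for k, v in by_tb.items() if k not in ortho_b)

    matches: list[MatchedSSR] = []
    for pair in ortholog_pairs:
        ca = by_ta.get(pair.id_a, [])
        cb = by_tb.get(pair.id_b, [])
        if not ca or not cb:
            continue
        ta = transcripts_a[pair.id_a]
        tb = transcripts_b[pair.id_b]
        candidates: list[tuple[float, int, int, MatchedSSR]] = []
        for ia, la in enumerate(sorted(ca, key=lambda l: l.start)):
            for ib, lb in enumerate(sorted(cb, key=lambda l: l.start)):
                if la.canonical_class != lb.canonical_class:
                    continue
                left, right = _flank_identities(
                    ta, la, tb, lb, config.flank_window
                )
                if (
                    left < config.min_flank_identity
                    or right < config.min_flank_identity
                ):
                    continue
                m = MatchedSSR(la, lb, left, right)
                candidates.append((-(left + right) / 2.0, ia, ib, m))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, ia, ib, m in sorted(candidates, key=lambda t: t[:3]):
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            matches.append(m)
    log.info(
        "match_ssr_loci: %d matches; %d/%d loci on transcripts outside the"
        " ortholog set (A/B)",
        len(matches),
        unanchored_a,
        unanchored_b,
    )
    return matches


@dataclass(frozen=True)
class PolymorphismSummary:
    n_polymorphic: int
    unit_diff_histogram: dict[int, int]
    n_diff_ge3: int
    n_diff_ge10: int
    class_frequencies: dict[str, int]


def classify_polymorphic(
    matched: Iterable[MatchedSSR],
) -> tuple[list[PolymorphicSSR], PolymorphismSummary]:
    """Keep matches whose repeat-unit counts differ and summarize them.

    The summary reports the unit-difference histogram and the counts with
    a difference of at least three units (fragment-length difference of
    at least 6 nt) and at least ten units, both boundaries inclusive.
    """
    poly = [PolymorphicSSR(m) for m in matched if m.unit_diff >= 1]
    hist: dict[int, int] = {}
    classes: dict[str, int] = {}
    for p in poly:
        hist[p.unit_diff] = hist.get(p.unit_diff, 0) + 1
        classes[p.canonical_class] = classes.get(p.canonical_class, 0) + 1
    summary = PolymorphismSummary(
        n_polymorphic=len(poly),
        unit_diff_histogram=hist,
        n_diff_ge3=sum(1 for p in poly if p.unit_diff >= 3),
        n_diff_ge10=sum(1 for p in poly if p.unit_diff >= 10),
        class_frequencies=classes,
    )
    return poly, summary


def positional_distribution(
    loci: Sequence[SSRLocus],
    transcripts: Mapping[str, Transcript],
    n_bins: int = 10,
) -> list[int]:
    """Counts of locus midpoints by relative position along the transcript.

    Bins partition [0, 1]; a midpoint at exactly 1.0 falls in the last
    bin; counts sum to the number of loci.
    """
    counts = [0] * n_bins
    for l in loci:
        t = transcripts[l.transcript_id]
        rel = l.midpoint / t.length
        b = min(int(rel * n_bins), n_bins - 1)
        counts[b] += 1
    return counts


def annotate_markers(
    markers: Sequence[PolymorphicSSR],
    annotation_table: Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, int]]:
    """Attach annotation labels to markers in place; return per-key,
    per-label marker counts.

    Labels of either side's transcript are inherited; unmatched
    transcripts keep empty labels.
    """
    counts: dict[str, dict[str, int]] = {}
    for m in markers:
        labels: dict[str, str] = {}
        for tid in (m.match.locus_a.transcript_id, m.match.locus_b.transcript_id):
            for key, value in annotation_table.get(tid, {}).items():
                labels.setdefault(key, value)
        m.annotations.update(labels)
        for key, value in labels.items():
            counts.setdefault(key, {})
            counts[key][value] = counts[key].get(value, 0) + 1
    return counts
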