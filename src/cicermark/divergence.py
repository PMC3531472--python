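"""Ortholog detection and synonymous-rate divergence dating.

Orthologous transcript pairs between two genotypes are taken as
reciprocal best hits (RBH) from all-vs-all similarity searches
(E <= 1e-20, alignment length >= 300 nt). For each pair, translated
sequences are globally aligned, the alignment is threaded back onto
codons, and synonymous (Ks) and nonsynonymous (Ka) substitution rates
are computed by Nei-Gojobori (1986) counting with Jukes-Cantor
multiple-hit correction. The mode of the Ks distribution across pairs
dates the split: T = Ks_peak / r with the dicot synonymous rate
r = 1.5e-8 substitutions per synonymous site per year (a T = Ks/(2r)
convention is also available). Ka/Ks classifies selection per pair.
"""

from __future__ import annotations

import itertools
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core_io import HitRecord, RunConfig, Transcript, read_hits, write_fasta
from .ssr_mining import revcomp

log = logging.getLogger("cicermark")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_BASES = "ACGT"


class CodonAlignmentError(ValueError):
    """Raised when no reading frame yields a usable codon alignment."""


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float
    aln_length: int  # the smaller of the two directions' best-hit lengths


@dataclass
class KaKsResult:
    id_a: str
    id_b: str
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    ps: float
    pn: float
    Ks: Optional[float]  # None when saturated
    Ka: Optional[float]
    n_codons: int

    @property
    def omega(self) -> Optional[float]:
        if self.Ka is None or self.Ks is None or self.Ks == 0:
            return None
        return self.Ka / self.Ks

    @property
    def selection_class(self) -> str:
        w = self.omega
        if w is None:
            return "undefined"
        if w < 1:
            return "purifying"
        if w > 1:
            return "diversifying"
        return "neutral"


# ---------------------------------------------------------------------------
# reciprocal best hits


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest evalue, then highest bitscore, then
    lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    config: RunConfig | None = None,
) -> list[OrthologPair]:
    """Ortholog pairs by reciprocal best hit.

    (a, b) is kept iff b is a's best hit in hits_ab and a is b's best hit
    in hits_ba, both best-hit evalues <= ``rbh_e_max`` and both best-hit
    alignment lengths >= ``rbh_min_aln``.
    """
    config = config or RunConfig()
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs: list[OrthologPair] = []
    for a, hab in sorted(best_ab.items()):
        hba = best_ba.get(hab.subject_id)
        if hba is None or hba.subject_id != a:
            continue
        if hab.evalue > config.rbh_e_max or hba.evalue > config.rbh_e_max:
            continue
        if hab.aln_length < config.rbh_min_aln or hba.aln_length < config.rbh_min_aln:
            continue
        pairs.append(
            OrthologPair(
                id_a=a,
                id_b=hab.subject_id,
                evalue_ab=hab.evalue,
                evalue_ba=hba.evalue,
                aln_length=min(hab.aln_length, hba.aln_length),
            )
        )
    log.info(
        "RBH: %d/%d queries with best hits yielded %d reciprocal pairs",
        len(pairs),
        len(best_ab),
        len(pairs),
    )
    return pairs


def compute_hits(
    queries: Sequence[Transcript],
    subjects: Sequence[Transcript],
    e_max: float = 1e-5,
) -> list[HitRecord]:
    """All-vs-all nucleotide similarity hits via the blastn executable.

    Intended for small in-memory sets (simulated fixtures, toy inputs);
    production-scale searches should supply precomputed hit tables.
    """
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastn/makeblastdb not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        out = Path(tmp) / "hits.tsv"
        write_fasta(queries, qpath)
        write_fasta(subjects, spath)
        subprocess.run(
            ["makeblastdb", "-in", str(spath), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        subprocess.run(
            [
                "blastn",
                "-query",
                str(qpath),
                "-db",
                str(spath),
                "-outfmt",
                "6",
                "-evalue",
                str(e_max),
                "-out",
                str(out),
            ],
            check=True,
            capture_output=True,
        )
        return read_hits(out)


# ---------------------------------------------------------------------------
# codon alignment


def _frames(seq: str) -> list[str]:
    """The six reading frames (three offsets on each strand)."""
    rc = revcomp(seq)
    return [seq[i:] for i in range(3)] + [rc[i:] for i in range(3)]


def _translate(frame: str) -> str:
    """Codon-wise translation; stops as '*', ambiguous codons as 'X'."""
    aas = []
    for i in range(0, len(frame) - len(frame) % 3, 3):
        codon = frame[i : i + 3]
        if codon in STOP_CODONS:
            aas.append("*")
        elif codon in _CODON_TO_AA:
            aas.append(_CODON_TO_AA[codon])
        else:
            aas.append("X")
    return "".join(aas)


def _longest_orf_run(protein: str) -> int:
    return max((len(run) for run in protein.split("*")), default=0)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(
    seq_a: str, seq_b: str, min_codons: int = 100
) -> list[tuple[str, str]]:
    """Align two transcripts at the codon level through their proteins.

    The reading frame of A is the one (of six) with the longest stop-free
    codon run; B's frame is the one whose translation aligns best to A's.
    The global protein alignment is threaded back onto codons, and every
    column containing a gap, stop, or ambiguous codon in either sequence
    is dropped pairwise.
    """
    frames_a = _frames(seq_a)
    prots_a = [_translate(f) for f in frames_a]
    fa = max(range(6), key=lambda i: (_longest_orf_run(prots_a[i]), -i))
    prot_a = prots_a[fa]
    frame_a = frames_a[fa]

    aligner = _make_aligner()
    frames_b = _frames(seq_b)
    best = None
    for i, frame in enumerate(frames_b):
        prot = _translate(frame)
        if not prot:
            continue
        score = aligner.score(prot_a, prot)
        if best is None or score > best[0]:
            best = (score, i, prot)
    if best is None:
        raise CodonAlignmentError("no translatable frame in second sequence")
    _, fb, prot_b = best
    frame_b = frames_b[fb]

    alignment = aligner.align(prot_a, prot_b)[0]
    pairs: list[tuple[str, str]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            if prot_a[ia] in "*X" or prot_b[ib] in "*X":
                continue
            ca = frame_a[3 * ia : 3 * ia + 3]
            cb = frame_b[3 * ib : 3 * ib + 3]
            pairs.append((ca, cb))
    if len(pairs) < min_codons:
        raise CodonAlignmentError(
            f"only {len(pairs)} aligned codons (need {min_codons})"
        )
    return pairs


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) counting with Jukes-Cantor correction

_syn_sites_cache: dict[str, float] = {}


def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon: at each position, the fraction of
    the three single-base changes that preserve the amino acid (changes to
    stop codons count as nonsynonymous)."""
    cached = _syn_sites_cache.get(codon)
    if cached is not None:
        return cached
    aa = _CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TO_AA.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    _syn_sites_cache[codon] = s
    return s


def _path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over minimal mutational pathways; pathways passing through a
    stop codon are excluded (all pathways are used if every one is
    blocked, with steps into or out of stops counted nonsynonymous)."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                return None
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_positions)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all pathways blocked by stops: fall back to counting through them
        valid = []
        for order in itertools.permutations(diff_positions):
            sd = nd = 0.0
            cur = codon_a
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if (
                    cur not in STOP_CODONS
                    and nxt not in STOP_CODONS
                    and _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]
                ):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance -(3/4) ln(1 - 4p/3); None at or beyond saturation."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(
    codon_pairs: Sequence[tuple[str, str]], id_a: str = "a", id_b: str = "b"
) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks over ungapped aligned codon pairs.

    Site counts are averaged over the two sequences; multi-hit codons are
    resolved by averaging over minimal mutational pathways; proportions
    are Jukes-Cantor corrected. S + N equals three times the number of
    codons.
    """
    if not codon_pairs:
        raise ValueError("ng86_kaks needs at least one codon pair")
    S = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in aligned pair ({ca}, {cb})")
        S += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        sd, nd = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * len(codon_pairs) - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsResult(
        id_a=id_a,
        id_b=id_b,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        Ks=jukes_cantor(ps),
        Ka=jukes_cantor(pn),
        n_codons=len(codon_pairs),
    )


# ---------------------------------------------------------------------------
# Ks distribution, divergence time, selection


def ks_peak(
    ks_values: Iterable[Optional[float]], bin_width: float = 0.002
) -> Optional[float]:
    """Mode of the Ks distribution as a bin midpoint.

    Values are binned to the nearest multiple of ``bin_width`` (bin j
    covers ((j-1/2)w, (j+1/2)w]). The zero-Ks mass (non-detectable
    divergence) and undefined values are excluded; ties take the smaller
    Ks. Returns None when nothing remains.
    """
    counts: dict[int, int] = {}
    for ks in ks_values:
        if ks is None or ks <= 0:
            continue
        j = round(ks / bin_width)
        counts[j] = counts.get(j, 0) + 1
    if not counts:
        return None
    peak_bin = min(counts, key=lambda j: (-counts[j], j))
    return peak_bin * bin_width


def divergence_time(
    ks: float, config: RunConfig | None = None
) -> float:
    """Divergence time in years from a synonymous rate peak.

    ``ks_over_r``: T = Ks / r (each lineage accumulating at rate r toward
    the observed pairwise divergence); ``ks_over_2r``: T = Ks / (2r).
    """
    config = config or RunConfig()
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    r = config.substitution_rate
    if config.time_convention == "ks_over_r":
        return ks / r
    if config.time_convention == "ks_over_2r":
        return ks / (2.0 * r)
    raise ValueError(f"unknown time convention {config.time_convention!r}")


@dataclass(frozen=True)
class SelectionSummary:
    n_in_window: int
    n_excluded: int
    mean_omega: Optional[float]
    n_purifying: int
    n_diversifying: int
    n_neutral: int


def selection_summary(
    results: Iterable[KaKsResult], config: RunConfig | None = None
) -> SelectionSummary:
    """Mean Ka/Ks and selection-class counts within 0 < Ks <= window max.

    Pairs with Ks outside the window or with undefined omega are excluded
    and tallied.
    """
    config = config or RunConfig()
    omegas: list[float] = []
    excluded = 0
    for r in results:
        w = r.omega
        if r.Ks is None or r.Ks <= 0 or r.Ks > config.ks_window_max or w is None:
            excluded += 1
            continue
        omegas.append(w)
    return SelectionSummary(
        n_in_window=len(omegas),
        n_excluded=excluded,
        mean_omega=sum(omegas) / len(omegas) if omegas else None,
        n_purifying=sum(1 for w in omegas if w < 1),
        n_diversifying=sum(1 for w in omegas if w > 1),
        n_neutral=sum(1 for w in omegas if w == 1),
    )
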