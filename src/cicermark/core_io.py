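"""Readers and writers for the flat-file formats the pipeline touches.

Three external formats are supported, all plain text:

* FASTA transcript sets (via :mod:`Bio.SeqIO`);
* 12-column tab-separated similarity hits (the ``-outfmt 6`` dialect:
  qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
  sstart, send, evalue, bitscore);
* a dual-genotype pileup TSV with one column of the transcript per line:
  transcript_id, pos (1-based), basesA, qualsA, basesB, qualsB,
  indelA, indelB — where quals are comma-separated Phred integers and
  indelA/indelB count reads reporting an indel touching the column.

All coordinates in files and reports are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("cicermark")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A line or record violating one of the declared file dialects."""


@dataclass
class Transcript:
    """One assembled transcript: id, uppercase DNA sequence, optional labels.

    ``labels`` carries annotation joins such as ``tissue`` (tissue-specific
    expression) or ``tf_family`` (transcription-factor family).
    """

    id: str
    seq: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.id:
            raise FormatError("transcript id must be non-empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"transcript {self.id!r}: invalid bases {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (single HSP) in the 12-column dialect."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def subject_reversed(self) -> bool:
        """True for minus-strand hits (sstart > send in the raw file)."""
        return self.sstart > self.send

    def subject_interval(self) -> tuple[int, int]:
        """Subject-coordinate interval normalized to (low, high), 1-based."""
        return (min(self.sstart, self.send), max(self.sstart, self.send))


@dataclass
class PileupColumn:
    """Per-site read evidence for two genotypes at one transcript position."""

    transcript_id: str
    pos: int
    bases_a: str
    quals_a: list[int]
    bases_b: str
    quals_b: list[int]
    indel_a: int = 0
    indel_b: int = 0

    def __post_init__(self) -> None:
        if len(self.bases_a) != len(self.quals_a) or len(self.bases_b) != len(
            self.quals_b
        ):
            raise FormatError(
                f"{self.transcript_id}:{self.pos}: base/quality length mismatch"
            )
        if any(q < 0 for q in self.quals_a) or any(q < 0 for q in self.quals_b):
            raise FormatError(
                f"{self.transcript_id}:{self.pos}: negative Phred quality"
            )

    @property
    def has_indel(self) -> bool:
        return self.indel_a > 0 or self.indel_b > 0


@dataclass
class RunConfig:
    """All tunables of the pipeline, with their default operating points.

    SSR thresholds follow the tract-length minima used for EST-SSR
    surveys (dinucleotide >=12 nt, tri- to hexa-nucleotide >=15 nt);
    SNP filters follow the fixed-difference filter chain (posterior,
    per-site mean Phred, depth, consensus ratio, cluster window, indel
    flank); ortholog detection uses reciprocal best hits at
    E <= 1e-20 and alignment length >= 300 nt; divergence time uses the
    dicot synonymous substitution rate 1.5e-8 per site per year.
    """

    # SSR mining
    ssr_min_len: dict[int, int] = field(
        default_factory=lambda: {2: 12, 3: 15, 4: 15, 5: 15, 6: 15}
    )
    compound_max_gap: int = 100
    primer_flank_min: int = 100
    primer_len_min: int = 18
    primer_len_max: int = 24
    primer_gc_min: float = 40.0
    primer_gc_max: float = 60.0
    primer_tm_min: float = 55.0
    primer_tm_max: float = 62.0
    primer_max_mono_run: int = 4
    # SSR polymorphism
    flank_window: int = 20
    min_flank_identity: float = 90.0
    n_position_bins: int = 10
    # SNP discovery
    snp_min_posterior: float = 0.95
    snp_min_mean_qual: float = 30.0
    snp_min_depth: int = 3
    snp_cluster_window: int = 10
    snp_cluster_count: int = 3
    snp_indel_flank: int = 3
    # divergence
    rbh_e_max: float = 1e-20
    rbh_min_aln: int = 300
    min_aligned_codons: int = 100
    ks_bin_width: float = 0.002
    ks_window_max: float = 2.0
    substitution_rate: float = 1.5e-8
    time_convention: str = "ks_over_r"  # or "ks_over_2r"
    # allele-specific assay
    allele_primer_len: int = 20
    outer_primer_offset_min: int = 100
    outer_primer_offset_max: int = 150
    min_product_diff: int = 50
    # misc
    seed: int = 0

    def min_unit_count(self, k: int) -> int:
        """Smallest number of complete units meeting the length minimum."""
        min_len = self.ssr_min_len[k]
        return -(-min_len // k)  # ceil

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, dict):
                value = ",".join(f"{k}:{v}" for k, v in sorted(value.items()))
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, dict):
                kwargs[key] = {
                    int(kv.split(":")[0]): int(kv.split(":")[1])
                    for kv in value.split(",")
                }
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA file into an ordered list of :class:`Transcript`.

    The id is the header token before the first whitespace; sequences are
    uppercased and wrapped lines concatenated. Duplicate ids are an error.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate transcript id {record.id!r} in {path}")
        seen.add(record.id)
        transcripts.append(Transcript(id=record.id, seq=str(record.seq)))
    if not transcripts:
        log.warning("no FASTA records in %s", path)
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# similarity hits


def _parse_hit_line(line: str, lineno: int, path: str | Path) -> HitRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 12:
        raise FormatError(
            f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
        )
    try:
        return HitRecord(
            query_id=parts[0],
            subject_id=parts[1],
            pct_identity=float(parts[2]),
            aln_length=int(parts[3]),
            mismatches=int(parts[4]),
            gap_opens=int(parts[5]),
            qstart=int(parts[6]),
            qend=int(parts[7]),
            sstart=int(parts[8]),
            send=int(parts[9]),
            evalue=float(parts[10]),
            bitscore=float(parts[11]),
        )
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read 12-column tabular similarity hits, preserving input order."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            hit = _parse_hit_line(line, lineno, path)
            if hit.aln_length < 1 or hit.evalue < 0:
                raise FormatError(
                    f"{path}:{lineno}: aln_length must be >=1 and evalue >=0"
                )
            if hit.qstart > hit.qend:
                raise FormatError(
                    f"{path}:{lineno}: qstart > qend (plus-strand query expected)"
                )
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# pileups


def _parse_quals(text: str) -> list[int]:
    if not text:
        return []
    return [int(q) for q in text.split(",")]


def read_pileup(path: str | Path) -> list[PileupColumn]:
    """Read the dual-genotype pileup TSV; one :class:`PileupColumn` per line."""
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise FormatError(
                    f"{path}:{lineno}: expected 8 columns, got {len(parts)}"
                )
            tid, pos, ba, qa, bb, qb, ia, ib = parts
            try:
                col = PileupColumn(
                    transcript_id=tid,
                    pos=int(pos),
                    bases_a=ba.upper(),
                    quals_a=_parse_quals(qa),
                    bases_b=bb.upper(),
                    quals_b=_parse_quals(qb),
                    indel_a=int(ia),
                    indel_b=int(ib),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            columns.append(col)
    return columns


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in columns:
            fh.write(
                "\t".join(
                    (
                        c.transcript_id,
                        str(c.pos),
                        c.bases_a,
                        ",".join(str(q) for q in c.quals_a),
                        c.bases_b,
                        ",".join(str(q) for q in c.quals_b),
                        str(c.indel_a),
                        str(c.indel_b),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# small TSV helpers (annotation tables, generic reports)


def read_annotation_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a transcript annotation TSV: transcript_id, key, value."""
    table: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (id, key, value)"
                )
            tid, key, value = parts
            table.setdefault(tid, {})[key] = value
    return table


def write_tsv(
    path: str | Path, header: list[str], rows: Iterable[Iterable]
) -> None:
    """Write a header row plus data rows as plain TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [l.split("\t") for l in lines[1:]]


def transcript_index(transcripts: Iterable[Transcript]) -> dict[str, Transcript]:
    index: dict[str, Transcript] = {}
    for t in transcripts:
        if t.id in index:
            raise FormatError(f"duplicate transcript id {t.id!r}")
        index[t.id] = t
    return index
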