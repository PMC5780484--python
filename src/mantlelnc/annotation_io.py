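"""Genomic annotation I/O and interval arithmetic.

All coordinates are held internally as 0-based half-open intervals.
GTF input/output converts to and from the format's 1-based inclusive
convention at the file boundary, so interval arithmetic inside the
package is unambiguous.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: reference biotypes treated as housekeeping non-coding RNA by the
#: filter cascade (removal list; anything else is left alone)
HOUSEKEEPING_BIOTYPES = frozenset(
    {"tRNA", "rRNA", "snoRNA", "snRNA", "pre_miRNA", "pseudogene"}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Invalid annotation content (bad coordinates, inconsistent records)."""


class GTFParseError(AnnotationError):
    """Malformed GTF input; the message names the offending line number."""


class SequenceLookupError(KeyError):
    """A requested chromosome or region is absent from the sequence store."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise AnnotationError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases between two intervals on the same chromosome; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise AnnotationError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript — the unit flowing through the
    filter cascade.

    Exons are sorted, pairwise disjoint ``GenomicInterval`` objects sharing
    one chromosome and strand.  ``biotype`` is a free label defaulting to
    ``"unknown"``; only the labels in :data:`HOUSEKEEPING_BIOTYPES` plus
    ``"protein_coding"`` carry meaning downstream.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span multiple chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced length: the sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


class AnnotationSet:
    """A queryable collection of transcripts grouped into genes.

    Maintains per-chromosome interval trees over transcript spans so
    overlap queries are O(log n + hits).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = defaultdict(list)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        self.genes[t.gene_id].append(t.transcript_id)
        self._trees[t.chrom].addi(t.span.start, t.span.end, t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose spans overlap [start, end) on `chrom`."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.transcripts[iv.data] for iv in tree.overlap(start, end)]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        members = [self.transcripts[tid] for tid in self.genes[gene_id]]
        if not members:
            raise AnnotationError(f"gene {gene_id} has no transcripts")
        start = min(t.span.start for t in members)
        end = max(t.span.end for t in members)
        return GenomicInterval(members[0].chrom, start, end, members[0].strand)

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self.transcripts[tid] for tid in transcript_ids)

    def by_biotype(self, *biotypes: str) -> list[TranscriptModel]:
        wanted = set(biotypes)
        return [t for t in self if t.biotype in wanted]


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(path: str | Path) -> AnnotationSet:
    """Parse exon features from a GTF file into an :class:`AnnotationSet`.

    1-based inclusive GTF coordinates become internal 0-based half-open
    intervals.  Biotype is taken from the ``transcript_biotype`` (or
    ``gene_biotype``) attribute when present, else ``"unknown"`` — never
    silently ``protein_coding``.  Malformed lines raise
    :class:`GTFParseError` naming the line number.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, biotype)
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise GTFParseError(f"line {lineno}: end {end1} < start {start1}")
            if strand not in STRANDS:
                strand = "."
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            gid = attributes.get("gene_id")
            if tid is None or gid is None:
                raise GTFParseError(
                    f"line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            biotype = attributes.get(
                "transcript_biotype", attributes.get("gene_biotype", "unknown")
            )
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons_by_tx[tid].append(interval)
            if tid in meta and meta[tid][0] != gid:
                raise GTFParseError(
                    f"line {lineno}: transcript {tid} assigned to two genes"
                )
            meta.setdefault(tid, (gid, biotype))
    if n_lines == 0:
        warnings.warn(f"{path}: empty GTF, returning empty annotation set")
    aset = AnnotationSet()
    for tid, exons in exons_by_tx.items():
        gid, biotype = meta[tid]
        aset.add(TranscriptModel(tid, gid, exons, biotype=biotype))
    return aset


def write_gtf(aset: AnnotationSet, path: str | Path, extra_attrs: Mapping[str, Mapping[str, str]] | None = None) -> None:
    """Write exon records back out in GTF (1-based inclusive) coordinates."""
    with open(path, "w") as fh:
        for t in sorted(aset, key=lambda t: (t.chrom, t.span.start, t.transcript_id)):
            attrs = {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "transcript_biotype": t.biotype,
            }
            if extra_attrs and t.transcript_id in extra_attrs:
                attrs.update(extra_attrs[t.transcript_id])
            attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tmantlelnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attr_str}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Transcript-level operations

def transcript_length(t: TranscriptModel) -> int:
    """Spliced length in nucleotides (sum of exon widths)."""
    return t.length


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenate exon sequences 5'→3'; minus-strand transcripts are
    reverse-complemented so the returned string reads in transcription order."""
    try:
        chrom_seq = genome[t.chrom]
    except KeyError:
        raise SequenceLookupError(f"chromosome {t.chrom!r} not in genome") from None
    if t.span.end > len(chrom_seq):
        raise AnnotationError(
            f"{t.transcript_id}: span end {t.span.end} exceeds chromosome "
            f"length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def nearest_transcript_distance(
    t: TranscriptModel, others: AnnotationSet | Iterable[TranscriptModel]
) -> float:
    """Minimum span-to-span gap (bases) between ``t`` and any other transcript
    on the same chromosome, strand-agnostic.  Overlap → 0.  No neighbour on
    the chromosome → ``math.inf``.
    """
    span = t.span
    best = math.inf
    for other in others:
        if other.transcript_id == t.transcript_id or other.chrom != t.chrom:
            continue
        best = min(best, span.gap_to(other.span))
        if best == 0:
            break
    return best


# ---------------------------------------------------------------------------
# Repeat annotations

@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker hit (or BED repeat interval) in genome coordinates."""

    interval: GenomicInterval
    repeat_class: str
    repeat_name: str = ""


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Read RepeatMasker ``.out`` tabular output, or a BED4+ fallback.

    ``.out`` rows are whitespace-separated with 1-based inclusive query
    coordinates; BED rows are already 0-based half-open.  The dialect is
    detected per file from the first data row.
    """
    features: list[RepeatFeature] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    data = [
        (i + 1, ln)
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().startswith(("SW", "score", "#", "track"))
    ]
    for lineno, line in data:
        cols = line.split()
        if _is_rm_out_row(cols):
            # score div del ins query qbegin qend (left) strand name class ...
            chrom, qbegin, qend = cols[4], int(cols[5]), int(cols[6])
            strand = "+" if cols[8] == "+" else "-"
            name, rclass = cols[9], cols[10]
            features.append(
                RepeatFeature(
                    GenomicInterval(chrom, qbegin - 1, qend, strand),
                    repeat_class=rclass,
                    repeat_name=name,
                )
            )
        elif len(cols) >= 4:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            rclass = cols[3]
            name = cols[4] if len(cols) >= 5 else ""
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            features.append(
                RepeatFeature(
                    GenomicInterval(chrom, start, end, strand),
                    repeat_class=rclass,
                    repeat_name=name,
                )
            )
        else:
            raise AnnotationError(
                f"{path} line {lineno}: unrecognized repeat record "
                f"({len(cols)} columns)"
            )
    return features


def _is_rm_out_row(cols: list[str]) -> bool:
    if len(cols) < 11:
        return False
    try:
        int(cols[0])
        float(cols[1])
        int(cols[5])
        int(cols[6])
    except ValueError:
        return False
    return cols[8] in ("+", "C")


def write_repeats_bed(features: Iterable[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.repeat_class}\t"
                f"{f.repeat_name}\t{iv.strand if iv.strand != '.' else '.'}\n"
            )
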