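"""Positional classification and the eight-step lncRNA filter cascade.

Assembled transcripts are classified against the reference annotation
(known-mRNA match, housekeeping ncRNA, antisense-exonic, intronic,
intergenic, other overlap), then pushed through the cascade in its fixed
order:

  (i)    drop single-exon transcripts within 500 bp of another transcript
  (ii)   drop transcripts shorter than 200 nt (spliced)
  (iii)  expression floor: single-exon FPKM ≥ 2, multi-exon FPKM ≥ 0.5
  (iv)   drop housekeeping-ncRNA overlaps (tRNA/rRNA/snoRNA/snRNA/
         pre-miRNA/pseudogene)
  (v)    drop known-mRNA matches (plus any external homology-hit table)
  (vi)   keep only the three positional subtypes (lincRNA/intronic/antisense)
  (vii)  keep only consensus-noncoding transcripts
  (viii) require detection in at least 3 of the libraries

The survivors form the lncRNA catalog with per-step audit counts and
locus grouping by the assembler's gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import (
    HOUSEKEEPING_BIOTYPES,
    AnnotationSet,
    TranscriptModel,
    nearest_transcript_distance,
    spliced_sequence,
)
from .coding_potential import CodingAssessment, HexamerModel, assess


class PositionalClass(Enum):
    KNOWN_MRNA_MATCH = "known_mRNA_match"
    HOUSEKEEPING_NC = "housekeeping_nc"
    ANTISENSE_EXONIC = "antisense_exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER_OVERLAP = "other_overlap"


#: positional class → catalog subtype label (anything else is discarded)
SUBTYPE_OF_CLASS = {
    PositionalClass.INTERGENIC: "lincRNA",
    PositionalClass.INTRONIC: "intronic",
    PositionalClass.ANTISENSE_EXONIC: "antisense",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Tunable thresholds of the cascade; defaults are the published rules
    where a rule is stated, field conventions where it is not."""

    single_exon_distance: int = 500       # step (i), bp, removal at ≤
    min_length: int = 200                 # step (ii), nt, removal at <
    single_min_fpkm: float = 2.0          # step (iii), ≥ keeps
    multi_min_fpkm: float = 0.5           # step (iii), ≥ keeps
    fpkm_aggregate: str = "max"           # max | mean | all (across samples)
    known_overlap_frac: float = 0.5       # step (v) same-strand overlap rule
    orf_cutoff: int = 300                 # step (vii) built-in assessor
    fickett_cutoff: float = 0.95          # step (vii) built-in assessor
    six_frame: bool = False
    min_libraries: int = 3                # step (viii), ≥ keeps
    detect_min_fpkm: float = 0.0          # step (viii), detection at >


@dataclass
class AuditEntry:
    step: str
    n_in: int
    n_out: int


@dataclass
class LncRNACatalog:
    """Retained lncRNAs with subtype labels, audit trail, and loci.

    Invariants: audit counts are non-increasing; subtype counts sum to the
    retained count; every retained transcript is ≥ 200 nt, consensus
    noncoding, and detected in ≥ 3 libraries.
    """

    subtypes: dict[str, str]                      # transcript_id -> subtype
    models: dict[str, TranscriptModel]
    audit: list[AuditEntry]
    loci: dict[str, list[str]] = field(default_factory=dict)
    assessments: dict[str, CodingAssessment] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subtypes)

    def subtype_counts(self) -> dict[str, int]:
        counts = {"lincRNA": 0, "intronic": 0, "antisense": 0}
        for s in self.subtypes.values():
            counts[s] += 1
        return counts

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.step, a.n_in, a.n_out) for a in self.audit],
            columns=["step", "n_in", "n_out"],
        )


# ---------------------------------------------------------------------------
# Positional classification

def _same_strand_exon_overlap(t: TranscriptModel, other: TranscriptModel) -> int:
    if t.strand != other.strand or t.chrom != other.chrom:
        return 0
    total = 0
    for e in t.exons:
        for oe in other.exons:
            total += e.overlap_length(oe)
    return total


def _opposite_strand_exon_overlap(t: TranscriptModel, other: TranscriptModel) -> bool:
    if t.chrom != other.chrom:
        return False
    if "." in (t.strand, other.strand) or t.strand == other.strand:
        return False
    return any(e.overlap_length(oe) > 0 for e in t.exons for oe in other.exons)


def _any_strand_exon_overlap(t: TranscriptModel, other: TranscriptModel) -> bool:
    return any(e.overlap_length(oe) > 0 for e in t.exons for oe in other.exons)


def classify_position(
    t: TranscriptModel,
    ref: AnnotationSet,
    known_overlap_frac: float = 0.5,
) -> PositionalClass:
    """Assign exactly one positional class relative to the reference.

    Precedence: known-mRNA match (same-strand exon-chain equality, or
    same-strand exonic overlap covering ≥ ``known_overlap_frac`` of the
    shorter transcript) → housekeeping overlap → antisense-exonic (≥1 exon
    overlapping a coding exon on the opposite strand) → intronic (span
    inside a coding gene's span with no exon–exon overlap) → intergenic
    (no overlap with any protein-coding gene) → other overlap.
    """
    span = t.span
    nearby = ref.overlapping(t.chrom, span.start, span.end)
    coding_nearby = [r for r in nearby if r.biotype == "protein_coding"]

    for r in coding_nearby:
        if t.strand == r.strand and t.exon_chain() == r.exon_chain():
            return PositionalClass.KNOWN_MRNA_MATCH
        ov = _same_strand_exon_overlap(t, r)
        if ov and ov >= known_overlap_frac * min(t.length, r.length):
            return PositionalClass.KNOWN_MRNA_MATCH

    if any(r.biotype in HOUSEKEEPING_BIOTYPES for r in nearby):
        return PositionalClass.HOUSEKEEPING_NC

    if any(_opposite_strand_exon_overlap(t, r) for r in coding_nearby):
        return PositionalClass.ANTISENSE_EXONIC

    # genes (not just transcripts) whose span overlaps t
    coding_genes = {r.gene_id for r in coding_nearby}
    for gene_id in sorted(coding_genes):
        gspan = ref.gene_span(gene_id)
        members = [ref.get(tid) for tid in ref.genes[gene_id]]
        if gspan.start <= span.start and span.end <= gspan.end:
            if not any(_any_strand_exon_overlap(t, m) for m in members):
                return PositionalClass.INTRONIC

    if not coding_genes:
        return PositionalClass.INTERGENIC
    return PositionalClass.OTHER_OVERLAP


def classify_all(
    ts: Iterable[TranscriptModel],
    ref: AnnotationSet,
    known_overlap_frac: float = 0.5,
) -> dict[str, PositionalClass]:
    return {
        t.transcript_id: classify_position(t, ref, known_overlap_frac) for t in ts
    }


# ---------------------------------------------------------------------------
# Cascade steps.  Each takes and returns lists of TranscriptModel so the
# survivors of one step feed the next; the audit is assembled by the driver.

def step1_single_exon_distance(
    ts: Sequence[TranscriptModel],
    all_transcripts: AnnotationSet,
    cutoff: int = 500,
) -> list[TranscriptModel]:
    """Drop single-exon transcripts whose nearest neighbour (span gap,
    strand-agnostic, within the assembled set) is ≤ ``cutoff`` bp; these are
    likely fragmented exon extensions.  Multi-exon transcripts always pass."""
    out = []
    for t in ts:
        if t.n_exons > 1:
            out.append(t)
            continue
        d = nearest_transcript_distance(t, all_transcripts)
        if d > cutoff:
            out.append(t)
    return out


def step2_length(
    ts: Sequence[TranscriptModel], min_len: int = 200
) -> list[TranscriptModel]:
    """Drop transcripts with spliced length < ``min_len`` nt."""
    return [t for t in ts if t.length >= min_len]


def step3_expression(
    ts: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    single_min: float = 2.0,
    multi_min: float = 0.5,
    aggregate: str = "max",
) -> list[TranscriptModel]:
    """Expression floor on the per-transcript FPKM aggregate across samples
    (default: max).  Single-exon transcripts need ≥ ``single_min``,
    multi-exon ≥ ``multi_min``."""
    if aggregate not in ("max", "mean", "all"):
        raise PipelineError(f"unknown FPKM aggregate {aggregate!r}")
    out = []
    for t in ts:
        if t.transcript_id not in fpkm.index:
            raise PipelineError(
                f"step3: no expression row for {t.transcript_id}"
            )
        row = fpkm.loc[t.transcript_id]
        if aggregate == "max":
            value = float(row.max())
        elif aggregate == "mean":
            value = float(row.mean())
        else:
            value = float(row.min())
        floor = single_min if t.n_exons == 1 else multi_min
        if value >= floor:
            out.append(t)
    return out


def step4_housekeeping(
    ts: Sequence[TranscriptModel],
    classes: Mapping[str, PositionalClass],
) -> list[TranscriptModel]:
    """Drop transcripts overlapping annotated housekeeping ncRNA
    (tRNA, rRNA, snoRNA, snRNA, pre-miRNA, pseudogene)."""
    return [
        t for t in ts
        if classes[t.transcript_id] is not PositionalClass.HOUSEKEEPING_NC
    ]


def step5_known_mRNA(
    ts: Sequence[TranscriptModel],
    classes: Mapping[str, PositionalClass],
    external_hits: set[str] | None = None,
) -> list[TranscriptModel]:
    """Drop known-mRNA matches; an external homology-hit table (ids with a
    known-mRNA BLAST hit) removes additional transcripts."""
    hits = external_hits or set()
    return [
        t for t in ts
        if classes[t.transcript_id] is not PositionalClass.KNOWN_MRNA_MATCH
        and t.transcript_id not in hits
    ]


def step6_subtype(
    ts: Sequence[TranscriptModel],
    classes: Mapping[str, PositionalClass],
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Keep the three positional subtypes, labelling each survivor;
    transcripts with other same-strand overlaps are discarded."""
    out = []
    labels: dict[str, str] = {}
    for t in ts:
        subtype = SUBTYPE_OF_CLASS.get(classes[t.transcript_id])
        if subtype is not None:
            out.append(t)
            labels[t.transcript_id] = subtype
    return out, labels


def step7_coding(
    ts: Sequence[TranscriptModel],
    assessments: Mapping[str, CodingAssessment],
) -> list[TranscriptModel]:
    """Keep only transcripts no assessor calls coding."""
    out = []
    for t in ts:
        if t.transcript_id not in assessments:
            raise PipelineError(f"step7: no coding assessment for {t.transcript_id}")
        if assessments[t.transcript_id].consensus_noncoding:
            out.append(t)
    return out


def step8_detection(
    ts: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    min_libraries: int = 3,
    detect_min: float = 0.0,
) -> list[TranscriptModel]:
    """Keep transcripts with FPKM > ``detect_min`` in ≥ ``min_libraries``
    samples."""
    out = []
    for t in ts:
        if t.transcript_id not in fpkm.index:
            raise PipelineError(f"step8: no expression row for {t.transcript_id}")
        detected = int((fpkm.loc[t.transcript_id] > detect_min).sum())
        if detected >= min_libraries:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Driver

def run_pipeline(
    assembled: AnnotationSet,
    ref: AnnotationSet,
    genome: Mapping[str, str],
    fpkm: pd.DataFrame,
    hexamer_model: HexamerModel,
    config: PipelineConfig | None = None,
    external_verdicts: Mapping[str, Mapping[str, str]] | None = None,
    external_blast_hits: set[str] | None = None,
) -> LncRNACatalog:
    """Run the cascade in its fixed order (i)→(viii) and assemble the catalog.

    Candidates are every assembled transcript; coding assessments are
    computed (on spliced sequences) only for the transcripts that reach the
    coding-potential step.  Loci group retained transcripts by the
    assembler's gene id.
    """
    cfg = config or PipelineConfig()
    audit: list[AuditEntry] = []
    current: list[TranscriptModel] = sorted(
        assembled, key=lambda t: t.transcript_id
    )

    def record(
        step: str,
        before: list[TranscriptModel],
        survivors: list[TranscriptModel],
    ) -> list[TranscriptModel]:
        audit.append(AuditEntry(step, len(before), len(survivors)))
        return survivors

    current = record(
        "i_single_exon_distance",
        current,
        step1_single_exon_distance(current, assembled, cfg.single_exon_distance),
    )
    current = record("ii_min_length", current, step2_length(current, cfg.min_length))
    current = record(
        "iii_expression",
        current,
        step3_expression(
            current, fpkm, cfg.single_min_fpkm, cfg.multi_min_fpkm, cfg.fpkm_aggregate
        ),
    )
    classes = classify_all(current, ref, cfg.known_overlap_frac)
    current = record("iv_housekeeping", current, step4_housekeeping(current, classes))
    current = record(
        "v_known_mrna", current, step5_known_mRNA(current, classes, external_blast_hits)
    )
    survivors, labels = step6_subtype(current, classes)
    current = record("vi_subtype", current, survivors)

    assessments: dict[str, CodingAssessment] = {}
    for t in current:
        seq = spliced_sequence(t, genome)
        assessments[t.transcript_id] = assess(
            t.transcript_id,
            seq,
            hexamer_model,
            external_verdicts,
            orf_cutoff=cfg.orf_cutoff,
            fickett_cutoff=cfg.fickett_cutoff,
            six_frame=cfg.six_frame,
        )
    current = record(
        "vii_coding_potential", current, step7_coding(current, assessments)
    )
    current = record(
        "viii_detection",
        current,
        step8_detection(current, fpkm, cfg.min_libraries, cfg.detect_min_fpkm),
    )

    retained = {t.transcript_id: labels[t.transcript_id] for t in current}
    loci: dict[str, list[str]] = {}
    for t in current:
        loci.setdefault(t.gene_id, []).append(t.transcript_id)
    return LncRNACatalog(
        subtypes=retained,
        models={t.transcript_id: t for t in current},
        audit=audit,
        loci=loci,
        assessments={tid: assessments[tid] for tid in retained},
    )
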