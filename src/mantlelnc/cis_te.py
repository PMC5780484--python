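"""Cis-proximal coding-gene search and transposable-element overlap.

A lncRNA's candidate cis targets are all protein-coding genes whose
genomic span lies within a fixed window (default 100 kb, inclusive)
up- or downstream of the lncRNA span.  TE overlap is counted at the
exon level by default: a transcript carries a TE when at least one
repeat interval overlaps at least one of its exons by ≥1 bp.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
)
from .enrichment_report import rate

DEFAULT_CIS_WINDOW = 100_000


@dataclass
class CisPair:
    """One (lncRNA, coding gene) proximity pair.

    ``distance`` is the span-to-span gap in bases (0 when the spans
    overlap); ``relation`` is resolved on the lncRNA's strand.  When the
    lncRNA strand is unknown, plus-strand orientation is assumed and
    ``strand_assumed`` is set.
    """

    lncRNA_id: str
    gene_id: str
    distance: int
    relation: str  # upstream | downstream | overlapping
    strand_assumed: bool = False
    both_de: dict[tuple[str, str], bool] | None = None


class GeneIndex:
    """Interval index over protein-coding gene spans."""

    def __init__(self, ref: AnnotationSet, biotype: str = "protein_coding"):
        self.spans: dict[str, GenomicInterval] = {}
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gene_id, tids in ref.genes.items():
            members = [ref.get(t) for t in tids if ref.get(t).biotype == biotype]
            if not members:
                continue
            start = min(t.span.start for t in members)
            end = max(t.span.end for t in members)
            span = GenomicInterval(members[0].chrom, start, end, members[0].strand)
            self.spans[gene_id] = span
            self._trees[span.chrom].addi(start, end, gene_id)

    def near(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def find_cis_targets(
    lnc: TranscriptModel,
    genes: GeneIndex,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[CisPair]:
    """All coding genes with span gap ≤ ``window`` (inclusive) of the lncRNA."""
    span = lnc.span
    # query 1 bp wider than the window on each side: half-open tree overlap
    # would otherwise drop genes whose gap is exactly the window
    hits = genes.near(span.chrom, max(0, span.start - window - 1), span.end + window + 1)
    pairs = []
    for gene_id in sorted(hits):
        gspan = genes.spans[gene_id]
        gap = span.gap_to(gspan)
        if gap > window:
            continue
        strand_assumed = lnc.strand == "."
        strand = "+" if strand_assumed else lnc.strand
        if gap == 0 and span.overlaps(gspan):
            relation = "overlapping"
        elif gspan.end <= span.start:
            relation = "upstream" if strand == "+" else "downstream"
        else:
            relation = "downstream" if strand == "+" else "upstream"
        pairs.append(
            CisPair(
                lncRNA_id=lnc.transcript_id,
                gene_id=gene_id,
                distance=gap,
                relation=relation,
                strand_assumed=strand_assumed,
            )
        )
    return pairs


def pair_de(
    cis_pairs: Iterable[CisPair],
    lnc_de: Mapping[tuple[str, str], set[str]],
    gene_de: Mapping[tuple[str, str], set[str]],
) -> list[CisPair]:
    """Flag each cis pair per sample pair when *both* members are significant.

    ``lnc_de`` / ``gene_de`` map sample pairs to the ids called significant
    in that comparison (lncRNA transcript ids and gene ids respectively).
    With no DE calls supplied, all flags are False.
    """
    sample_pairs = sorted(set(lnc_de) | set(gene_de))
    flagged = []
    for cp in cis_pairs:
        flags = {
            sp: cp.lncRNA_id in lnc_de.get(sp, set())
            and cp.gene_id in gene_de.get(sp, set())
            for sp in sample_pairs
        }
        flagged.append(
            CisPair(
                lncRNA_id=cp.lncRNA_id,
                gene_id=cp.gene_id,
                distance=cp.distance,
                relation=cp.relation,
                strand_assumed=cp.strand_assumed,
                both_de=flags,
            )
        )
    return flagged


def cis_pairs_table(pairs: Iterable[CisPair]) -> pd.DataFrame:
    rows = []
    for cp in pairs:
        row = {
            "lncRNA_id": cp.lncRNA_id,
            "gene_id": cp.gene_id,
            "distance": cp.distance,
            "relation": cp.relation,
        }
        if cp.both_de:
            for (a, b), flag in cp.both_de.items():
                row[f"both_de_{a}_{b}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transposable-element overlap

def te_overlap(
    classes: Mapping[str, Iterable[TranscriptModel]],
    repeats: Iterable[RepeatFeature],
    *,
    exon_level: bool = True,
) -> pd.DataFrame:
    """Per-class TE overlap summary.

    A transcript "has TE" iff ≥1 repeat interval overlaps ≥1 of its exons
    by ≥1 bp (``exon_level=False`` relaxes this to the unspliced span).
    ``te_hits_total`` counts overlapping (transcript, repeat) pairs, so one
    transcript crossed by three repeats contributes three hits.  Percentages
    are half-up rounded to 2 decimals.  Also tallies hits per repeat class.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rf in repeats:
        trees[rf.interval.chrom].addi(rf.interval.start, rf.interval.end, rf)
    rows = []
    per_repeat_class: dict[str, dict[str, int]] = {}
    for label, transcripts in classes.items():
        total = 0
        with_te = 0
        hits = 0
        class_hits: dict[str, int] = defaultdict(int)
        for t in transcripts:
            total += 1
            tree = trees.get(t.chrom)
            if tree is None:
                continue
            regions = t.exons if exon_level else [t.span]
            seen: set[RepeatFeature] = set()
            for region in regions:
                for iv in tree.overlap(region.start, region.end):
                    seen.add(iv.data)
            if seen:
                with_te += 1
                hits += len(seen)
                for rf in seen:
                    class_hits[rf.repeat_class] += 1
        per_repeat_class[label] = dict(class_hits)
        rows.append(
            {
                "class": label,
                "transcripts_total": total,
                "transcripts_with_TE": with_te,
                "te_hits_total": hits,
                "percent_with_TE": rate(with_te, total) if total else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["per_repeat_class"] = per_repeat_class
    return df
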