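"""Seeded synthetic datasets with the structure the pipeline assumes.

The generator emulates the study design this package targets: a small
multi-chromosome genome; protein-coding genes carrying long ORFs with a
biased codon (hence in-frame hexamer) composition; noncoding transcripts
planted intergenically, inside introns, and antisense across coding exons;
housekeeping-ncRNA decoys (tRNA/rRNA/snoRNA/snRNA/pre-miRNA/pseudogene);
four pooled libraries (one per shell-colour family, no replicates) as an
FPKM matrix with planted fold changes between designated sample pairs; and
repeat intervals overlapping a known fraction of each transcript class.

Every placement and sequence draw flows through one seeded generator, so a
fixed spec yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_repeats_bed,
)
from .coding_potential import (
    ALL_HEXAMERS,
    STOP_CODONS,
    HexamerModel,
    find_longest_orf,
)
from .expression_de import ExpressionMatrix, write_counts_table, write_fpkm_table

HOUSEKEEPING_DECOY_BIOTYPES = (
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "pre_miRNA",
    "pseudogene",
)

ALL_CODONS = tuple("".join(p) for p in product("ACGT", repeat=3))
_NONSTOP_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

# Frozen per-codon preference scores defining the coding composition model;
# fixed independently of the user seed so the coding/noncoding contrast is a
# property of the generator, not of an individual dataset.
_CODON_SCORES = np.random.default_rng(20180123).normal(size=len(ALL_CODONS))

REPEAT_CLASSES = ("DNA/hAT", "RC/Helitron", "Satellite/minisat", "LINE/L2", "SINE/tRNA")


class GenerationError(RuntimeError):
    """Requested features cannot be placed under the given genome geometry."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a small but fully structured genome: three 300-kb
    chromosomes, 45 coding genes, 15 planted lncRNAs per positional
    subtype, two decoys per housekeeping biotype, and four pooled
    libraries with fold changes planted in one pairwise comparison.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 300_000
    n_coding_genes: int = 45
    n_linc: int = 15
    n_intronic: int = 15
    n_antisense: int = 15
    n_decoys_per_biotype: int = 2
    coding_orf_min: int = 600
    hexamer_bias: float = 1.0
    sample_names: tuple[str, ...] = ("BSM", "GSM", "NSM", "WSM")
    de_pairs: tuple[tuple[str, str, int, float], ...] = (("BSM", "WSM", 10, 2.5),)
    fpkm_log2_mean: float = 3.5
    fpkm_log2_sd: float = 1.0
    noise_sd_log2: float = 0.25
    planted_fpkm_floor: float = 5.0
    min_intergenic_distance: int = 2000
    library_size: int = 20_000_000
    noncoding_orf_max: int = 300
    te_frac_coding: float = 0.8
    te_frac_lnc: float = 0.6
    n_background_repeats: int = 5

    def __post_init__(self) -> None:
        counts = (
            self.n_coding_genes,
            self.n_linc,
            self.n_intronic,
            self.n_antisense,
            self.n_decoys_per_biotype,
        )
        if any(c < 0 for c in counts):
            raise GenerationError("feature counts must be non-negative")
        if self.n_coding_genes < self.n_intronic + self.n_antisense:
            raise GenerationError(
                "need at least one coding gene per hosted intronic/antisense lncRNA"
            )
        for a, b, _n, eff in self.de_pairs:
            if a not in self.sample_names or b not in self.sample_names:
                raise GenerationError(f"DE pair ({a}, {b}) references unknown sample")
            if not math.isfinite(eff):
                raise GenerationError("planted log2 effect must be finite")


@dataclass(frozen=True)
class TruthLabel:
    is_lncRNA: bool
    subtype: str  # lincRNA | intronic | antisense | ""
    is_coding: bool
    is_decoy: bool


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-transcript labels, DE sets, repeats."""

    labels: dict[str, TruthLabel] = field(default_factory=dict)
    de: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    repeats: list[RepeatFeature] = field(default_factory=list)

    @property
    def lnc_ids(self) -> set[str]:
        return {t for t, lab in self.labels.items() if lab.is_lncRNA}

    @property
    def coding_ids(self) -> set[str]:
        return {t for t, lab in self.labels.items() if lab.is_coding}

    def subtype_of(self, tid: str) -> str:
        return self.labels[tid].subtype


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    reference: AnnotationSet
    assembled: AnnotationSet
    expression: ExpressionMatrix
    repeats: list[RepeatFeature]
    truth: SyntheticTruth
    hexamer_model: HexamerModel
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Composition models

def codon_probabilities(bias: float) -> np.ndarray:
    """Codon multinomial of the coding model: p ∝ exp(bias · score)."""
    w = np.exp(bias * _CODON_SCORES)
    return w / w.sum()


def build_hexamer_model(bias: float) -> HexamerModel:
    """The explicit hexamer tables the generator samples from.

    The coding table is the product measure of two codon draws; the
    noncoding table is uniform.  At ``bias = 0`` the two tables coincide,
    so the hexamer log-likelihood ratio carries no signal.
    """
    p = codon_probabilities(bias)
    p_by_codon = dict(zip(ALL_CODONS, p))
    coding = {}
    for h in ALL_HEXAMERS:
        coding[h] = p_by_codon[h[:3]] * p_by_codon[h[3:]]
    total = sum(coding.values())
    coding = {h: v / total for h, v in coding.items()}
    noncoding = {h: 1.0 / 4096 for h in ALL_HEXAMERS}
    return HexamerModel(coding, noncoding)


def _draw_orf_codons(rng: np.random.Generator, n_codons: int, bias: float) -> str:
    """Internal ORF codons under the coding model, stop codons excluded."""
    p = codon_probabilities(bias)
    keep = np.array([c not in STOP_CODONS for c in ALL_CODONS])
    p = p * keep
    p = p / p.sum()
    idx = rng.choice(len(ALL_CODONS), size=n_codons, p=p)
    return "".join(ALL_CODONS[i] for i in idx)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _noncoding_seq(rng: np.random.Generator, n: int, orf_max: int) -> str:
    """Uniform-composition sequence whose longest ORF stays below ``orf_max``.

    Long chance ORFs are broken by overwriting an in-frame internal codon
    with a stop; the perturbation touches a negligible fraction of bases.
    """
    seq = list(_random_seq(rng, n))
    for _ in range(200):
        orf = find_longest_orf("".join(seq))
        if orf.length < orf_max:
            return "".join(seq)
        # overwrite a codon in the middle of the offending ORF
        codon_index = orf.length // 6
        pos = orf.start + 3 * codon_index
        seq[pos : pos + 3] = "TAA"
    raise GenerationError("could not suppress open reading frames")


# ---------------------------------------------------------------------------
# Sequence planting helpers

def _spliced_to_genome(t: TranscriptModel) -> list[int]:
    """Genome coordinate of each spliced base, in transcription order."""
    coords: list[int] = []
    for e in t.exons:
        coords.extend(range(e.start, e.end))
    if t.strand == "-":
        coords.reverse()
    return coords

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _write_transcript_seq(t: TranscriptModel, seq: str, chrom: list[str]) -> None:
    coords = _spliced_to_genome(t)
    if len(coords) != len(seq):
        raise GenerationError(
            f"{t.transcript_id}: sequence length {len(seq)} != spliced length {len(coords)}"
        )
    if t.strand == "-":
        for pos, base in zip(coords, seq):
            chrom[pos] = _COMP[base]
    else:
        for pos, base in zip(coords, seq):
            chrom[pos] = base


def _read_transcript_seq(t: TranscriptModel, chrom: list[str]) -> str:
    coords = _spliced_to_genome(t)
    if t.strand == "-":
        return "".join(_COMP[chrom[p]] for p in coords)
    return "".join(chrom[p] for p in coords)


def _force_noncoding(
    t: TranscriptModel,
    chrom: list[str],
    protected: set[int],
    orf_max: int,
) -> None:
    """Break chance ORFs in a planted noncoding transcript by writing stop
    codons at genome positions outside ``protected`` (coding exon bases)."""
    coords = _spliced_to_genome(t)
    for _ in range(200):
        seq = _read_transcript_seq(t, chrom)
        orf = find_longest_orf(seq)
        if orf.length < orf_max:
            return
        placed = False
        # walk in-frame codons of the ORF, innermost outward, seeking one
        # whose three bases are all mutable
        n_codons = orf.length // 3
        order = sorted(range(1, n_codons - 1), key=lambda i: abs(i - n_codons // 2))
        for ci in order:
            s = orf.start + 3 * ci
            pos3 = coords[s : s + 3]
            if any(p in protected for p in pos3):
                continue
            for p, base in zip(pos3, "TAA"):
                chrom[p] = base if t.strand == "+" else _COMP[base]
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"{t.transcript_id}: cannot break ORF without touching coding exons"
            )
    raise GenerationError(f"{t.transcript_id}: could not suppress reading frames")


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    if total < parts * minimum:
        raise GenerationError(f"cannot split {total} into {parts} parts of ≥{minimum}")
    extra = rng.multinomial(total - parts * minimum, np.full(parts, 1.0 / parts))
    return [minimum + int(e) for e in extra]


# ---------------------------------------------------------------------------
# Main generator

def generate_bundle(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate the full dataset described by ``spec``.

    Returns in-memory objects; when ``out_dir`` is given, also writes
    genome.fa, reference.gtf, assembled.gtf, fpkm.tsv, counts.tsv,
    repeats.bed, truth.tsv, de_truth.tsv and hexamer_model.tsv.
    Placement that does not fit the genome geometry raises
    :class:`GenerationError` rather than silently truncating.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chroms: dict[str, list[str]] = {
        name: list(_random_seq(rng, spec.chromosome_length)) for name in chrom_names
    }
    cursors = {name: 1000 for name in chrom_names}

    reference = AnnotationSet()
    assembled = AnnotationSet()
    truth = SyntheticTruth()
    protected: dict[str, set[int]] = {name: set() for name in chrom_names}
    repeats: list[RepeatFeature] = []

    # build the work list: coding genes host intronic/antisense lncRNAs on
    # distinct genes; remaining genes are plain
    jobs: list[tuple[str, int, str]] = []
    hosts = ["intronic"] * spec.n_intronic + ["antisense"] * spec.n_antisense
    for gi in range(spec.n_coding_genes):
        host = hosts[gi] if gi < len(hosts) else "plain"
        jobs.append(("gene", gi, host))
    for li in range(spec.n_linc):
        jobs.append(("linc", li, ""))
    di = 0
    for biotype in HOUSEKEEPING_DECOY_BIOTYPES:
        for _ in range(spec.n_decoys_per_biotype):
            jobs.append(("decoy", di, biotype))
            di += 1

    def advance(chrom_name: str, span_len: int) -> int:
        gap = spec.min_intergenic_distance + int(rng.integers(0, 1000))
        start = cursors[chrom_name] + gap
        end = start + span_len
        if end > spec.chromosome_length - 1000:
            raise GenerationError(
                f"{chrom_name}: features exceed chromosome length "
                f"{spec.chromosome_length}; enlarge the genome or reduce counts"
            )
        cursors[chrom_name] = end
        return start

    lnc_counter = 0
    for ji, job in enumerate(jobs):
        kind, index, extra = job
        chrom_name = chrom_names[ji % len(chrom_names)]
        chrom = chroms[chrom_name]
        if kind == "gene":
            _place_coding_gene(
                spec, rng, chrom_name, chrom, advance, reference, assembled,
                truth, protected[chrom_name], repeats, index, extra, lnc_counter,
            )
            if extra in ("intronic", "antisense"):
                lnc_counter += 1
        elif kind == "linc":
            _place_intergenic_lnc(
                spec, rng, chrom_name, chrom, advance, assembled, truth,
                repeats, index,
            )
        else:
            _place_decoy(
                spec, rng, chrom_name, chrom, advance, reference, assembled,
                truth, index, extra,
            )

    # background repeats in the unused chromosome tails
    for chrom_name in chrom_names:
        tail_start = cursors[chrom_name] + 2000
        tail_end = spec.chromosome_length - 200
        if tail_end - tail_start < 1000:
            continue
        for _ in range(spec.n_background_repeats):
            start = int(rng.integers(tail_start, tail_end - 300))
            length = int(rng.integers(80, 300))
            rclass = REPEAT_CLASSES[int(rng.integers(0, len(REPEAT_CLASSES)))]
            repeats.append(
                RepeatFeature(
                    GenomicInterval(chrom_name, start, start + length, "+"),
                    repeat_class=rclass,
                    repeat_name=f"bg_{chrom_name}_{start}",
                )
            )
    truth.repeats = list(repeats)

    expression = _make_expression(spec, rng, assembled, truth)
    genome = {name: "".join(seq) for name, seq in chroms.items()}
    model = build_hexamer_model(spec.hexamer_bias)

    bundle = SyntheticBundle(
        genome=genome,
        reference=reference,
        assembled=assembled,
        expression=expression,
        repeats=repeats,
        truth=truth,
        hexamer_model=model,
    )
    if out_dir is not None:
        bundle.paths = _write_bundle(bundle, Path(out_dir))
    return bundle


def _place_coding_gene(
    spec, rng, chrom_name, chrom, advance, reference, assembled, truth,
    protected, repeats, index, host, lnc_counter,
) -> None:
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    orf_len = spec.coding_orf_min + 3 * int(rng.integers(0, 100))
    utr5 = int(rng.integers(40, 90))
    utr3 = int(rng.integers(60, 150))
    spliced_len = utr5 + orf_len + utr3
    n_exons = int(rng.integers(4, 8))
    exon_sizes = _partition(rng, spliced_len, n_exons, 90)
    intron_sizes = [int(rng.integers(300, 650)) for _ in range(n_exons - 1)]
    host_intron = None
    if host == "intronic":
        host_intron = (n_exons - 1) // 2
        intron_sizes[host_intron] = max(intron_sizes[host_intron], 900)
    if host == "antisense":
        intron_sizes[0] = max(intron_sizes[0], 700)

    gene_span_len = sum(exon_sizes) + sum(intron_sizes)
    start = advance(chrom_name, gene_span_len)

    exons = []
    pos = start
    for i, size in enumerate(exon_sizes):
        exons.append(GenomicInterval(chrom_name, pos, pos + size, strand))
        pos += size
        if i < len(intron_sizes):
            pos += intron_sizes[i]

    gene_id = f"PCG{index + 1:04d}"
    ref_tid = f"{gene_id}.t1"
    ref_tx = TranscriptModel(ref_tid, gene_id, exons, biotype="protein_coding")

    # spliced sequence: UTRs free of long ORFs, CDS from the coding model
    cds = "ATG" + _draw_orf_codons(rng, orf_len // 3 - 2, spec.hexamer_bias) + "TAA"
    seq = (
        _noncoding_seq(rng, utr5, spec.noncoding_orf_max)
        + cds
        + _noncoding_seq(rng, utr3, spec.noncoding_orf_max)
    )
    _write_transcript_seq(ref_tx, seq, chrom)
    for e in exons:
        protected.update(range(e.start, e.end))

    reference.add(ref_tx)
    asm_tid = f"TCONS_C{index + 1:05d}"
    assembled.add(
        TranscriptModel(asm_tid, f"XLOC_C{index + 1:05d}", list(exons))
    )
    truth.labels[asm_tid] = TruthLabel(False, "", True, False)

    if rng.random() < spec.te_frac_coding:
        e = exons[int(rng.integers(0, len(exons)))]
        repeats.append(_repeat_over(rng, e, f"te_{asm_tid}"))

    if host == "intronic":
        _place_intronic_lnc(
            spec, rng, chrom_name, chrom, ref_tx, host_intron, assembled,
            truth, protected, repeats, lnc_counter,
        )
    elif host == "antisense":
        _place_antisense_lnc(
            spec, rng, chrom_name, chrom, ref_tx, assembled, truth,
            protected, repeats, lnc_counter,
        )


def _repeat_over(rng, exon: GenomicInterval, name: str) -> RepeatFeature:
    length = int(rng.integers(60, min(180, len(exon))))
    offset = int(rng.integers(0, len(exon) - length + 1))
    rclass = REPEAT_CLASSES[int(rng.integers(0, len(REPEAT_CLASSES)))]
    return RepeatFeature(
        GenomicInterval(exon.chrom, exon.start + offset, exon.start + offset + length, "+"),
        repeat_class=rclass,
        repeat_name=name,
    )


def _lnc_ids(counter_or_index: int, prefix: str) -> tuple[str, str]:
    return (
        f"TCONS_{prefix}{counter_or_index + 1:05d}",
        f"XLOC_{prefix}{counter_or_index + 1:05d}",
    )


def _place_intronic_lnc(
    spec, rng, chrom_name, chrom, host_tx, intron_index, assembled, truth,
    protected, repeats, counter,
) -> None:
    introns = host_tx.introns()
    intron = introns[intron_index]
    # two exons wholly inside the intron, margins keep exon–exon overlap at 0
    e1 = int(rng.integers(140, 200))
    gap = int(rng.integers(90, 140))
    e2 = int(rng.integers(140, 200))
    need = e1 + gap + e2 + 120
    if len(intron) < need:
        raise GenerationError("hosting intron too small for intronic lncRNA")
    offset = 60 + int(rng.integers(0, len(intron) - need + 1))
    s = intron.start + offset
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    exons = [
        GenomicInterval(chrom_name, s, s + e1, strand),
        GenomicInterval(chrom_name, s + e1 + gap, s + e1 + gap + e2, strand),
    ]
    tid, gid = _lnc_ids(counter, "I")
    t = TranscriptModel(tid, gid, exons)
    _write_transcript_seq(t, _noncoding_seq(rng, t.length, spec.noncoding_orf_max), chrom)
    _force_noncoding(t, chrom, protected, spec.noncoding_orf_max)
    assembled.add(t)
    truth.labels[tid] = TruthLabel(True, "intronic", False, False)
    if rng.random() < spec.te_frac_lnc:
        repeats.append(_repeat_over(rng, exons[0], f"te_{tid}"))


def _place_antisense_lnc(
    spec, rng, chrom_name, chrom, host_tx, assembled, truth, protected,
    repeats, counter,
) -> None:
    gene_exon = host_tx.exons[0]
    overlap = int(rng.integers(100, 140))
    ext = int(rng.integers(60, 100))
    gap = int(rng.integers(80, 120))
    e2 = int(rng.integers(140, 190))
    strand = "-" if host_tx.strand == "+" else "+"
    s1 = gene_exon.end - overlap
    exons = [
        GenomicInterval(chrom_name, s1, gene_exon.end + ext, strand),
        GenomicInterval(
            chrom_name,
            gene_exon.end + ext + gap,
            gene_exon.end + ext + gap + e2,
            strand,
        ),
    ]
    tid, gid = _lnc_ids(counter, "A")
    t = TranscriptModel(tid, gid, exons)
    # only the bases outside the coding exon are writable; seed them with
    # noncoding sequence, then break any ORF the overlap region induces
    coords = _spliced_to_genome(t)
    fresh = _noncoding_seq(rng, t.length, spec.noncoding_orf_max)
    for pos, base in zip(coords, fresh):
        if pos not in protected:
            chrom[pos] = base if t.strand == "+" else _COMP[base]
    _force_noncoding(t, chrom, protected, spec.noncoding_orf_max)
    assembled.add(t)
    truth.labels[tid] = TruthLabel(True, "antisense", False, False)
    if rng.random() < spec.te_frac_lnc:
        repeats.append(_repeat_over(rng, exons[1], f"te_{tid}"))


def _place_intergenic_lnc(
    spec, rng, chrom_name, chrom, advance, assembled, truth, repeats, index
) -> None:
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    two_exons = index % 2 == 0
    if two_exons:
        e1 = int(rng.integers(180, 260))
        gap = int(rng.integers(120, 220))
        e2 = int(rng.integers(180, 260))
        span_len = e1 + gap + e2
    else:
        e1 = int(rng.integers(320, 560))
        span_len = e1
    start = advance(chrom_name, span_len)
    if two_exons:
        exons = [
            GenomicInterval(chrom_name, start, start + e1, strand),
            GenomicInterval(chrom_name, start + e1 + gap, start + span_len, strand),
        ]
    else:
        exons = [GenomicInterval(chrom_name, start, start + e1, strand)]
    tid, gid = _lnc_ids(index, "L")
    t = TranscriptModel(tid, gid, exons)
    _write_transcript_seq(t, _noncoding_seq(rng, t.length, spec.noncoding_orf_max), chrom)
    assembled.add(t)
    truth.labels[tid] = TruthLabel(True, "lincRNA", False, False)
    if rng.random() < spec.te_frac_lnc:
        repeats.append(_repeat_over(rng, exons[0], f"te_{tid}"))


def _place_decoy(
    spec, rng, chrom_name, chrom, advance, reference, assembled, truth, index, biotype
) -> None:
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    length = int(rng.integers(220, 420))
    start = advance(chrom_name, length)
    exon = GenomicInterval(chrom_name, start, start + length, strand)
    ref_gid = f"HK{index + 1:03d}"
    reference.add(
        TranscriptModel(f"{ref_gid}.t1", ref_gid, [exon], biotype=biotype)
    )
    seq = _noncoding_seq(rng, length, spec.noncoding_orf_max)
    ref_tx = reference.get(f"{ref_gid}.t1")
    _write_transcript_seq(ref_tx, seq, chrom)
    tid = f"TCONS_H{index + 1:05d}"
    assembled.add(TranscriptModel(tid, f"XLOC_H{index + 1:05d}", [exon]))
    truth.labels[tid] = TruthLabel(False, "", False, True)


# ---------------------------------------------------------------------------
# Expression

def _make_expression(
    spec: SyntheticSpec, rng: np.random.Generator, assembled: AnnotationSet,
    truth: SyntheticTruth,
) -> ExpressionMatrix:
    tids = sorted(assembled.transcripts)
    samples = list(spec.sample_names)
    baseline = np.exp2(
        rng.normal(spec.fpkm_log2_mean, spec.fpkm_log2_sd, size=len(tids))
    )
    baseline = np.maximum(baseline, spec.planted_fpkm_floor)
    values = np.tile(baseline[:, None], (1, len(samples)))

    # plant fold changes: effect applied to sample_b of each designated pair
    plantable = sorted(truth.lnc_ids | truth.coding_ids)
    for a, b, n_de, effect in spec.de_pairs:
        if n_de > len(plantable):
            raise GenerationError("more planted DE transcripts requested than exist")
        chosen = rng.choice(len(plantable), size=n_de, replace=False)
        pair_truth: dict[str, float] = {}
        bi = samples.index(b)
        for ci in sorted(int(c) for c in chosen):
            tid = plantable[ci]
            values[tids.index(tid), bi] *= 2.0 ** effect
            pair_truth[tid] = effect
        truth.de[(a, b)] = pair_truth

    noise = np.exp2(rng.normal(0.0, spec.noise_sd_log2, size=values.shape))
    fpkm_df = pd.DataFrame(values * noise, index=tids, columns=samples)

    lengths = np.array([assembled.get(t).length for t in tids], dtype=float)
    counts = np.rint(
        fpkm_df.to_numpy() * lengths[:, None] * spec.library_size / 1e9
    ).astype(int)
    counts_df = pd.DataFrame(counts, index=tids, columns=samples)
    totals = {s: spec.library_size for s in samples}
    return ExpressionMatrix(fpkm=fpkm_df, counts=counts_df, totals=totals)


def plant_detection_pattern(
    fpkm: pd.DataFrame, present: pd.DataFrame
) -> pd.DataFrame:
    """Zero out FPKM entries where ``present`` is False (library-detection
    patterns for exercising the detection filter).  Shapes must match."""
    if present.shape != fpkm.shape:
        raise GenerationError(
            f"presence mask shape {present.shape} != expression shape {fpkm.shape}"
        )
    mask = pd.DataFrame(
        present.to_numpy().astype(bool), index=fpkm.index, columns=fpkm.columns
    )
    return fpkm.where(mask, 0.0)


# ---------------------------------------------------------------------------
# Term-map fabrication (enrichment inputs are user-supplied in real runs)

def make_term_annotations(
    population: Sequence[str],
    enriched_genes: set[str],
    n_terms: int = 10,
    seed: int = 0,
    term_size: int = 12,
):
    """Fabricate a term map over ``population`` with term_0001 concentrated
    on ``enriched_genes`` and the rest drawn uniformly."""
    from .enrichment_report import TermAnnotation

    rng = np.random.default_rng(seed)
    pop = list(population)
    terms = []
    enriched = sorted(enriched_genes)
    if enriched:
        background = [g for g in pop if g not in enriched_genes]
        pad = list(rng.choice(background, size=max(0, term_size - len(enriched)), replace=False))
        terms.append(TermAnnotation("term_0001", set(enriched) | set(pad), "planted"))
    for i in range(2, n_terms + 1):
        members = rng.choice(pop, size=min(term_size, len(pop)), replace=False)
        terms.append(TermAnnotation(f"term_{i:04d}", set(members), f"random_{i}"))
    return terms


# ---------------------------------------------------------------------------
# File output

def _write_bundle(bundle: SyntheticBundle, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "reference": out_dir / "reference.gtf",
        "assembled": out_dir / "assembled.gtf",
        "fpkm": out_dir / "fpkm.tsv",
        "counts": out_dir / "counts.tsv",
        "repeats": out_dir / "repeats.bed",
        "truth": out_dir / "truth.tsv",
        "de_truth": out_dir / "de_truth.tsv",
        "hexamer_model": out_dir / "hexamer_model.tsv",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gtf(bundle.reference, paths["reference"])
    write_gtf(bundle.assembled, paths["assembled"])
    write_fpkm_table(bundle.expression.fpkm, paths["fpkm"])
    write_counts_table(bundle.expression.counts, bundle.expression.totals, paths["counts"])
    write_repeats_bed(bundle.repeats, paths["repeats"])
    with open(paths["truth"], "w") as fh:
        fh.write("transcript_id\tis_lncRNA\tsubtype\tis_coding\tis_decoy\n")
        for tid in sorted(bundle.truth.labels):
            lab = bundle.truth.labels[tid]
            fh.write(
                f"{tid}\t{int(lab.is_lncRNA)}\t{lab.subtype}\t"
                f"{int(lab.is_coding)}\t{int(lab.is_decoy)}\n"
            )
    with open(paths["de_truth"], "w") as fh:
        fh.write("sample_a\tsample_b\ttranscript_id\tlog2_effect\n")
        for (a, b), planted in sorted(bundle.truth.de.items()):
            for tid, eff in sorted(planted.items()):
                fh.write(f"{a}\t{b}\t{tid}\t{eff}\n")
    bundle.hexamer_model.to_table(paths["hexamer_model"])
    return paths
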