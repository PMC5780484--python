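# Methods

This note documents the models, parameter choices and numerical decisions
behind `mantlelnc`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open; GTF I/O converts to and
from the format's 1-based inclusive convention at the file boundary.
Span-to-span "distance" between transcripts is the number of bases strictly
between the spans: overlapping *or abutting* spans have distance 0. The
nearest-neighbour rule of cascade step (i) is strand-agnostic and measured
span-to-span rather than exon-to-exon, since its purpose is to catch
fragmented extensions of neighbouring transcripts regardless of annotated
strand; a same-strand-only variant would only loosen the filter.

## Positional classification

One class per transcript, assigned by precedence: known-mRNA match →
housekeeping-ncRNA overlap → antisense-exonic → intronic → intergenic →
other overlap. Precedence resolves genuinely ambiguous geometries (e.g. a
transcript inside a gene that also has an opposite-strand exon overlap is
antisense, not intronic). "Known mRNA" without running BLAST means exon
chains identical to a reference mRNA or same-strand exonic overlap covering
≥ 50 % of the shorter transcript (configurable); an external homology-hit
table can remove additional transcripts at step (v). Reference biotypes
are free labels defaulting to `unknown` — a transcript is never silently
promoted to `protein_coding`, so the housekeeping filter removes only what
the annotation actually marks as tRNA/rRNA/snoRNA/snRNA/pre-miRNA/
pseudogene.

## Coding-potential assessors

* **ORF finder** — longest ATG→stop span (stop inclusive) over the three
  forward frames of the strand-resolved spliced sequence; ORFs containing
  `N` are skipped; a lenient mode scores open-ended frames and a six-frame
  mode adds the reverse complement (both off by default, since the
  libraries the pipeline targets are strand-specific).
* **Fickett TESTCODE** — the published position-asymmetry and composition
  lookup tables with their per-base weights. `N` bases are excluded from
  all counts; a sequence > 50 % `N` is undefined (NaN). The reachable
  score range is fixed by the tables (≈ 0.29–1.39, available as
  `fickett_score_bounds()`).
* **Hexamer LLR** — mean of log(f_coding/f_noncoding) over frame-0,
  step-3 hexamers.

The built-in verdict is *coding* when ORF ≥ 300 nt, or Fickett ≥ 0.95 with
positive hexamer LLR. The ORF cutoff is the common < 100-codon lncRNA
convention; the Fickett cutoff is the classical "probably coding"
decision point. Both are stand-ins for external classifiers whose
thresholds published pipelines rarely state, so both are plain
configuration, not constants. External tools participate as verdict
tables (`transcript_id  tool  coding|noncoding`); the retention rule is
consensus: a transcript survives only if *every* verdict is noncoding.

## Replicate-free differential expression

With one pooled library per sample group there is no dispersion to
estimate, so no negative-binomial model is fit. The test is the
conditional binomial (Audic–Claverie flavour): conditional on the total
count of a transcript across the two libraries, the count split follows a
binomial with success probability equal to the library-size ratio;
two-sided p-values are BH-adjusted within each comparison. This test is
deliberately simple and known to be anti-conservative for biological
(rather than sampling) variation — with four pooled libraries that
limitation is inherent to the design, and the fold-change requirement
(|log₂FC| > 1, strict) does most of the filtering. A fold-change-only
mode applies when no raw counts exist. The log₂ fold change uses a 0.5
FPKM pseudocount (configurable) to keep zeros finite.

## Cis pairing, TE overlap, enrichment

Cis distance is the span-to-span gap, inclusive at the 100-kb boundary;
up/downstream is resolved on the lncRNA's strand (unknown strand is
reported in plus orientation and flagged). TE overlap is exon-level by
default — a repeat wholly inside an intron does not mark the transcript —
with a span-level mode for comparison; hits are (transcript, repeat)
pairs, so percentages and hit totals are reported separately, with
explicit numerators and denominators. Enrichment significance follows the
two conventions the workflow needs: adjusted p < 0.05 (GO-style) or raw
p < 0.05 (pathway-style), selectable. The length-bias correction is the
resampling flavour: study-sized sets drawn without replacement with
weights from an isotonic fit of study membership against gene length, with
a small weight floor so no gene becomes unreachable, +1-smoothed empirical
p-values and a fixed seed. BH is used wherever a p-value family needs
adjustment; published pipelines often leave the correction method
unstated, and BH is the field default.

## Synthetic data: what it emulates

The generator builds a genome of three 300-kb chromosomes and places, with
≥ 2-kb gaps: 45 coding genes (4–7 exons, ORF ≥ 600 nt plus UTRs), 15
planted lncRNAs per positional subtype, and 12 housekeeping decoys (2 per
removal-list biotype, mirrored as assembled transcripts so the
housekeeping filter is exercised). Four pooled libraries get lognormal
baseline FPKM (log₂ mean 3.5, sd 1.0, floored at 5 FPKM for planted
features so the expression filters test classification rather than
abundance), multiplicative log₂-normal noise (sd 0.25 — there are no
replicates in the emulated design, so no empirical dispersion exists to
copy), and 2^2.5-fold changes planted for 10 transcripts in one sample
pair. Counts are derived from FPKM by inverting the FPKM formula at
2×10⁷ mapped fragments per library. Repeats overlap 80 % of coding and
60 % of lncRNA transcripts plus background intervals in unused regions.

The coding composition model is a codon multinomial p ∝ exp(bias·w) with
frozen per-codon scores; the generator's hexamer tables are the product
measure of two codon draws (coding) versus uniform (noncoding), and ORF
codons are sampled from the stop-excluded renormalization. At bias = 0
the two tables coincide exactly, giving the null-generator property that
hexamer LLR carries no signal. Chance ORFs in noncoding sequence are
broken by overwriting an internal in-frame codon with a stop at positions
outside coding exons; this touches a negligible base fraction.

Planted intronic and antisense lncRNAs have **two exons**. This is a
deliberate design point: a single-exon transcript inside or overlapping a
gene has nearest-neighbour distance 0 and is — correctly — removed by
cascade step (i), so single-exon planting would make those subtypes
unrecoverable by construction. Two-exon lncRNAs match the observed
few-exon character of real lncRNA catalogs while keeping the recovery
property meaningful. Intergenic lncRNAs alternate between one and two
exons so the single-exon expression floor (FPKM ≥ 2) is exercised.

**What passing tests show.** With strong separation (long planted ORFs,
hexamer bias 1.0, floored FPKM, detection in all libraries) the cascade
recovers ≥ 95 % of planted lncRNAs with exact subtype labels, and planted
|log₂| ≥ 2 fold changes are recalled ≥ 90 % of the time across 20 seeds.
This validates the plumbing — ordering, boundaries, classification
geometry, bookkeeping — not real-world discrimination: real transcriptomes
have fragmented assemblies, ambiguous biotypes, overdispersed counts and
coding/noncoding composition far less separable than the planted model.

## Problem sizes and determinism

Default synthetic runs use ~100 assembled transcripts on a ~1-Mb genome;
oracle comparisons use 1,000 random sequences (ORF), exhaustive
enumeration at N ≤ 12 (hypergeometric), 500 genes (cis window) and a few
hundred intervals (TE sweep) — sizes at which the independent oracles are
exact and fast while still exercising every code path. All randomness is
funnelled through one seeded generator per run; a fixed spec reproduces
byte-identical output files.

## Known limitations

No GFF3 support beyond the GTF dialect; no transcript assembly or read
alignment; the binomial DE test understates biological variance; no GO
DAG propagation; locus grouping trusts the assembler's gene ids rather
than re-clustering; qPCR relative quantification assumes perfect
amplification efficiency.
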