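"""Coding-potential assessment for candidate lncRNA transcripts.

Three built-in assessors — longest-ORF length, the Fickett TESTCODE
statistic, and an in-frame hexamer log-likelihood ratio — plus optional
external verdict tables (one verdict per named tool, e.g. a BLAST/Pfam
scan run elsewhere).  A transcript is kept as noncoding only when *no*
assessor calls it coding ("consensus noncoding").
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_io import reverse_complement

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

ALL_HEXAMERS = tuple("".join(p) for p in product("ACGT", repeat=6))

DEFAULT_ORF_CUTOFF = 300  # nt; common operational lncRNA convention (<100 aa)
DEFAULT_FICKETT_CUTOFF = 0.95


# ---------------------------------------------------------------------------
# ORF search

@dataclass(frozen=True)
class ORFResult:
    """Longest open reading frame found in a transcript sequence.

    ``length`` counts ATG through the stop codon inclusive (0 when no ORF);
    ``frame`` is 0/1/2 on the given strand, negative for the reverse
    complement in six-frame mode; ``start`` is the 0-based offset of the ATG
    in the scanned strand's sequence.
    """

    length: int = 0
    frame: int | None = None
    start: int | None = None


def find_longest_orf(
    seq: str,
    *,
    six_frame: bool = False,
    require_stop: bool = True,
) -> ORFResult:
    """Longest ATG..stop span over the forward reading frames.

    The input is assumed already strand-resolved (a spliced transcript
    sequence), so only the 3 forward frames are scanned by default;
    ``six_frame=True`` adds the reverse complement.  ORFs whose span
    contains an ``N`` are skipped.  With ``require_stop=False`` an ATG with
    no downstream in-frame stop scores its open-ended length (lenient mode,
    off by default).
    """
    seq = seq.upper()
    best = ORFResult()
    best = _scan_frames(seq, best, sign=+1, require_stop=require_stop)
    if six_frame:
        best = _scan_frames(
            reverse_complement(seq), best, sign=-1, require_stop=require_stop
        )
    return best


def _scan_frames(seq: str, best: ORFResult, *, sign: int, require_stop: bool) -> ORFResult:
    n = len(seq)
    # prefix sums of N so the "contains N" check is O(1) per candidate
    n_prefix = [0] * (n + 1)
    for i, c in enumerate(seq):
        n_prefix[i + 1] = n_prefix[i] + (c == "N")

    def has_n(a: int, b: int) -> bool:
        return n_prefix[b] - n_prefix[a] > 0

    for frame in range(3):
        stops: list[int] = []
        starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                starts.append(i)
            elif codon in STOP_CODONS:
                stops.append(i)
        for s in starts:
            j = bisect_left(stops, s)
            if j < len(stops):
                end = stops[j] + 3
            elif require_stop:
                continue
            else:
                end = frame + 3 * ((n - frame) // 3)
                if end <= s:
                    continue
            if has_n(s, end):
                continue
            length = end - s
            if length > best.length:
                best = ORFResult(length, frame if sign > 0 else -(frame + 1), s)
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE

# Published TESTCODE lookup tables: probability-of-coding values indexed by
# thresholded position-asymmetry and composition parameters, with per-base
# weights reflecting each parameter's discriminative power.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def fickett_score_bounds() -> tuple[float, float]:
    """(min, max) score reachable under the lookup tables."""
    lo = sum(min(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT")
    lo += sum(min(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT")
    hi = sum(max(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT")
    hi += sum(max(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT")
    return lo, hi


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for threshold, prob in zip(thresholds, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic.

    Combines, for each base, its position asymmetry across the three codon
    positions (max count / (min count + 1)) and its overall fraction, mapped
    through the published probability tables and weights.  ``N`` bases are
    excluded from both counts.  Sequences that are >50% ``N`` are undefined
    and return ``nan`` with a warning.
    """
    seq = seq.upper()
    if not seq:
        return float("nan")
    n_frac = seq.count("N") / len(seq)
    if n_frac > 0.5:
        warnings.warn("fickett_score undefined for sequence with >50% N")
        return float("nan")
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    for i, c in enumerate(seq):
        if c in pos_counts:
            pos_counts[c][i % 3] += 1
            totals[c] += 1
    n_acgt = sum(totals.values())
    if n_acgt == 0:
        return float("nan")
    score = 0.0
    for b in "ACGT":
        counts = pos_counts[b]
        position_param = max(counts) / (min(counts) + 1)
        score += (
            _lookup(position_param, _POSITION_PARA, _POSITION_PROB[b])
            * _POSITION_WEIGHT[b]
        )
        content_param = totals[b] / n_acgt
        score += (
            _lookup(content_param, _CONTENT_PARA, _CONTENT_PROB[b])
            * _CONTENT_WEIGHT[b]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer model

@dataclass
class HexamerModel:
    """In-frame hexamer frequency tables under a coding and a noncoding model.

    Both tables cover all 4096 hexamers with pseudocount smoothing, each
    summing to 1; the log-ratio of the two is the discriminative feature.
    """

    coding: dict[str, float]
    noncoding: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("coding", self.coding), ("noncoding", self.noncoding)):
            if len(table) != 4096:
                raise ValueError(f"{name} table must cover all 4096 hexamers")
            total = math.fsum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} table sums to {total}, expected 1")
            if min(table.values()) <= 0:
                raise ValueError(f"{name} table contains non-positive frequency")

    @classmethod
    def from_counts(
        cls,
        coding_counts: Mapping[str, float],
        noncoding_counts: Mapping[str, float],
        pseudocount: float = 1.0,
    ) -> "HexamerModel":
        def normalize(counts: Mapping[str, float]) -> dict[str, float]:
            raw = {h: counts.get(h, 0.0) + pseudocount for h in ALL_HEXAMERS}
            total = math.fsum(raw.values())
            return {h: v / total for h, v in raw.items()}

        return cls(normalize(coding_counts), normalize(noncoding_counts))

    @classmethod
    def from_sequences(
        cls,
        coding_seqs: Iterable[str],
        noncoding_seqs: Iterable[str],
        pseudocount: float = 1.0,
    ) -> "HexamerModel":
        """Train both tables from in-frame hexamer counts of example sequences."""

        def count(seqs: Iterable[str]) -> dict[str, int]:
            counts: dict[str, int] = {}
            for s in seqs:
                s = s.upper()
                for i in range(0, len(s) - 5, 3):
                    h = s[i : i + 6]
                    if set(h) <= set("ACGT"):
                        counts[h] = counts.get(h, 0) + 1
            return counts

        return cls.from_counts(count(coding_seqs), count(noncoding_seqs), pseudocount)

    def swapped(self) -> "HexamerModel":
        return HexamerModel(dict(self.noncoding), dict(self.coding))

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tcoding\tnoncoding\n")
            for h in ALL_HEXAMERS:
                fh.write(f"{h}\t{self.coding[h]:.10e}\t{self.noncoding[h]:.10e}\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "HexamerModel":
        coding: dict[str, float] = {}
        noncoding: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("hexamer"):
                raise ValueError("hexamer table must have a hexamer/coding/noncoding header")
            for line in fh:
                h, c, nc = line.split()
                coding[h] = float(c)
                noncoding[h] = float(nc)
        # renormalize to absorb round-off from the text representation
        return cls.from_counts(coding, noncoding, pseudocount=0.0)


def hexamer_llr(seq: str, model: HexamerModel) -> float:
    """Mean log(coding/noncoding) over frame-0 in-frame hexamers (step 3).

    Hexamers containing non-ACGT characters are skipped; a sequence with no
    scorable hexamer returns 0.
    """
    seq = seq.upper()
    total = 0.0
    n = 0
    acgt = set("ACGT")
    for i in range(0, len(seq) - 5, 3):
        h = seq[i : i + 6]
        if set(h) <= acgt:
            total += math.log(model.coding[h] / model.noncoding[h])
            n += 1
    return total / n if n else 0.0


# ---------------------------------------------------------------------------
# Consensus assessment

@dataclass
class CodingAssessment:
    """Per-transcript assessor outputs and the consensus-noncoding flag.

    ``verdicts`` maps assessor name → ``"coding"``/``"noncoding"``;
    ``consensus_noncoding`` is true iff every verdict is noncoding — the
    retention rule for the coding-potential filter step.
    """

    transcript_id: str
    orf_length: int
    fickett: float
    hexamer: float
    verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def consensus_noncoding(self) -> bool:
        return all(v == "noncoding" for v in self.verdicts.values())


def read_verdict_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read ``transcript_id <TAB> tool <TAB> verdict`` rows into a nested map."""
    verdicts: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("coding", "noncoding"):
                raise ValueError(
                    f"{path} line {lineno}: expected "
                    "'transcript_id<TAB>tool<TAB>coding|noncoding'"
                )
            tid, tool, verdict = parts
            verdicts.setdefault(tid, {})[tool] = verdict
    return verdicts


def assess(
    transcript_id: str,
    seq: str,
    model: HexamerModel,
    external_verdicts: Mapping[str, Mapping[str, str]] | None = None,
    *,
    orf_cutoff: int = DEFAULT_ORF_CUTOFF,
    fickett_cutoff: float = DEFAULT_FICKETT_CUTOFF,
    six_frame: bool = False,
) -> CodingAssessment:
    """Run the built-in assessors and merge external tool verdicts.

    Built-in rule: coding if the longest ORF reaches ``orf_cutoff``, or the
    Fickett score reaches ``fickett_cutoff`` while the hexamer LLR is
    positive.  External tables contribute one verdict per tool; any single
    coding verdict breaks the noncoding consensus.
    """
    orf = find_longest_orf(seq, six_frame=six_frame)
    fick = fickett_score(seq)
    hexa = hexamer_llr(seq, model)
    verdicts = {
        "orf": "coding" if orf.length >= orf_cutoff else "noncoding",
        "fickett_hexamer": (
            "coding"
            if (not math.isnan(fick) and fick >= fickett_cutoff and hexa > 0)
            else "noncoding"
        ),
    }
    if external_verdicts:
        for tool, verdict in external_verdicts.get(transcript_id, {}).items():
            verdicts[tool] = verdict
    return CodingAssessment(
        transcript_id=transcript_id,
        orf_length=orf.length,
        fickett=fick,
        hexamer=hexa,
        verdicts=verdicts,
    )
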