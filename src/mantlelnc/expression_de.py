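"""Expression quantification and pairwise differential-expression calls.

The four libraries are single pooled samples (one per shell-colour family),
so there are no biological replicates and no dispersion to estimate.
Differential expression between two libraries therefore uses a
replicate-free conditional-binomial test on raw fragment counts
(Audic–Claverie style): conditional on the total count of a transcript in
the two libraries, its split follows a binomial whose success probability
is the ratio of library sizes.  When no counts are available, a fold-change
-only mode is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_CUT = 1.0
DEFAULT_PSEUDOCOUNT = 0.5  # FPKM offset guarding log2 of zero


class ExpressionError(ValueError):
    """Inconsistent expression inputs (missing rows, bad dimensions)."""


@dataclass
class ExpressionMatrix:
    """Transcript-by-sample FPKM values, optionally with raw fragment counts.

    ``fpkm`` is a DataFrame indexed by transcript id with one column per
    sample; ``counts`` (same shape) and ``totals`` (mapped fragments per
    sample) enable the count-based test.
    """

    fpkm: pd.DataFrame
    counts: pd.DataFrame | None = None
    totals: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ExpressionError("negative FPKM values")
        if self.fpkm.columns.duplicated().any():
            raise ExpressionError("duplicate sample ids")
        if self.counts is not None:
            if not self.counts.columns.equals(self.fpkm.columns):
                raise ExpressionError("counts and fpkm sample columns differ")
            if self.totals is None:
                raise ExpressionError("counts supplied without library totals")

    @property
    def samples(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.fpkm.index)


def read_fpkm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_fpkm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_counts_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Counts table with a ``__totals__`` row holding per-sample library sizes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "__totals__" not in df.index:
        raise ExpressionError("counts table lacks a __totals__ row")
    totals = df.loc["__totals__"].astype(int).to_dict()
    counts = df.drop(index="__totals__").astype(int)
    return counts, totals


def write_counts_table(
    counts: pd.DataFrame, totals: Mapping[str, int], path: str | Path
) -> None:
    out = counts.copy()
    out.loc["__totals__"] = [totals[s] for s in counts.columns]
    out.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Elementary quantities

def fpkm(C: float, N: float, L: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = C · 10⁹ / (N · L) for C fragments on a transcript of L nt in a
    library of N mapped fragments.
    """
    if N <= 0 or L <= 0:
        raise ExpressionError(f"N and L must be positive (got N={N}, L={L})")
    if C < 0:
        raise ExpressionError("fragment count must be non-negative")
    return C * 1e9 / (N * L)


def log2fc(a: float, b: float, pseudo: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 fold change of b over a with a pseudocount offset."""
    if a < 0 or b < 0:
        raise ExpressionError("FPKM values must be non-negative")
    if pseudo <= 0:
        raise ExpressionError("pseudocount must be positive")
    return float(np.log2((b + pseudo) / (a + pseudo)))


def pairwise_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    total_a: int,
    total_b: int,
) -> np.ndarray:
    """Replicate-free two-library test: per transcript, a two-sided
    conditional binomial p-value for the split (x_a, x_b) given library
    totals.  Under the null, x_b | (x_a + x_b = n) ~ Binom(n, N_b/(N_a+N_b)).
    Transcripts with zero total count get p = 1.
    """
    xa = np.asarray(counts_a, dtype=int)
    xb = np.asarray(counts_b, dtype=int)
    if xa.shape != xb.shape:
        raise ExpressionError("count vectors differ in length")
    p_null = total_b / (total_a + total_b)
    out = np.ones(xa.shape, dtype=float)
    for i, (a, b) in enumerate(zip(xa, xb)):
        n = int(a + b)
        if n == 0:
            continue
        out[i] = stats.binomtest(int(b), n, p_null, alternative="two-sided").pvalue
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DE calling

@dataclass(frozen=True)
class DECall:
    transcript_id: str
    sample_a: str
    sample_b: str
    log2fc: float
    pvalue: float
    padj: float
    significant: bool


def all_pairs(samples: Sequence[str]) -> list[tuple[str, str]]:
    """The pairwise comparison groups (six for four samples)."""
    return list(combinations(samples, 2))


def call_de(
    expr: ExpressionMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
    lfc_cut: float = DEFAULT_LFC_CUT,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Call differential expression for every transcript in every sample pair.

    Significance requires BH-adjusted p < ``alpha`` AND |log2FC| > ``lfc_cut``
    (both strict).  The p-value family for adjustment is one comparison
    (all transcripts in one pair).  Without counts, p and padj are NaN and
    significance rests on the fold-change criterion alone.

    Returns a tidy DataFrame with columns transcript_id, sample_a, sample_b,
    log2fc, pvalue, padj, significant.
    """
    if pairs is None:
        pairs = all_pairs(expr.samples)
    frames = []
    tids = expr.fpkm.index
    for a, b in pairs:
        if a not in expr.fpkm.columns or b not in expr.fpkm.columns:
            raise ExpressionError(f"unknown sample in pair ({a}, {b})")
        lfc = np.log2((expr.fpkm[b] + pseudo) / (expr.fpkm[a] + pseudo))
        if expr.counts is not None:
            pvals = pairwise_test(
                expr.counts[a].to_numpy(),
                expr.counts[b].to_numpy(),
                int(expr.totals[a]),
                int(expr.totals[b]),
            )
            padj = bh_adjust(pvals)
            significant = (padj < alpha) & (np.abs(lfc) > lfc_cut)
        else:
            pvals = np.full(len(tids), np.nan)
            padj = pvals
            significant = np.abs(lfc) > lfc_cut
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tids,
                    "sample_a": a,
                    "sample_b": b,
                    "log2fc": lfc.to_numpy(),
                    "pvalue": pvals,
                    "padj": padj,
                    "significant": np.asarray(significant, dtype=bool),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def significant_sets(
    de: pd.DataFrame, id_map: Mapping[str, str] | None = None
) -> dict[tuple[str, str], set[str]]:
    """Significant ids per pair, optionally mapped (e.g. transcript → locus)."""
    out: dict[tuple[str, str], set[str]] = {}
    for (a, b), sub in de.groupby(["sample_a", "sample_b"], sort=False):
        ids = sub.loc[sub["significant"], "transcript_id"]
        if id_map is not None:
            out[(a, b)] = {id_map.get(t, t) for t in ids}
        else:
            out[(a, b)] = set(ids)
    return out


# ---------------------------------------------------------------------------
# DEM intersection / union

@dataclass
class DEMJoin:
    """Per-pair intersection of two DE gene-set families, and its union.

    ``shared[pair]`` holds genes called DE in that pair by *both* analyses;
    ``union`` collapses the shared sets across all pairs by gene id.
    """

    shared: dict[tuple[str, str], set[str]]
    union: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.union = set().union(*self.shared.values()) if self.shared else set()


def join_dem(
    det_by_pair: Mapping[tuple[str, str], set[str]],
    dem_by_pair: Mapping[tuple[str, str], set[str]],
) -> DEMJoin:
    """Retain genes differentially expressed in the *same* pairwise group by
    both analyses, then take the union over the pairwise groups."""
    shared = {
        pair: set(det_by_pair.get(pair, set())) & set(dem_by_pair.get(pair, set()))
        for pair in set(det_by_pair) | set(dem_by_pair)
    }
    return DEMJoin(shared=shared)
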