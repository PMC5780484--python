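"""Term enrichment, qPCR relative quantification, and summary tables.

Enrichment of a study gene set against a population is tested with the
upper-tail hypergeometric distribution per term.  An optional length-bias
corrected mode builds the null by resampling study-sized gene sets with
length-dependent weights, mirroring the strategy of length-aware GO tools
for RNA-seq where long genes are more likely to be called DE.

Annotation content is never bundled: term maps are plain two-column
``gene_id <TAB> term_id`` inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .expression_de import bh_adjust


class EnrichmentError(ValueError):
    pass


@dataclass
class TermAnnotation:
    term_id: str
    annotated_genes: set[str]
    term_name: str = ""

    def __post_init__(self) -> None:
        if not self.annotated_genes:
            raise EnrichmentError(f"term {self.term_id} annotates no genes")


def read_term_map(path: str | Path) -> list[TermAnnotation]:
    """Read ``gene_id <TAB> term_id [<TAB> term_name]`` rows."""
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise EnrichmentError(f"bad term-map row: {line!r}")
            gene, term = parts[0], parts[1]
            genes_by_term.setdefault(term, set()).add(gene)
            if len(parts) >= 3:
                names[term] = parts[2]
    return [
        TermAnnotation(term, genes, names.get(term, ""))
        for term, genes in sorted(genes_by_term.items())
    ]


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    terms: Iterable[TermAnnotation],
    *,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``study`` within ``population``.

    Per term with K annotated genes in a population of N, and k of the n
    study genes annotated: p = P(X ≥ k) for X ~ Hypergeom(N, K, n).
    A BH-adjusted column is always emitted; the significance flag uses the
    adjusted p when ``use_adjusted`` (the convention for GO), else the raw
    p (the convention for pathway tests).
    """
    missing = study - population
    if missing:
        raise EnrichmentError(
            f"study genes absent from population: {sorted(missing)[:10]}"
        )
    N, n = len(population), len(study)
    rows = []
    for term in terms:
        annotated = term.annotated_genes & population
        if not annotated:
            continue
        K = len(annotated)
        k = len(annotated & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "pvalue"]
    )
    df["padj"] = bh_adjust(df["pvalue"]) if len(df) else []
    crit = df["padj"] if use_adjusted else df["pvalue"]
    df["significant"] = crit < alpha
    return df


def _length_weights(
    population: Sequence[str], study: set[str], lengths: Mapping[str, float]
) -> np.ndarray:
    """Monotone selection-probability weights from an isotonic fit of
    study membership against gene length."""
    lens = np.array([lengths[g] for g in population], dtype=float)
    flags = np.array([g in study for g in population], dtype=float)
    order = np.argsort(lens, kind="stable")
    iso = IsotonicRegression(y_min=0.0, increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(lens[order], flags[order])
    weights = np.empty_like(fitted)
    weights[order] = fitted
    # floor avoids zero-probability genes, which would make some study
    # compositions unreachable under the null
    floor = max(weights.max() * 1e-3, 1e-12)
    return np.maximum(weights, floor)


def length_bias_enrich(
    study: set[str],
    population: set[str],
    terms: Iterable[TermAnnotation],
    lengths: Mapping[str, float],
    *,
    n_null: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Length-bias-corrected enrichment by weighted resampling.

    The null distribution of per-term study hits is built by drawing
    ``n_null`` study-sized gene sets without replacement, with selection
    weights from a monotone (isotonic) fit of study membership versus gene
    length.  Empirical p-values use +1 smoothing; deterministic per seed.
    """
    if n_null < 100:
        raise EnrichmentError("n_null must be at least 100 for a usable null")
    missing = study - population
    if missing:
        raise EnrichmentError(
            f"study genes absent from population: {sorted(missing)[:10]}"
        )
    missing_len = [g for g in population if g not in lengths]
    if missing_len:
        raise EnrichmentError(f"genes lack lengths: {missing_len[:10]}")
    pop = sorted(population)
    weights = _length_weights(pop, study, lengths)
    prob = weights / weights.sum()
    rng = np.random.default_rng(seed)
    n = len(study)
    term_list = [t for t in terms if t.annotated_genes & population]
    idx = {g: i for i, g in enumerate(pop)}
    term_masks = np.zeros((len(term_list), len(pop)), dtype=np.int64)
    for ti, term in enumerate(term_list):
        for g in term.annotated_genes & population:
            term_masks[ti, idx[g]] = 1
    k_obs = np.array([len(t.annotated_genes & study) for t in term_list])
    exceed = np.zeros(len(term_list), dtype=int)
    for _ in range(n_null):
        draw = rng.choice(len(pop), size=n, replace=False, p=prob)
        mask = np.zeros(len(pop), dtype=np.int64)
        mask[draw] = 1
        k_null = term_masks @ mask
        exceed += k_null >= k_obs
    pvals = (exceed + 1) / (n_null + 1)
    df = pd.DataFrame(
        {
            "term_id": [t.term_id for t in term_list],
            "term_name": [t.term_name for t in term_list],
            "k": k_obs,
            "n": n,
            "K": [len(t.annotated_genes & population) for t in term_list],
            "N": len(pop),
            "pvalue": pvals,
        }
    )
    df["padj"] = bh_adjust(df["pvalue"]) if len(df) else []
    crit = df["padj"] if use_adjusted else df["pvalue"]
    df["significant"] = crit < alpha
    return df


# ---------------------------------------------------------------------------
# Comparative-CT (ΔΔCT) relative quantification

@dataclass(frozen=True)
class QPCRResult:
    ddct: float
    rq: float


def ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> QPCRResult:
    """Comparative threshold-cycle method against an endogenous control.

    ΔΔCT = (CT_target − CT_ref)_condition − (CT_target − CT_ref)_control;
    relative quantity = 2^−ΔΔCT.
    """
    delta = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return QPCRResult(ddct=delta, rq=2.0 ** (-delta))


# ---------------------------------------------------------------------------
# Characterization tables and rate arithmetic

def rate(part: int, whole: int) -> float:
    """Percentage 100·part/whole, half-up rounded to 2 decimals (the
    formatting used for mapping-rate and TE-fraction tables)."""
    if whole <= 0:
        raise EnrichmentError("whole must be positive")
    if part < 0 or part > whole:
        raise EnrichmentError("part must lie in [0, whole]")
    pct = Decimal(100 * part) / Decimal(whole)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def characterize(
    classes: Mapping[str, Iterable],
    expr_fpkm: pd.DataFrame | None = None,
    orf_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-class summary of exon count, spliced length, longest-ORF length
    and expression — the catalog-vs-mRNA comparison table.

    ``classes`` maps a class label (e.g. ``mRNA``, ``lincRNA``) to its
    transcripts.  Expression is summarized as mean log2(max FPKM + 1).
    Empty classes yield a row of NaNs rather than an error.
    """
    rows = []
    for label, transcripts in classes.items():
        ts = list(transcripts)
        row: dict[str, float | int | str] = {"class": label, "n": len(ts)}
        if not ts:
            rows.append(row)
            continue
        row["mean_exons"] = float(np.mean([t.n_exons for t in ts]))
        row["median_exons"] = float(np.median([t.n_exons for t in ts]))
        row["mean_length"] = float(np.mean([t.length for t in ts]))
        row["median_length"] = float(np.median([t.length for t in ts]))
        if orf_lengths is not None:
            orfs = [orf_lengths[t.transcript_id] for t in ts if t.transcript_id in orf_lengths]
            if orfs:
                row["mean_orf"] = float(np.mean(orfs))
        if expr_fpkm is not None:
            tids = [t.transcript_id for t in ts if t.transcript_id in expr_fpkm.index]
            if tids:
                mx = expr_fpkm.loc[tids].max(axis=1)
                row["mean_log2_fpkm"] = float(np.mean(np.log2(mx + 1)))
        rows.append(row)
    return pd.DataFrame(rows)
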