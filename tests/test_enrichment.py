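import math
from itertools import combinations

import numpy as np
import pytest

from mantlelnc.enrichment_report import (
    EnrichmentError,
    TermAnnotation,
    characterize,
    ddct,
    hypergeom_enrich,
    length_bias_enrich,
    rate,
    read_term_map,
)


def enumerate_p(N, K, n, k):
    """Exhaustive oracle: over all C(N, n) study draws from a population with
    K annotated genes, the fraction with ≥ k annotated members."""
    population = range(N)
    annotated = set(range(K))
    hits = total = 0
    for draw in combinations(population, n):
        total += 1
        hits += len(annotated & set(draw)) >= k
    return hits / total


def term(tid, genes, name=""):
    return TermAnnotation(tid, set(genes), name)


class TestHypergeomEnrich:
    def test_full_overlap_example(self):
        # all 5 study genes carry the term: p = 1/C(20,5) = 1/15504
        pop = {f"g{i}" for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        df = hypergeom_enrich(study, pop, [term("T", study)])
        assert df.pvalue.iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_degenerate_cases(self):
        pop = {f"g{i}" for i in range(10)}
        study = {"g0", "g1"}
        no_hit = term("T0", {"g8", "g9"})
        whole_pop = term("T1", pop)
        df = hypergeom_enrich(study, pop, [no_hit, whole_pop])
        by = df.set_index("term_id")
        assert by.loc["T0", "pvalue"] == pytest.approx(
            enumerate_p(10, 2, 2, 0)
        )  # k=0 → upper tail = 1
        assert by.loc["T1", "pvalue"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric upper tail equals brute-force enumeration, N ≤ 12."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            pop = [f"g{i}" for i in range(N)]
            study = set(rng.choice(pop, size=n, replace=False))
            t = term("T", pop[:K])
            df = hypergeom_enrich(study, set(pop), [t])
            k = len(study & set(pop[:K]))
            assert df.pvalue.iloc[0] == pytest.approx(enumerate_p(N, K, n, k), rel=1e-9)

    def test_p_monotone_nonincreasing_in_k(self):
        from scipy import stats

        N, K, n = 50, 12, 10
        ps = [float(stats.hypergeom.sf(k - 1, N, K, n)) for k in range(0, n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_study_outside_population_rejected(self):
        with pytest.raises(EnrichmentError, match="absent"):
            hypergeom_enrich({"x"}, {"a"}, [term("T", {"a"})])

    def test_significance_convention_switch(self):
        pop = {f"g{i}" for i in range(40)}
        study = {f"g{i}" for i in range(5)}
        terms = [term("T", study)] + [
            term(f"R{i}", {f"g{j}" for j in range(i, i + 8)}) for i in range(10, 30, 4)
        ]
        adj = hypergeom_enrich(study, pop, terms, use_adjusted=True)
        raw = hypergeom_enrich(study, pop, terms, use_adjusted=False)
        assert adj.significant.sum() <= raw.significant.sum()


class TestLengthBias:
    def _fixture(self):
        rng = np.random.default_rng(4)
        pop = [f"g{i}" for i in range(60)]
        lengths = {g: 200 + 100 * i for i, g in enumerate(pop)}
        # study biased toward long genes
        study = set(pop[40:52])
        long_term = term("LONG", pop[45:60])
        return pop, lengths, study, long_term

    def test_equal_lengths_converge_to_hypergeometric(self):
        pop = [f"g{i}" for i in range(30)]
        lengths = {g: 500 for g in pop}
        study = set(pop[:8])
        t = term("T", pop[:12])
        hg = hypergeom_enrich(study, set(pop), [t]).pvalue.iloc[0]
        lb = length_bias_enrich(
            study, set(pop), [t], lengths, n_null=10_000, seed=0
        ).pvalue.iloc[0]
        assert abs(lb - hg) < 0.02

    def test_deterministic_per_seed(self):
        pop, lengths, study, t = self._fixture()
        a = length_bias_enrich(study, set(pop), [t], lengths, n_null=500, seed=3)
        b = length_bias_enrich(study, set(pop), [t], lengths, n_null=500, seed=3)
        assert a.pvalue.tolist() == b.pvalue.tolist()

    def test_correction_weakens_long_gene_terms(self):
        pop, lengths, study, t = self._fixture()
        uncorrected = hypergeom_enrich(study, set(pop), [t]).pvalue.iloc[0]
        corrected = length_bias_enrich(
            study, set(pop), [t], lengths, n_null=4000, seed=1
        ).pvalue.iloc[0]
        assert corrected > uncorrected

    def test_small_null_refused(self):
        pop, lengths, study, t = self._fixture()
        with pytest.raises(EnrichmentError):
            length_bias_enrich(study, set(pop), [t], lengths, n_null=50, seed=0)


class TestDDCT:
    @pytest.mark.parametrize(
        "cts,expected_ddct,expected_rq",
        [
            ((20, 15, 20, 15), 0.0, 1.0),
            ((19, 15, 20, 15), -1.0, 2.0),
            ((20, 15, 22, 15), -2.0, 4.0),
        ],
    )
    def test_examples(self, cts, expected_ddct, expected_rq):
        res = ddct(*cts)
        assert res.ddct == pytest.approx(expected_ddct)
        assert res.rq == pytest.approx(expected_rq)

    def test_rq_strictly_decreasing_and_reciprocal(self):
        rqs = [ddct(20 + d, 15, 20, 15).rq for d in np.linspace(-3, 3, 13)]
        assert all(a > b for a, b in zip(rqs, rqs[1:]))
        a = ddct(18.3, 15, 20, 15)
        b = ddct(21.7, 15, 20, 15)  # mirrored ΔΔCT
        assert a.rq * b.rq == pytest.approx(1.0)


class TestRate:
    def test_mapping_rate_arithmetic(self):
        assert rate(70_571_864, 93_987_492) == 75.09

    def test_extremes(self):
        assert rate(0, 5) == 0.0
        assert rate(5, 5) == 100.0

    def test_half_up_rounding(self):
        assert rate(1, 800) == 0.13  # 0.125% rounds up
        assert rate(5005, 10_000) == 50.05

    def test_scale_invariance(self):
        assert rate(3, 7) == rate(300, 700) == rate(3_000_000, 7_000_000)

    def test_rejects_bad_input(self):
        with pytest.raises(EnrichmentError):
            rate(1, 0)
        with pytest.raises(EnrichmentError):
            rate(5, 3)


class TestCharacterize:
    def test_generated_classes_ordered_as_expected(self, bundle):
        from mantlelnc.annotation_io import spliced_sequence
        from mantlelnc.coding_potential import find_longest_orf

        lncs = [bundle.assembled.get(t) for t in sorted(bundle.truth.lnc_ids)]
        mrnas = [bundle.assembled.get(t) for t in sorted(bundle.truth.coding_ids)]
        orfs = {
            t.transcript_id: find_longest_orf(
                spliced_sequence(t, bundle.genome)
            ).length
            for t in lncs + mrnas
        }
        df = characterize(
            {"lncRNA": lncs, "mRNA": mrnas},
            expr_fpkm=bundle.expression.fpkm,
            orf_lengths=orfs,
        ).set_index("class")
        assert df.loc["lncRNA", "mean_exons"] < df.loc["mRNA", "mean_exons"]
        assert df.loc["lncRNA", "mean_length"] < df.loc["mRNA", "mean_length"]
        assert df.loc["lncRNA", "mean_orf"] < df.loc["mRNA", "mean_orf"]

    def test_empty_class_no_crash(self):
        df = characterize({"empty": []}).set_index("class")
        assert df.loc["empty", "n"] == 0

    def test_orf_column_consistent_with_assessor(self, bundle):
        from mantlelnc.annotation_io import spliced_sequence
        from mantlelnc.coding_potential import assess, find_longest_orf

        tid = sorted(bundle.truth.lnc_ids)[0]
        t = bundle.assembled.get(tid)
        seq = spliced_sequence(t, bundle.genome)
        assert (
            assess(tid, seq, bundle.hexamer_model).orf_length
            == find_longest_orf(seq).length
        )


class TestTermMapIO:
    def test_round_structure(self, tmp_path):
        p = tmp_path / "terms.tsv"
        p.write_text("g1\tT1\tname one\ng2\tT1\ng3\tT2\n")
        terms = {t.term_id: t for t in read_term_map(p)}
        assert terms["T1"].annotated_genes == {"g1", "g2"}
        assert terms["T1"].term_name == "name one"
        assert terms["T2"].annotated_genes == {"g3"}
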