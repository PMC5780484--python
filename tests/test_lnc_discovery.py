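import pandas as pd
import pytest

from mantlelnc.annotation_io import AnnotationSet
from mantlelnc.coding_potential import CodingAssessment
from mantlelnc.lnc_discovery import (
    PipelineConfig,
    PipelineError,
    PositionalClass,
    classify_position,
    run_pipeline,
    step1_single_exon_distance,
    step2_length,
    step3_expression,
    step4_housekeeping,
    step5_known_mRNA,
    step6_subtype,
    step7_coding,
    step8_detection,
)
from conftest import tx


def fake_assessment(tid, noncoding=True):
    verdict = "noncoding" if noncoding else "coding"
    return CodingAssessment(tid, 0, 0.5, -0.1, {"orf": verdict, "fickett_hexamer": "noncoding"})


class TestClassifyPosition:
    """Reference gene (small_ref): 3 exons at [1000,1400), [1800,2200),
    [2600,3000) on chr1:+; rRNA at [5000,5300)."""

    def test_antisense_exonic(self, small_ref):
        t = tx("c", "chr1", "-", [(1300, 1500)])
        assert classify_position(t, small_ref) is PositionalClass.ANTISENSE_EXONIC

    def test_intronic_either_strand(self, small_ref):
        for strand in "+-":
            t = tx("c", "chr1", strand, [(1450, 1750)])
            assert classify_position(t, small_ref) is PositionalClass.INTRONIC

    def test_intergenic(self, small_ref):
        t = tx("c", "chr1", "+", [(8000, 8400)])
        assert classify_position(t, small_ref) is PositionalClass.INTERGENIC

    def test_known_mrna_exact_chain(self, small_ref):
        t = tx("c", "chr1", "+", [(1000, 1400), (1800, 2200), (2600, 3000)])
        assert classify_position(t, small_ref) is PositionalClass.KNOWN_MRNA_MATCH

    def test_known_mrna_half_overlap_same_strand(self, small_ref):
        # 400 nt transcript fully inside one coding exon, same strand
        t = tx("c", "chr1", "+", [(1000, 1400)])
        assert classify_position(t, small_ref) is PositionalClass.KNOWN_MRNA_MATCH

    def test_small_same_strand_overlap_is_other(self, small_ref):
        # 500 nt transcript sharing only 100 nt of exon, below the 50% rule
        t = tx("c", "chr1", "+", [(1300, 1800)])
        assert classify_position(t, small_ref) is PositionalClass.OTHER_OVERLAP

    def test_housekeeping_overlap(self, small_ref):
        t = tx("c", "chr1", "-", [(5100, 5400)])
        assert classify_position(t, small_ref) is PositionalClass.HOUSEKEEPING_NC

    def test_antisense_takes_precedence_over_intronic(self, small_ref):
        # exon overlap on opposite strand while the span sits inside the gene
        t = tx("c", "chr1", "-", [(1350, 1600)])
        assert classify_position(t, small_ref) is PositionalClass.ANTISENSE_EXONIC

    def test_exhaustive_and_exclusive_on_bundle(self, bundle):
        for t in bundle.assembled:
            c = classify_position(t, bundle.reference)
            assert isinstance(c, PositionalClass)


class TestCascadeSteps:
    def test_step1_distance_boundaries(self):
        target400 = tx("a", "chr1", "+", [(0, 100)])
        n400 = tx("n1", "chr1", "+", [(500, 600)])
        aset = AnnotationSet([target400, n400])
        assert step1_single_exon_distance([target400], aset) == []

        target501 = tx("b", "chr1", "+", [(0, 100)])
        n501 = tx("n2", "chr1", "+", [(601, 700)])
        aset2 = AnnotationSet([target501, n501])
        assert step1_single_exon_distance([target501], aset2) == [target501]

        exactly500 = tx("c", "chr1", "+", [(0, 100)])
        n500 = tx("n3", "chr1", "+", [(600, 700)])
        aset3 = AnnotationSet([exactly500, n500])
        assert step1_single_exon_distance([exactly500], aset3) == []

    def test_step1_multi_exon_always_passes(self):
        multi = tx("m", "chr1", "+", [(0, 100), (150, 250)])
        close = tx("n", "chr1", "+", [(350, 450)])
        aset = AnnotationSet([multi, close])
        assert step1_single_exon_distance([multi], aset) == [multi]

    @pytest.mark.parametrize("length,kept", [(199, False), (200, True), (5000, True)])
    def test_step2_length_boundary(self, length, kept):
        t = tx("t", "chr1", "+", [(0, length)])
        assert (step2_length([t]) == [t]) is kept

    @pytest.mark.parametrize(
        "exons,max_fpkm,kept",
        [
            ([(0, 300)], 1.9, False),
            ([(0, 300)], 2.0, True),
            ([(0, 150), (200, 350)], 0.5, True),
            ([(0, 150), (200, 350)], 0.49, False),
        ],
    )
    def test_step3_expression_thresholds(self, exons, max_fpkm, kept):
        t = tx("t", "chr1", "+", exons)
        fpkm = pd.DataFrame(
            {"s1": [max_fpkm], "s2": [max_fpkm / 2], "s3": [0.0], "s4": [0.0]},
            index=["t"],
        )
        assert (step3_expression([t], fpkm) == [t]) is kept

    def test_step3_missing_row_is_error(self):
        t = tx("t", "chr1", "+", [(0, 300)])
        with pytest.raises(PipelineError, match="t"):
            step3_expression([t], pd.DataFrame(columns=["s1"]))

    def test_step4_removes_only_housekeeping_class(self, small_ref):
        over_rrna = tx("r", "chr1", "+", [(5100, 5400)])
        intergenic = tx("i", "chr1", "+", [(8000, 8300)])
        classes = {
            "r": classify_position(over_rrna, small_ref),
            "i": classify_position(intergenic, small_ref),
        }
        assert step4_housekeeping([over_rrna, intergenic], classes) == [intergenic]

    def test_step4_lincrna_biotype_reference_not_removed(self):
        # a reference transcript annotated lincRNA is not in the removal list
        ref = AnnotationSet(
            [tx("l", "chr1", "+", [(100, 500)], gene="gl", biotype="lincRNA")]
        )
        t = tx("c", "chr1", "+", [(120, 480)])
        classes = {"c": classify_position(t, ref)}
        assert step4_housekeeping([t], classes) == [t]

    def test_step5_known_mrna_and_external_table(self, small_ref):
        match = tx("m", "chr1", "+", [(1000, 1400), (1800, 2200), (2600, 3000)])
        inter = tx("i", "chr1", "+", [(8000, 8300)])
        listed = tx("x", "chr1", "+", [(9000, 9300)])
        classes = {
            tid: classify_position(t, small_ref)
            for tid, t in [("m", match), ("i", inter), ("x", listed)]
        }
        out = step5_known_mRNA([match, inter, listed], classes, external_hits={"x"})
        assert out == [inter]

    def test_step6_subtype_mapping(self, small_ref):
        anti = tx("a", "chr1", "-", [(1300, 1550)])
        intr = tx("n", "chr1", "+", [(1450, 1750)])
        inter = tx("g", "chr1", "+", [(8000, 8300)])
        other = tx("o", "chr1", "+", [(1300, 1800)])
        ts = [anti, intr, inter, other]
        classes = {t.transcript_id: classify_position(t, small_ref) for t in ts}
        kept, labels = step6_subtype(ts, classes)
        assert [t.transcript_id for t in kept] == ["a", "n", "g"]
        assert labels == {"a": "antisense", "n": "intronic", "g": "lincRNA"}

    def test_step6_empty_input(self):
        assert step6_subtype([], {}) == ([], {})

    def test_step7_consensus_rule(self):
        keep = tx("k", "chr1", "+", [(0, 300)])
        drop = tx("d", "chr1", "+", [(0, 300)])
        assessments = {"k": fake_assessment("k"), "d": fake_assessment("d", noncoding=False)}
        assert step7_coding([keep, drop], assessments) == [keep]
        with pytest.raises(PipelineError):
            step7_coding([tx("u", "chr1", "+", [(0, 300)])], assessments)

    @pytest.mark.parametrize(
        "values,kept",
        [((1.2, 0.8, 2.0, 0.0), True), ((1.2, 0.0, 2.0, 0.0), False), ((1, 1, 1, 1), True)],
    )
    def test_step8_detection_counts(self, values, kept):
        t = tx("t", "chr1", "+", [(0, 300)])
        fpkm = pd.DataFrame([values], index=["t"], columns=list("abcd"))
        assert (step8_detection([t], fpkm) == [t]) is kept


class TestRunPipeline:
    def test_recovers_planted_catalog_exactly(self, bundle):
        catalog = run_pipeline(
            bundle.assembled, bundle.reference, bundle.genome,
            bundle.expression.fpkm, bundle.hexamer_model,
        )
        truth_lnc = bundle.truth.lnc_ids
        recovered = set(catalog.subtypes) & truth_lnc
        assert len(recovered) / len(truth_lnc) >= 0.95
        for tid in recovered:
            assert catalog.subtypes[tid] == bundle.truth.subtype_of(tid)
        # nothing that is not a planted lncRNA survives
        assert set(catalog.subtypes) <= truth_lnc

    def test_audit_monotone_and_consistent(self, bundle):
        catalog = run_pipeline(
            bundle.assembled, bundle.reference, bundle.genome,
            bundle.expression.fpkm, bundle.hexamer_model,
        )
        audit = catalog.audit
        assert len(audit) == 8
        for entry in audit:
            assert entry.n_out <= entry.n_in
        for prev, nxt in zip(audit, audit[1:]):
            assert nxt.n_in == prev.n_out
        assert audit[-1].n_out == len(catalog)
        assert sum(catalog.subtype_counts().values()) == len(catalog)

    def test_retained_invariants(self, bundle):
        catalog = run_pipeline(
            bundle.assembled, bundle.reference, bundle.genome,
            bundle.expression.fpkm, bundle.hexamer_model,
        )
        for tid, subtype in catalog.subtypes.items():
            assert subtype in ("lincRNA", "intronic", "antisense")
            assert catalog.models[tid].length >= 200
            assert catalog.assessments[tid].consensus_noncoding
            detected = (bundle.expression.fpkm.loc[tid] > 0).sum()
            assert detected >= 3
        assert sum(len(v) for v in catalog.loci.values()) == len(catalog)

    def test_deterministic(self, bundle):
        args = (
            bundle.assembled, bundle.reference, bundle.genome,
            bundle.expression.fpkm, bundle.hexamer_model,
        )
        assert run_pipeline(*args).subtypes == run_pipeline(*args).subtypes

    def test_empty_assembled_gives_empty_catalog(self, bundle):
        empty = AnnotationSet()
        fpkm = pd.DataFrame(columns=bundle.expression.fpkm.columns)
        catalog = run_pipeline(
            empty, bundle.reference, bundle.genome, fpkm, bundle.hexamer_model
        )
        assert len(catalog) == 0
        assert all(a.n_in == 0 and a.n_out == 0 for a in catalog.audit)

    def test_detection_step_drops_sparse_transcripts(self, bundle):
        """A planted lncRNA masked to 2 of 4 libraries is removed; one
        present in 3 of 4 is retained."""
        from mantlelnc.synthetic_data import plant_detection_pattern

        fpkm = bundle.expression.fpkm
        lncs = sorted(bundle.truth.lnc_ids)
        mask = pd.DataFrame(True, index=fpkm.index, columns=fpkm.columns)
        mask.loc[lncs[0], fpkm.columns[:2]] = False  # 2 of 4 → drop
        mask.loc[lncs[1], fpkm.columns[:1]] = False  # 3 of 4 → keep
        masked = plant_detection_pattern(fpkm, mask)
        catalog = run_pipeline(
            bundle.assembled, bundle.reference, bundle.genome, masked,
            bundle.hexamer_model,
        )
        assert lncs[0] not in catalog.subtypes
        assert lncs[1] in catalog.subtypes
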