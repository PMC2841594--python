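"""Tri-mark signature detection and bivalency-transition classification."""

import itertools

import pytest

from imprintmarks.annotations_io import EnrichmentCallSet, GenomicInterval, ValidationError
from imprintmarks.signatures import (
    BIVALENCY_STATES,
    TRI_MARKS,
    bivalency_state,
    classify_transition,
    detect_tri_mark,
    scan_icr_signature,
)
from imprintmarks.states import EXPRESSED, REPRESSED, UNKNOWN

K4, K27, K9, K20 = "H3K4me3", "H3K27me3", "H3K9me3", "H4K20me3"

REGION = GenomicInterval("chr7", 10_000, 12_000)


def _callsets(enriched_marks, ct="ESC"):
    out = []
    for mark in TRI_MARKS:
        ivs = [GenomicInterval("chr7", 10_500, 11_500)] if mark in enriched_marks else []
        out.append(EnrichmentCallSet(mark, ct, "HMM" if mark == K20 else "WI", ivs))
    return out


class TestDetectTriMark:
    @pytest.mark.parametrize(
        "enriched", [set(c) for r in range(4) for c in itertools.combinations(TRI_MARKS, r)]
    )
    def test_signature_is_conjunction_over_all_combinations(self, enriched):
        rep = detect_tri_mark("r1", REGION, _callsets(enriched))
        assert rep.signature == (enriched == set(TRI_MARKS))
        assert rep.marks == {m: m in enriched for m in TRI_MARKS}

    def test_wrong_mark_set_rejected(self):
        callsets = _callsets(set(TRI_MARKS))
        callsets[0] = EnrichmentCallSet(K27, "ESC", "WI", [])
        with pytest.raises(ValidationError, match="tri-mark"):
            detect_tri_mark("r1", REGION, callsets)

    def test_k27_reported_as_annotation_not_signature(self):
        k27 = EnrichmentCallSet(K27, "ESC", "WI", [GenomicInterval("chr7", 10_500, 11_000)])
        rep = detect_tri_mark("r1", REGION, _callsets(set(TRI_MARKS)), k27_callset=k27)
        assert rep.signature and rep.k27 is True
        rep2 = detect_tri_mark("r2", REGION, _callsets({K4, K9}), k27_callset=k27)
        assert not rep2.signature and rep2.k27 is True

    def test_region_evaluated_directly_not_via_tss_window(self):
        # A call overlapping the region but far from its midpoint still counts.
        edge = [GenomicInterval("chr7", 11_990, 12_500)]
        callsets = [
            EnrichmentCallSet(m, "ESC", "WI", edge) for m in TRI_MARKS
        ]
        assert detect_tri_mark("r", REGION, callsets).signature


class TestScan:
    def test_summary_fractions_and_flags(self):
        regions = [
            ("icr1", REGION, "promoter_icr"),
            ("icr2", GenomicInterval("chr7", 20_000, 22_000), "intergenic_icr"),
            ("gnas_like", GenomicInterval("chr7", 40_000, 42_000), "non_icr_germline_dmr"),
        ]
        ivs = [GenomicInterval("chr7", 10_000, 12_000),
               GenomicInterval("chr7", 20_000, 22_000)]
        callsets = [
            EnrichmentCallSet(m, "ESC", "HMM" if m == K20 else "WI", ivs)
            for m in TRI_MARKS
        ]
        reports, summary = scan_icr_signature(regions, callsets)
        assert summary.icr_fraction == 1.0
        assert summary.fraction("non_icr_germline_dmr") == 0.0
        assert summary.non_icr_with_signature == ()
        assert [r.signature for r in reports] == [True, True, False]

    def test_non_icr_carrier_is_flagged(self):
        regions = [("odd", REGION, "other")]
        callsets = _callsets(set(TRI_MARKS))
        _, summary = scan_icr_signature(regions, callsets)
        assert summary.non_icr_with_signature == ("odd",)

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValidationError):
            scan_icr_signature([], _callsets(set()))


class TestBivalencyState:
    @pytest.mark.parametrize(
        "k4,k27,state",
        [
            (True, True, "bivalent"),
            (True, False, "K4_only"),
            (False, True, "K27_only"),
            (False, False, "neither"),
        ],
    )
    def test_four_way_mapping(self, k4, k27, state):
        assert bivalency_state(k4, k27) == state


class TestTransitions:
    def test_total_and_deterministic_over_all_state_pairs(self):
        for frm, to in itertools.product(BIVALENCY_STATES, repeat=2):
            rec = classify_transition("g", "ESC", "NPC", frm, to)
            again = classify_transition("g", "ESC", "NPC", frm, to)
            assert rec.transition_class == again.transition_class

    def test_resolution_classes_iff_from_bivalent(self):
        for frm, to in itertools.product(BIVALENCY_STATES, repeat=2):
            rec = classify_transition("g", "ESC", "MEF", frm, to)
            is_resolution = rec.transition_class in (
                "resolved_to_K4", "resolved_to_K27", "resolved_to_none",
                "retained_bivalent",
            )
            assert is_resolution == (frm == "bivalent")

    def test_gained_marks_for_nonbivalent_to_bivalent(self):
        rec = classify_transition("g", "ESC", "NPC", "neither", "bivalent")
        assert rec.transition_class == "gained_marks"

    def test_identical_cell_types_rejected(self):
        with pytest.raises(ValidationError):
            classify_transition("g", "ESC", "ESC", "bivalent", "K4_only")

    @pytest.mark.parametrize(
        "frm_expr,to_expr,outcome",
        [
            (REPRESSED, EXPRESSED, "activated"),
            (REPRESSED, REPRESSED, "still_repressed"),
            (EXPRESSED, EXPRESSED, "still_expressed"),
            (EXPRESSED, REPRESSED, "silenced"),
            (UNKNOWN, EXPRESSED, "unknown"),
            (REPRESSED, UNKNOWN, "unknown"),
        ],
    )
    def test_expression_outcomes(self, frm_expr, to_expr, outcome):
        rec = classify_transition("g", "ESC", "NPC", "bivalent", "K4_only",
                                  frm_expr, to_expr)
        assert rec.expression_outcome == outcome


# The published worked examples: every ESC-bivalent gene row of the printed
# cross-cell-type dynamics table, encoded as (gene, target cell type,
# ESC expression, target expression, target K4, target K27) with the
# expected transition class and expression outcome.
TABLE1_ROWS = [
    ("Gatm", "NPC", REPRESSED, EXPRESSED, True, False, "resolved_to_K4", "activated"),
    ("Gatm", "MEF", REPRESSED, EXPRESSED, True, True, "retained_bivalent", "activated"),
    ("Peg12", "NPC", REPRESSED, EXPRESSED, True, False, "resolved_to_K4", "activated"),
    ("Peg12", "MEF", REPRESSED, EXPRESSED, True, False, "resolved_to_K4", "activated"),
    ("Tfpi2", "MEF", REPRESSED, EXPRESSED, False, False, "resolved_to_none", "activated"),
    ("Ascl2", "NPC", REPRESSED, REPRESSED, True, True, "retained_bivalent", "still_repressed"),
    ("Calcr", "NPC", REPRESSED, REPRESSED, False, True, "resolved_to_K27", "still_repressed"),
    ("Kcnq1", "NPC", REPRESSED, REPRESSED, False, True, "resolved_to_K27", "still_repressed"),
    ("Rasgrf", "NPC", REPRESSED, REPRESSED, True, True, "retained_bivalent", "still_repressed"),
    ("Slc22a3", "NPC", REPRESSED, REPRESSED, False, True, "resolved_to_K27", "still_repressed"),
    ("Tfpi2", "NPC", REPRESSED, REPRESSED, False, False, "resolved_to_none", "still_repressed"),
]


@pytest.mark.parametrize(
    "gene,to_ct,frm_expr,to_expr,k4,k27,expected_class,expected_outcome",
    TABLE1_ROWS,
    ids=[f"{r[0]}->{r[1]}" for r in TABLE1_ROWS],
)
def test_published_transition_rows(gene, to_ct, frm_expr, to_expr, k4, k27,
                                   expected_class, expected_outcome):
    rec = classify_transition(
        gene, "ESC", to_ct, "bivalent", bivalency_state(k4, k27), frm_expr, to_expr
    )
    assert rec.transition_class == expected_class
    assert rec.expression_outcome == expected_outcome
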