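"""ICR tri-mark signature detection and bivalency-resolution tracking.

The tri-mark signature is the joint enrichment of H3K4me3, H3K9me3 and
H4K20me3 at a region — characteristic of imprinting control regions (ICRs)
in embryonic stem cells, whether the ICR sits at a gene promoter or is
intergenic. H3K27me3 is deliberately *not* part of the signature (it is not
found at all ICRs) but can be reported as an annotation column.

Bivalency (H3K4me3 + H3K27me3 co-enrichment) is tracked across cell types:
a bivalent gene in the pluripotent state may resolve to either single mark,
to neither, or be retained upon differentiation, each coupled to an
expression outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotations_io import EnrichmentCallSet, GenomicInterval, ValidationError
from .overlap import is_enriched_at
from .states import EXPRESSED, REPRESSED, UNKNOWN

__all__ = [
    "TRI_MARKS",
    "REGION_CLASSES",
    "TriMarkReport",
    "TriMarkSummary",
    "TransitionRecord",
    "detect_tri_mark",
    "scan_icr_signature",
    "bivalency_state",
    "classify_transition",
]

K4, K27, K9, K20 = "H3K4me3", "H3K27me3", "H3K9me3", "H4K20me3"
TRI_MARKS = (K4, K9, K20)

REGION_CLASSES = ("promoter_icr", "intergenic_icr", "non_icr_germline_dmr", "other")
ICR_CLASSES = ("promoter_icr", "intergenic_icr")

BIVALENCY_STATES = ("K4_only", "K27_only", "bivalent", "neither")

RESOLUTION_CLASSES = (
    "resolved_to_K4",
    "resolved_to_K27",
    "resolved_to_none",
    "retained_bivalent",
)
TRANSITION_CLASSES = RESOLUTION_CLASSES + ("gained_marks", "not_applicable")

EXPRESSION_OUTCOMES = (
    "activated",
    "still_repressed",
    "still_expressed",
    "silenced",
    "unknown",
)


@dataclass(frozen=True)
class TriMarkReport:
    """Per-region mark booleans and the tri-mark conjunction verdict."""

    region_id: str
    marks: Mapping[str, bool]  # keyed by TRI_MARKS
    signature: bool
    region_class: str = "other"
    k27: bool | None = None  # optional annotation, never part of the signature

    def __post_init__(self) -> None:
        if self.signature != all(self.marks[m] for m in TRI_MARKS):
            raise ValidationError("signature must equal the tri-mark conjunction")


def detect_tri_mark(
    region_id: str,
    region: GenomicInterval,
    callsets: Sequence[EnrichmentCallSet],
    region_class: str = "other",
    k27_callset: EnrichmentCallSet | None = None,
) -> TriMarkReport:
    """Evaluate the three signature marks on the region itself (no TSS window).

    Exactly the H3K4me3/H3K9me3/H4K20me3 call sets of one cell type must be
    supplied; the signature is their overlap conjunction.
    """
    supplied = sorted(cs.mark for cs in callsets)
    if supplied != sorted(TRI_MARKS):
        raise ValidationError(
            f"tri-mark detection needs call sets for {TRI_MARKS}, got {supplied}"
        )
    if len({cs.cell_type for cs in callsets}) != 1:
        raise ValidationError("call sets must share one cell type")
    if region_class not in REGION_CLASSES:
        raise ValidationError(f"region_class must be one of {REGION_CLASSES}")
    marks = {cs.mark: is_enriched_at(region, cs) for cs in callsets}
    k27 = is_enriched_at(region, k27_callset) if k27_callset is not None else None
    return TriMarkReport(
        region_id=region_id,
        marks=marks,
        signature=all(marks[m] for m in TRI_MARKS),
        region_class=region_class,
        k27=k27,
    )


@dataclass
class TriMarkSummary:
    """Signature prevalence by region class, with non-ICR carriers flagged."""

    n_by_class: dict[str, int]
    signature_by_class: dict[str, int]
    non_icr_with_signature: tuple[str, ...]

    def fraction(self, region_class: str) -> float | None:
        n = self.n_by_class.get(region_class, 0)
        if n == 0:
            return None
        return self.signature_by_class.get(region_class, 0) / n

    @property
    def icr_fraction(self) -> float | None:
        n = sum(self.n_by_class.get(c, 0) for c in ICR_CLASSES)
        if n == 0:
            return None
        k = sum(self.signature_by_class.get(c, 0) for c in ICR_CLASSES)
        return k / n


def scan_icr_signature(
    regions: Sequence[tuple[str, GenomicInterval, str]],
    callsets: Sequence[EnrichmentCallSet],
    k27_callset: EnrichmentCallSet | None = None,
) -> tuple[list[TriMarkReport], TriMarkSummary]:
    """Scan annotated regions for the tri-mark signature.

    ``regions`` are (region_id, interval, region_class) triples. The summary
    gives per-class signature fractions and flags any non-ICR region
    carrying the signature.
    """
    if not regions:
        raise ValidationError("empty region list")
    reports = [
        detect_tri_mark(rid, iv, callsets, region_class=cls, k27_callset=k27_callset)
        for rid, iv, cls in regions
    ]
    n_by_class: dict[str, int] = {}
    sig_by_class: dict[str, int] = {}
    flagged = []
    for rep in reports:
        n_by_class[rep.region_class] = n_by_class.get(rep.region_class, 0) + 1
        if rep.signature:
            sig_by_class[rep.region_class] = sig_by_class.get(rep.region_class, 0) + 1
            if rep.region_class not in ICR_CLASSES:
                flagged.append(rep.region_id)
    return reports, TriMarkSummary(
        n_by_class=n_by_class,
        signature_by_class=sig_by_class,
        non_icr_with_signature=tuple(flagged),
    )


def bivalency_state(k4: bool, k27: bool) -> str:
    """Four-way state from the two bivalency marks."""
    if k4 and k27:
        return "bivalent"
    if k4:
        return "K4_only"
    if k27:
        return "K27_only"
    return "neither"


@dataclass(frozen=True)
class TransitionRecord:
    """One gene's bivalency-state change between two cell types."""

    gene_id: str
    from_cell_type: str
    to_cell_type: str
    from_state: str
    to_state: str
    from_expression: str
    to_expression: str
    transition_class: str
    expression_outcome: str


def _expression_outcome(from_expression: str, to_expression: str) -> str:
    if UNKNOWN in (from_expression, to_expression):
        return "unknown"
    if from_expression == REPRESSED:
        return "activated" if to_expression == EXPRESSED else "still_repressed"
    return "still_expressed" if to_expression == EXPRESSED else "silenced"


def classify_transition(
    gene_id: str,
    from_cell_type: str,
    to_cell_type: str,
    from_state: str,
    to_state: str,
    from_expression: str = UNKNOWN,
    to_expression: str = UNKNOWN,
) -> TransitionRecord:
    """Classify a bivalency-state change coupled to an expression outcome.

    Resolution classes apply only when the starting state is bivalent;
    a non-bivalent start that gains bivalency is ``gained_marks``; any other
    non-bivalent start is ``not_applicable``. Total and deterministic over
    all state and expression pairs.
    """
    if from_cell_type == to_cell_type:
        raise ValidationError("transition requires two distinct cell types")
    for state in (from_state, to_state):
        if state not in BIVALENCY_STATES:
            raise ValidationError(f"unknown bivalency state {state!r}")
    if from_state == "bivalent":
        transition_class = {
            "K4_only": "resolved_to_K4",
            "K27_only": "resolved_to_K27",
            "neither": "resolved_to_none",
            "bivalent": "retained_bivalent",
        }[to_state]
    elif to_state == "bivalent":
        transition_class = "gained_marks"
    else:
        transition_class = "not_applicable"
    return TransitionRecord(
        gene_id=gene_id,
        from_cell_type=from_cell_type,
        to_cell_type=to_cell_type,
        from_state=from_state,
        to_state=to_state,
        from_expression=from_expression,
        to_expression=to_expression,
        transition_class=transition_class,
        expression_outcome=_expression_outcome(from_expression, to_expression),
    )
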