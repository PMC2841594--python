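"""Integration of expression status, DMR/imprint annotation and mark profiles.

Expression status comes either from a microarray-style intensity threshold
(a gene is *repressed* if its signal intensity is strictly below the
threshold, 25 by default) or from consolidating binary calls across assays
(unanimity required; any disagreement yields *unknown*). The integrated
per-gene, per-cell-type state table keeps genes with missing layers as
*unknown* rather than dropping them, so every reported n is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotations_io import EnrichmentCallSet, GeneRecord, ValidationError
from .overlap import DEFAULT_FLANK, mark_vector
from .profiles import ProfileTaxonomy, THREE_MARK_TAXONOMY, classify_profile

__all__ = [
    "EXPRESSED",
    "REPRESSED",
    "UNKNOWN",
    "DEFAULT_INTENSITY_THRESHOLD",
    "DMRAnnotation",
    "StratifiedGroups",
    "call_expression_from_intensity",
    "consolidate_expression_calls",
    "build_state_table",
    "stratify",
]

EXPRESSED = "expressed"
REPRESSED = "repressed"
UNKNOWN = "unknown"

DEFAULT_INTENSITY_THRESHOLD = 25.0

DMR_CLASSES = ("none", "somatic", "germline")


def call_expression_from_intensity(
    intensity: float | None,
    threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> str:
    """Intensity strictly below the threshold => repressed; at/above =>
    expressed; missing => unknown. Exactly-threshold values are expressed."""
    if intensity is None or (isinstance(intensity, float) and math.isnan(intensity)):
        return UNKNOWN
    if intensity < 0:
        raise ValidationError(f"negative intensity {intensity}")
    return REPRESSED if intensity < threshold else EXPRESSED


def consolidate_expression_calls(calls: Sequence[str]) -> str:
    """Unanimous multi-assay calls keep their status; any conflict => unknown.

    Mirrors pooling of microarray and sequencing-based expression evidence,
    where only consistent data is classified.
    """
    if not calls:
        raise ValidationError("no expression calls to consolidate")
    for c in calls:
        if c not in (EXPRESSED, REPRESSED, UNKNOWN):
            raise ValidationError(f"unknown expression status {c!r}")
    informative = {c for c in calls if c != UNKNOWN}
    if len(informative) == 1:
        return informative.pop()
    return UNKNOWN


@dataclass(frozen=True)
class DMRAnnotation:
    """Promoter-DMR and imprinting-control annotation for one gene.

    ``icr`` marks a region experimentally confirmed to control imprinting;
    an ICR either sits at a germline promoter DMR or is intergenic. A
    germline DMR known *not* to act as an ICR carries
    ``non_icr_germline_flag``.
    """

    gene_id: str
    promoter_dmr: str  # none | somatic | germline
    icr: bool = False
    icr_location: str = "n/a"  # promoter | intergenic | n/a
    non_icr_germline_flag: bool = False

    def __post_init__(self) -> None:
        if self.promoter_dmr not in DMR_CLASSES:
            raise ValidationError(f"promoter_dmr must be one of {DMR_CLASSES}")
        if self.icr_location not in ("promoter", "intergenic", "n/a"):
            raise ValidationError(f"bad icr_location {self.icr_location!r}")
        if self.icr and not (
            self.promoter_dmr == "germline" or self.icr_location == "intergenic"
        ):
            raise ValidationError(
                "an ICR requires a germline promoter DMR or intergenic location"
            )
        if self.non_icr_germline_flag and self.icr:
            raise ValidationError("non-ICR germline flag contradicts icr=True")


def build_state_table(
    genes: Sequence[GeneRecord],
    callsets_by_cell_type: Mapping[str, Sequence[EnrichmentCallSet]],
    expression_by_cell_type: Mapping[str, Mapping[str, str]],
    dmr_annotations: Mapping[str, DMRAnnotation],
    imprinted_ids: set[str] | None = None,
    taxonomy: ProfileTaxonomy = THREE_MARK_TAXONOMY,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Join marks, profile label, expression and DMR status per gene x cell type.

    Returns a DataFrame with one row per (gene_id, cell_type); genes missing
    from the expression or DMR layer are retained with ``unknown`` status.
    Mark columns are booleans named after the marks present in the call
    sets of each cell type (all cell types must supply the same mark set).
    """
    if not genes:
        raise ValidationError("empty gene list")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate gene ids in input: {dupes}")

    mark_sets = {
        ct: tuple(sorted(cs.mark for cs in css))
        for ct, css in callsets_by_cell_type.items()
    }
    if len(set(mark_sets.values())) != 1:
        raise ValidationError(f"cell types supply different mark sets: {mark_sets}")
    marks = next(iter(mark_sets.values()))

    imprinted_ids = imprinted_ids or set()
    rows = []
    for ct, callsets in callsets_by_cell_type.items():
        expression = expression_by_cell_type.get(ct, {})
        for gene in genes:
            vec = mark_vector(gene, callsets, flank)
            dmr = dmr_annotations.get(gene.gene_id)
            row = {
                "gene_id": gene.gene_id,
                "cell_type": ct,
                **{m: vec.calls[m] for m in marks},
                "profile": classify_profile(vec, taxonomy),
                "expression": expression.get(gene.gene_id, UNKNOWN),
                "promoter_dmr": dmr.promoter_dmr if dmr else UNKNOWN,
                "icr": dmr.icr if dmr else False,
                "icr_location": dmr.icr_location if dmr else "n/a",
                "non_icr_germline_flag": dmr.non_icr_germline_flag if dmr else False,
                "imprinted": gene.gene_id in imprinted_ids,
            }
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.duplicated(subset=["gene_id", "cell_type"]).any():
        raise ValidationError("duplicate (gene_id, cell_type) rows")
    return table


@dataclass
class StratifiedGroups:
    """Partition of known-status rows into named groups; unknowns kept aside."""

    by: str
    cell_type: str | None
    groups: dict[str, pd.DataFrame]
    unknown: pd.DataFrame

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.groups.items()}

    @property
    def n_unknown(self) -> int:
        return len(self.unknown)


_STRATIFIERS = ("promoter_dmr", "promoter_dmr_class", "expression", "imprint_status")


def stratify(
    table: pd.DataFrame,
    by: str,
    cell_type: str | None = None,
) -> StratifiedGroups:
    """Split state-table rows into groups by one annotation layer.

    ``by="promoter_dmr"`` gives the two-way with/without-DMR split (germline
    and somatic pooled); ``"promoter_dmr_class"`` keeps the three classes;
    ``"expression"`` splits expressed/repressed; ``"imprint_status"`` splits
    imprinted vs not. Rows with unknown status for the chosen layer are
    excluded from groups but returned (and counted) separately.
    """
    if by not in _STRATIFIERS:
        raise ValidationError(f"unknown stratifier {by!r}; choose from {_STRATIFIERS}")
    sub = table if cell_type is None else table[table["cell_type"] == cell_type]

    if by in ("promoter_dmr", "promoter_dmr_class"):
        known = sub[sub["promoter_dmr"].isin(DMR_CLASSES)]
        unknown = sub[~sub["promoter_dmr"].isin(DMR_CLASSES)]
        if by == "promoter_dmr":
            groups = {
                "dmr": known[known["promoter_dmr"].isin(["somatic", "germline"])],
                "no_dmr": known[known["promoter_dmr"] == "none"],
            }
        else:
            groups = {
                cls: known[known["promoter_dmr"] == cls] for cls in DMR_CLASSES
            }
    elif by == "expression":
        known = sub[sub["expression"].isin([EXPRESSED, REPRESSED])]
        unknown = sub[~sub["expression"].isin([EXPRESSED, REPRESSED])]
        groups = {
            EXPRESSED: known[known["expression"] == EXPRESSED],
            REPRESSED: known[known["expression"] == REPRESSED],
        }
    else:  # imprint_status — always known (boolean)
        unknown = sub.iloc[0:0]
        groups = {
            "imprinted": sub[sub["imprinted"]],
            "not_imprinted": sub[~sub["imprinted"]],
        }
    return StratifiedGroups(by=by, cell_type=cell_type, groups=groups, unknown=unknown)
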