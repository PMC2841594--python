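"""TSS-window construction and interval-overlap enrichment calls.

A gene's TSS is assessed for enrichment of a mark by intersecting a
symmetric window around the (strand-aware) TSS coordinate with the mark's
merged call intervals; any >=1 bp overlap under half-open semantics counts.
The window half-width (``flank``) is an explicit, reported parameter — the
default of 1,000 bp each side is a configuration choice, not a property of
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations_io import (
    EnrichmentCallSet,
    GeneRecord,
    GenomicInterval,
    ValidationError,
)

__all__ = [
    "DEFAULT_FLANK",
    "TSSWindow",
    "MarkVector",
    "tss_window",
    "is_enriched_at",
    "mark_vector",
]

DEFAULT_FLANK = 1000  # bp each side of the TSS


@dataclass(frozen=True)
class TSSWindow:
    """Symmetric window around a gene's TSS (clamped at coordinate 0)."""

    gene_id: str
    interval: GenomicInterval
    flank: int


@dataclass(frozen=True)
class MarkVector:
    """Per-gene boolean enrichment calls for a fixed set of marks."""

    gene_id: str
    calls: Mapping[str, bool]
    cell_type: str
    methods: Mapping[str, str]

    def subset(self, marks: Sequence[str]) -> dict[str, bool]:
        missing = [m for m in marks if m not in self.calls]
        if missing:
            raise ValidationError(f"marks missing from vector: {missing}")
        return {m: self.calls[m] for m in marks}


def tss_window(gene: GeneRecord, flank: int = DEFAULT_FLANK) -> TSSWindow:
    """[TSS - flank, TSS + flank), clamped at 0; flank 0 degenerates to 1 bp.

    The annotation table stores the strand-aware TSS coordinate directly, so
    the symmetric window needs no strand arithmetic here.
    """
    if flank < 0:
        raise ValidationError(f"flank must be >= 0, got {flank}")
    if flank == 0:
        iv = GenomicInterval(gene.chrom, gene.tss, gene.tss + 1)
    else:
        iv = GenomicInterval(gene.chrom, max(0, gene.tss - flank), gene.tss + flank)
    return TSSWindow(gene.gene_id, iv, flank)


def is_enriched_at(window: GenomicInterval, callset: EnrichmentCallSet) -> bool:
    """True iff some called interval overlaps ``window`` by >=1 bp.

    A chromosome absent from the call set simply means no enrichment.
    """
    arrays = callset.arrays(window.chrom)
    if arrays is None:
        return False
    starts, ends = arrays
    # Merged + sorted: the only candidate is the last interval starting
    # before window.end; it overlaps iff it also ends after window.start.
    i = int(np.searchsorted(starts, window.end, side="left"))
    return i > 0 and int(ends[i - 1]) > window.start


def mark_vector(
    gene: GeneRecord,
    callsets: Sequence[EnrichmentCallSet],
    flank: int = DEFAULT_FLANK,
) -> MarkVector:
    """Per-mark enrichment booleans at the gene's TSS window.

    All call sets must come from one cell type; each mark may appear once.
    """
    if not callsets:
        raise ValidationError("at least one call set required")
    cell_types = {cs.cell_type for cs in callsets}
    if len(cell_types) != 1:
        raise ValidationError(f"mixed cell types in call sets: {sorted(cell_types)}")
    marks = [cs.mark for cs in callsets]
    if len(set(marks)) != len(marks):
        raise ValidationError(f"duplicate marks in call sets: {marks}")
    window = tss_window(gene, flank).interval
    calls = {cs.mark: is_enriched_at(window, cs) for cs in callsets}
    methods = {cs.mark: cs.method for cs in callsets}
    return MarkVector(gene.gene_id, calls, cell_types.pop(), methods)
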