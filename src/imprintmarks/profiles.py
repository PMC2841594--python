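"""Combinatorial mark-profile taxonomies, distributions and method concordance.

A *profile taxonomy* maps each subset of an ordered mark list to exactly one
label: named categories for the combinations of interest, "Other" for any
unnamed non-empty combination and "None" for no enrichment. Two presets
mirror the figure conventions of mined-chromatin studies: a three-mark
taxonomy (H3K4me3/H3K27me3/H3K9me3) and a two-mark bivalency taxonomy
(H3K4me3/H3K27me3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotations_io import EnrichmentCallSet, GeneRecord, ValidationError
from .overlap import DEFAULT_FLANK, MarkVector, mark_vector

__all__ = [
    "OTHER_LABEL",
    "NONE_LABEL",
    "ProfileTaxonomy",
    "ProfileDistribution",
    "ConcordanceReport",
    "THREE_MARK_TAXONOMY",
    "BIVALENCY_TAXONOMY",
    "classify_profile",
    "profile_distribution",
    "method_concordance",
]

OTHER_LABEL = "Other"
NONE_LABEL = "None"

HMM_CAVEAT = (
    "assessed with the more stringent HMM calling method; "
    "enrichment may be slightly underrepresented relative to WI-called marks"
)


@dataclass(frozen=True)
class ProfileTaxonomy:
    """Ordered marks plus named (label, exact mark subset) categories.

    Totality: every possible subset of ``marks`` maps to exactly one label
    (a named category, ``Other`` or ``None``).
    """

    marks: tuple[str, ...]
    named: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        mark_set = set(self.marks)
        if len(mark_set) != len(self.marks):
            raise ValidationError("taxonomy marks must be distinct")
        seen: set[frozenset[str]] = set()
        for label, subset in self.named:
            if not subset:
                raise ValidationError(f"named category {label!r} has empty subset")
            if not subset <= mark_set:
                raise ValidationError(
                    f"category {label!r} uses marks outside the taxonomy: "
                    f"{sorted(subset - mark_set)}"
                )
            if subset in seen:
                raise ValidationError(f"duplicate subset for category {label!r}")
            seen.add(subset)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.named) + (OTHER_LABEL, NONE_LABEL)

    def classify(self, calls: Mapping[str, bool]) -> str:
        if set(calls) != set(self.marks):
            raise ValidationError(
                f"mark vector {sorted(calls)} does not cover taxonomy marks "
                f"{sorted(self.marks)}"
            )
        enriched = frozenset(m for m, v in calls.items() if v)
        for label, subset in self.named:
            if enriched == subset:
                return label
        return NONE_LABEL if not enriched else OTHER_LABEL


K4, K27, K9, K20 = "H3K4me3", "H3K27me3", "H3K9me3", "H4K20me3"

#: Three activating/repressive marks at TSSs; named categories cover the
#: singletons plus the two co-enrichment combinations of interest
#: (bivalent K4+K27 and the imprinting-linked K4+K9).
THREE_MARK_TAXONOMY = ProfileTaxonomy(
    marks=(K4, K27, K9),
    named=(
        ("H3K4me3", frozenset({K4})),
        ("H3K27me3", frozenset({K27})),
        ("H3K4me3+H3K27me3", frozenset({K4, K27})),
        ("H3K4me3+H3K9me3", frozenset({K4, K9})),
    ),
)

#: Two-mark bivalency taxonomy used for cross-cell-type comparisons.
BIVALENCY_TAXONOMY = ProfileTaxonomy(
    marks=(K4, K27),
    named=(
        ("H3K4me3 only", frozenset({K4})),
        ("H3K27me3 only", frozenset({K27})),
        ("H3K4me3+H3K27me3", frozenset({K4, K27})),
    ),
)


def classify_profile(vector: MarkVector, taxonomy: ProfileTaxonomy) -> str:
    """Label for the vector's exact enriched-mark subset."""
    return taxonomy.classify(vector.subset(taxonomy.marks))


@dataclass
class ProfileDistribution:
    """Counts (and percentages) of profile labels over an assessed gene set."""

    cell_type: str
    taxonomy: ProfileTaxonomy
    counts: dict[str, int]
    n: int
    caveats: tuple[str, ...] = ()

    @property
    def percentages(self) -> dict[str, float]:
        return {label: 100.0 * c / self.n for label, c in self.counts.items()}

    def count(self, label: str) -> int:
        return self.counts.get(label, 0)


def profile_distribution(
    genes: Sequence[GeneRecord],
    callsets: Sequence[EnrichmentCallSet],
    taxonomy: ProfileTaxonomy = THREE_MARK_TAXONOMY,
    flank: int = DEFAULT_FLANK,
) -> ProfileDistribution:
    """Tally profile labels at the TSS windows of ``genes``.

    ``genes`` must already be resolved records (absent queries are handled —
    and reported — at the resolution stage); the call sets must share one
    cell type and include every taxonomy mark.
    """
    if not genes:
        raise ValidationError("empty gene list")
    relevant = [cs for cs in callsets if cs.mark in taxonomy.marks]
    missing = set(taxonomy.marks) - {cs.mark for cs in relevant}
    if missing:
        raise ValidationError(f"no call set for marks: {sorted(missing)}")
    counts = {label: 0 for label in taxonomy.labels}
    for gene in genes:
        vec = mark_vector(gene, relevant, flank)
        counts[classify_profile(vec, taxonomy)] += 1
    caveats = tuple(
        f"{cs.mark}: {HMM_CAVEAT}" for cs in relevant if cs.method == "HMM"
    )
    return ProfileDistribution(
        cell_type=relevant[0].cell_type,
        taxonomy=taxonomy,
        counts=counts,
        n=len(genes),
        caveats=caveats,
    )


@dataclass
class ConcordanceReport:
    """Per-gene agreement of two calling methods for one mark/cell type."""

    mark: str
    cell_type: str
    method_a: str
    method_b: str
    n: int
    n_discordant: int
    discordant_genes: tuple[str, ...] = ()

    @property
    def fraction_discordant(self) -> float:
        return self.n_discordant / self.n if self.n else 0.0


def method_concordance(
    callset_a: EnrichmentCallSet,
    callset_b: EnrichmentCallSet,
    genes: Sequence[GeneRecord],
    flank: int = DEFAULT_FLANK,
) -> ConcordanceReport:
    """Count genes whose TSS enrichment boolean differs between two methods."""
    if callset_a.mark != callset_b.mark:
        raise ValidationError(
            f"mark mismatch: {callset_a.mark} vs {callset_b.mark}"
        )
    if callset_a.cell_type != callset_b.cell_type:
        raise ValidationError(
            f"cell-type mismatch: {callset_a.cell_type} vs {callset_b.cell_type}"
        )
    discordant = []
    for gene in genes:
        va = mark_vector(gene, [callset_a], flank).calls[callset_a.mark]
        vb = mark_vector(gene, [callset_b], flank).calls[callset_b.mark]
        if va != vb:
            discordant.append(gene.gene_id)
    return ConcordanceReport(
        mark=callset_a.mark,
        cell_type=callset_a.cell_type,
        method_a=callset_a.method,
        method_b=callset_b.method,
        n=len(genes),
        n_discordant=len(discordant),
        discordant_genes=tuple(discordant),
    )
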