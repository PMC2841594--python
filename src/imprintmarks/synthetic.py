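"""Parameterized generator of complete synthetic input bundles.

The generator emulates the statistical structure of mined genome-wide
chromatin data: a genome of N genes of which a small subset is imprinted;
promoter-DMR classes (germline / somatic / none) for imprinted genes;
conditional mark enrichment at TSSs (the K9/K20 repressive pair conditional
on a germline ICR promoter, bivalency conditional on developmental
repression); per-cell-type expression with differentiation dynamics;
bivalency resolution on differentiation; two calling methods with a small
per-gene discordance rate; and interval-level realization of every
enrichment call around the TSS. Ground truth (latent classes, true mark
states, region signature indicators) is retained for recovery testing.

Geometry guarantees make the pipeline's overlap stage exact on synthetic
data: genes are laid out on a fixed grid with spacing far exceeding window
and peak widths, every realized peak covers its TSS, and decoy "noise"
intervals are placed in guaranteed-empty zones between genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import (
    EnrichmentCallSet,
    GeneRecord,
    GeneTable,
    GenomicInterval,
    ValidationError,
    read_enrichment_bed,
    read_gene_table,
    write_enrichment_bed,
    write_gene_table,
)
from .overlap import DEFAULT_FLANK
from .states import (
    DEFAULT_INTENSITY_THRESHOLD,
    DMRAnnotation,
    EXPRESSED,
    REPRESSED,
    UNKNOWN,
    call_expression_from_intensity,
    build_state_table,
)
from .profiles import ProfileTaxonomy, THREE_MARK_TAXONOMY

__all__ = [
    "MARKS",
    "MarkStateProbs",
    "SyntheticConfig",
    "SyntheticBundle",
    "SyntheticTruth",
    "generate_bundle",
    "recover_parameters",
]

K4, K27, K9, K20 = "H3K4me3", "H3K27me3", "H3K9me3", "H4K20me3"
MARKS = (K4, K27, K9, K20)

WI, HMM = "WI", "HMM"

_CATEGORIES = ("bivalent", "K4_only", "K27_only", "neither")
_RESOLUTION = ("resolved_to_K4", "resolved_to_K27", "resolved_to_none", "retained_bivalent")


@dataclass(frozen=True)
class MarkStateProbs:
    """Probabilities of the K4/K27 category given an expression status;
    the remainder goes to 'neither'."""

    bivalent: float
    k4_only: float
    k27_only: float

    def __post_init__(self) -> None:
        for p in (self.bivalent, self.k4_only, self.k27_only):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of range: {p}")
        if self.bivalent + self.k4_only + self.k27_only > 1.0 + 1e-12:
            raise ValidationError("category probabilities exceed 1")

    @property
    def neither(self) -> float:
        return max(0.0, 1.0 - self.bivalent - self.k4_only - self.k27_only)

    def as_vector(self) -> np.ndarray:
        return np.array([self.bivalent, self.k4_only, self.k27_only, self.neither])


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; defaults echo the scale and conditional
    structure of genome-wide mouse chromatin surveys (17,761 annotated
    genes, 54 imprinted of which about half carry a promoter DMR)."""

    n_genes: int = 17761
    n_imprinted: int = 54
    # P(germline, somatic, none) promoter-DMR class for imprinted genes.
    dmr_split: tuple[float, float, float] = (0.24, 0.24, 0.52)
    n_icr_intergenic: int = 4
    include_non_icr_germline_dmr: bool = True
    # Tri-mark signature probabilities by region kind.
    p_signature_icr: float = 1.0
    p_k9k20_given_germline_dmr: float = 1.0
    p_k9k20_given_somatic_dmr: float = 0.0
    p_k9k20_given_no_dmr: float = 0.0
    p_k9k20_non_icr_germline: float = 0.0
    p_background_k9k20: float = 0.005
    # Expression.
    p_expressed_dmr: float = 0.71
    p_expressed_no_dmr: float = 0.48
    p_expressed_background: float = 0.55
    p_activation: float = 0.30  # repressed in ESC -> expressed on differentiation
    p_silencing: float = 0.15  # expressed in ESC -> repressed on differentiation
    # K4/K27 category conditionals (ESC vs differentiated; K27-only is
    # absent among imprinted genes in the pluripotent state).
    esc_marks_repressed: MarkStateProbs = MarkStateProbs(0.53, 0.33, 0.0)
    esc_marks_expressed: MarkStateProbs = MarkStateProbs(0.25, 0.60, 0.0)
    diff_marks_repressed: MarkStateProbs = MarkStateProbs(0.10, 0.12, 0.35)
    diff_marks_expressed: MarkStateProbs = MarkStateProbs(0.05, 0.70, 0.0)
    background_marks: MarkStateProbs = MarkStateProbs(0.16, 0.38, 0.03)
    # Resolution of ESC-bivalent genes in each differentiated cell type.
    p_resolution: tuple[float, float, float, float] = (0.30, 0.30, 0.20, 0.20)
    # Two calling methods (per-gene flip probability between WI and HMM).
    p_method_discordance: float = 0.019
    # Per-layer missingness ("gene not present" in a study's files).
    p_missing_expression: float = 0.08
    # Interval geometry.
    cell_types: tuple[str, ...] = ("ESC", "NPC", "MEF")
    n_chromosomes: int = 19
    gene_spacing: int = 10_000
    peak_width: int = 1000
    peak_jitter: int = 300
    icr_region_width: int = 2000
    noise_rate: float = 0.02
    expression_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    seed: int = 0

    # ESC conditional shortcuts used in parameter recovery.
    @property
    def p_bivalent_given_repressed(self) -> float:
        return self.esc_marks_repressed.bivalent

    @property
    def p_bivalent_given_expressed(self) -> float:
        return self.esc_marks_expressed.bivalent

    def validate(self) -> None:
        if self.n_imprinted > self.n_genes:
            raise ValidationError("n_imprinted exceeds n_genes")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if abs(sum(self.dmr_split) - 1.0) > 1e-9:
            raise ValidationError("dmr_split must sum to 1")
        if abs(sum(self.p_resolution) - 1.0) > 1e-9:
            raise ValidationError("p_resolution must sum to 1")
        for name in (
            "p_signature_icr",
            "p_k9k20_given_germline_dmr",
            "p_k9k20_given_somatic_dmr",
            "p_k9k20_given_no_dmr",
            "p_k9k20_non_icr_germline",
            "p_background_k9k20",
            "p_expressed_dmr",
            "p_expressed_no_dmr",
            "p_expressed_background",
            "p_activation",
            "p_silencing",
            "p_method_discordance",
            "p_missing_expression",
            "noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0, 1]: {v}")
        if self.peak_jitter >= self.peak_width // 2:
            raise ValidationError("peak_jitter must be < peak_width/2 so peaks cover the TSS")
        if len(self.cell_types) < 1 or self.cell_types[0] != "ESC":
            raise ValidationError("cell_types must begin with the pluripotent 'ESC'")
        if self.gene_spacing < 4 * (self.peak_width + DEFAULT_FLANK):
            raise ValidationError("gene_spacing too small for non-interacting windows")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, indent=1)


@dataclass(frozen=True)
class RegionRecord:
    region_id: str
    interval: GenomicInterval
    region_class: str


@dataclass
class SyntheticBundle:
    """In-memory input bundle mirroring the on-disk file layout."""

    gene_table: GeneTable
    callsets: dict[tuple[str, str, str], EnrichmentCallSet]  # (cell_type, mark, method)
    expression: dict[str, dict[str, float]]  # cell_type -> gene_id -> intensity
    dmr: dict[str, DMRAnnotation]
    regions: list[RegionRecord]
    imprinted_queries: list[str]
    config_json: str = "{}"

    def callset(
        self, cell_type: str, mark: str, method: str | None = None
    ) -> EnrichmentCallSet:
        if method is None:
            method = HMM if mark == K20 else WI
        return self.callsets[(cell_type, mark, method)]

    def callsets_for(
        self, cell_type: str, marks: Sequence[str] = MARKS
    ) -> list[EnrichmentCallSet]:
        return [self.callset(cell_type, m) for m in marks]

    def cell_types(self) -> list[str]:
        return sorted({ct for ct, _, _ in self.callsets})

    def expression_status(
        self, cell_type: str, threshold: float = DEFAULT_INTENSITY_THRESHOLD
    ) -> dict[str, str]:
        return {
            gid: call_expression_from_intensity(val, threshold)
            for gid, val in self.expression.get(cell_type, {}).items()
        }

    def scan_regions(self) -> list[tuple[str, GenomicInterval, str]]:
        return [(r.region_id, r.interval, r.region_class) for r in self.regions]

    def state_table(
        self,
        genes: Sequence[GeneRecord] | None = None,
        taxonomy: ProfileTaxonomy = THREE_MARK_TAXONOMY,
        flank: int = DEFAULT_FLANK,
        threshold: float | None = None,
    ) -> pd.DataFrame:
        """Run the integration stage over this bundle (imprinted genes by
        default) and return the per-gene, per-cell-type state table."""
        if genes is None:
            from .annotations_io import resolve_gene_records

            report = resolve_gene_records(self.imprinted_queries, self.gene_table)
            genes = report.records
        threshold = self.config_dict().get("expression_threshold", DEFAULT_INTENSITY_THRESHOLD) if threshold is None else threshold
        cts = self.cell_types()
        return build_state_table(
            genes,
            {ct: self.callsets_for(ct) for ct in cts},
            {ct: self.expression_status(ct, threshold) for ct in cts},
            self.dmr,
            imprinted_ids={r.gene_id for r in genes},
            taxonomy=taxonomy,
            flank=flank,
        )

    def config_dict(self) -> dict:
        return json.loads(self.config_json)

    # ------------------------------------------------------------------ io

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "enrichment").mkdir(parents=True, exist_ok=True)
        write_gene_table(self.gene_table, outdir / "genes.tsv")
        for (ct, mark, method) in sorted(self.callsets):
            write_enrichment_bed(
                self.callsets[(ct, mark, method)],
                outdir / "enrichment" / f"{ct}_{mark}_{method}.bed",
            )
        for ct in sorted(self.expression):
            with open(outdir / f"expression_{ct}.tsv", "w") as fh:
                fh.write("gene_id\tintensity\n")
                for gid in sorted(self.expression[ct]):
                    fh.write(f"{gid}\t{self.expression[ct][gid]:.4f}\n")
        with open(outdir / "dmr_annotations.tsv", "w") as fh:
            fh.write(
                "gene_id\tpromoter_dmr\ticr\ticr_location\tnon_icr_germline_flag\n"
            )
            for gid in sorted(self.dmr):
                a = self.dmr[gid]
                fh.write(
                    f"{gid}\t{a.promoter_dmr}\t{int(a.icr)}\t{a.icr_location}\t"
                    f"{int(a.non_icr_germline_flag)}\n"
                )
        with open(outdir / "icr_regions.tsv", "w") as fh:
            fh.write("region_id\tchrom\tstart\tend\tregion_class\n")
            for r in self.regions:
                fh.write(
                    f"{r.region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                    f"{r.interval.end}\t{r.region_class}\n"
                )
        with open(outdir / "imprinted_queries.txt", "w") as fh:
            fh.write("\n".join(self.imprinted_queries) + "\n")
        with open(outdir / "bundle_config.json", "w") as fh:
            fh.write(self.config_json + "\n")

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticBundle":
        indir = Path(indir)
        gene_table = read_gene_table(indir / "genes.tsv")
        callsets: dict[tuple[str, str, str], EnrichmentCallSet] = {}
        for path in sorted((indir / "enrichment").glob("*.bed")):
            ct, mark, method = path.stem.split("_")
            callsets[(ct, mark, method)] = read_enrichment_bed(path, mark, ct, method)
        expression: dict[str, dict[str, float]] = {}
        for path in sorted(indir.glob("expression_*.tsv")):
            ct = path.stem.removeprefix("expression_")
            table = pd.read_csv(path, sep="\t")
            expression[ct] = dict(
                zip(table["gene_id"], table["intensity"].astype(float))
            )
        dmr: dict[str, DMRAnnotation] = {}
        dmr_table = pd.read_csv(
            indir / "dmr_annotations.tsv", sep="\t", keep_default_na=False
        )
        for row in dmr_table.itertuples(index=False):
            dmr[row.gene_id] = DMRAnnotation(
                gene_id=row.gene_id,
                promoter_dmr=row.promoter_dmr,
                icr=bool(row.icr),
                icr_location=row.icr_location,
                non_icr_germline_flag=bool(row.non_icr_germline_flag),
            )
        regions = []
        region_table = pd.read_csv(
            indir / "icr_regions.tsv", sep="\t", keep_default_na=False
        )
        for row in region_table.itertuples(index=False):
            regions.append(
                RegionRecord(
                    row.region_id,
                    GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    row.region_class,
                )
            )
        queries = (indir / "imprinted_queries.txt").read_text().split()
        config_json = (indir / "bundle_config.json").read_text().strip()
        return cls(
            gene_table=gene_table,
            callsets=callsets,
            expression=expression,
            dmr=dmr,
            regions=regions,
            imprinted_queries=queries,
            config_json=config_json,
        )


@dataclass
class SyntheticTruth:
    """Ground truth retained from generation.

    ``genes``: gene_id, imprinted, dmr_class, icr, non_icr_flag.
    ``states``: per gene x cell type: expression, category, k4/k27/k9/k20.
    ``transitions``: gene_id, to_cell_type, transition_class (ESC-bivalent genes).
    ``regions``: region_id, region_class, signature.
    ``discordant``: mark -> gene ids flipped between WI and HMM (ESC).
    ``missing_expression``: cell_type -> gene ids absent from that table.
    """

    config: SyntheticConfig
    genes: pd.DataFrame
    states: pd.DataFrame
    transitions: pd.DataFrame
    regions: pd.DataFrame
    discordant: dict[str, tuple[str, ...]]
    missing_expression: dict[str, tuple[str, ...]]


def _category_from_u(u: np.ndarray, probs: MarkStateProbs) -> np.ndarray:
    """Map uniforms to category indices 0..3 via the cumulative vector."""
    cum = np.cumsum(probs.as_vector())
    return np.searchsorted(cum, u, side="right").clip(0, 3)


def _peak(chrom: str, center: int, width: int, jitter: int) -> GenomicInterval:
    start = max(0, center + jitter - width // 2)
    return GenomicInterval(chrom, start, start + width)


def generate_bundle(config: SyntheticConfig) -> tuple[SyntheticBundle, SyntheticTruth]:
    """Deterministically generate an input bundle and its ground truth.

    The same (config, seed) always produces byte-identical written bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_imp = config.n_imprinted
    cts = config.cell_types
    diff_cts = cts[1:]

    # --- gene layout -----------------------------------------------------
    gene_ids = [f"imp{i:03d}" for i in range(n_imp)] + [
        f"gene{i:05d}" for i in range(n_imp, n)
    ]
    chroms = [f"chr{(i % config.n_chromosomes) + 1}" for i in range(n)]
    slots = np.arange(n) // config.n_chromosomes
    tss = slots * config.gene_spacing + config.gene_spacing // 2
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]
    records = [
        GeneRecord(
            gene_id=gene_ids[i],
            aliases=frozenset({f"NM_{100000 + i}", f"MGI:{1900000 + i}"}),
            chrom=chroms[i],
            tss=int(tss[i]),
            strand=strands[i],
        )
        for i in range(n)
    ]
    gene_table = GeneTable(records)
    imprinted = np.zeros(n, dtype=bool)
    imprinted[:n_imp] = True

    # --- latent classes --------------------------------------------------
    dmr_class = np.full(n, "none", dtype=object)
    dmr_class[:n_imp] = rng.choice(
        ["germline", "somatic", "none"], size=n_imp, p=config.dmr_split
    )
    germline_idx = np.flatnonzero((dmr_class == "germline") & imprinted)
    non_icr_flag = np.zeros(n, dtype=bool)
    if config.include_non_icr_germline_dmr and len(germline_idx) > 0:
        non_icr_flag[germline_idx[0]] = True
    icr_promoter = (dmr_class == "germline") & imprinted & ~non_icr_flag

    # Expression in the pluripotent state.
    p_expr = np.full(n, config.p_expressed_background)
    p_expr[:n_imp] = np.where(
        dmr_class[:n_imp] != "none", config.p_expressed_dmr, config.p_expressed_no_dmr
    )
    expr: dict[str, np.ndarray] = {"ESC": rng.random(n) < p_expr}
    for ct in diff_cts:
        u = rng.random(n)
        expr[ct] = np.where(
            expr["ESC"], u >= config.p_silencing, u < config.p_activation
        )

    # K9/K20 repressive pair at the TSS (pluripotent state only).
    p_pair = np.full(n, config.p_background_k9k20)
    p_pair[:n_imp] = np.select(
        [
            icr_promoter[:n_imp],
            non_icr_flag[:n_imp],
            dmr_class[:n_imp] == "somatic",
        ],
        [
            config.p_k9k20_given_germline_dmr,
            config.p_k9k20_non_icr_germline,
            config.p_k9k20_given_somatic_dmr,
        ],
        default=config.p_k9k20_given_no_dmr,
    )
    k9k20 = {"ESC": rng.random(n) < p_pair}
    for ct in diff_cts:
        k9k20[ct] = np.zeros(n, dtype=bool)

    # K4/K27 category in the pluripotent state.
    u = rng.random(n)
    cat_esc = np.where(
        imprinted,
        np.where(
            expr["ESC"],
            _category_from_u(u, config.esc_marks_expressed),
            _category_from_u(u, config.esc_marks_repressed),
        ),
        _category_from_u(u, config.background_marks),
    )
    # The repressive pair co-occurs with K4 (the tri-mark includes it):
    # force K4 on where the pair is present.
    pair = k9k20["ESC"]
    cat_esc = np.where(pair & (cat_esc == 3), 1, cat_esc)  # neither -> K4_only
    cat_esc = np.where(pair & (cat_esc == 2), 0, cat_esc)  # K27_only -> bivalent
    categories = {"ESC": cat_esc}

    # Differentiated states: ESC-bivalent genes draw a resolution class;
    # the rest re-draw their category from the differentiated conditionals.
    transitions_rows = []
    for ct in diff_cts:
        u = rng.random(n)
        resolved = _category_from_u(u, MarkStateProbs(*[
            config.p_resolution[3],  # retained -> bivalent (index 0)
            config.p_resolution[0],  # resolved_to_K4 -> K4_only (index 1)
            config.p_resolution[1],  # resolved_to_K27 -> K27_only (index 2)
        ]))  # remainder -> neither (resolved_to_none)
        redrawn = np.where(
            expr[ct],
            _category_from_u(u, config.diff_marks_expressed),
            _category_from_u(u, config.diff_marks_repressed),
        )
        was_bivalent = categories["ESC"] == 0
        categories[ct] = np.where(was_bivalent, resolved, redrawn)
        class_by_cat = {0: "retained_bivalent", 1: "resolved_to_K4",
                        2: "resolved_to_K27", 3: "resolved_to_none"}
        for i in np.flatnonzero(was_bivalent & imprinted):
            transitions_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "to_cell_type": ct,
                    "transition_class": class_by_cat[int(categories[ct][i])],
                }
            )

    # --- mark booleans ---------------------------------------------------
    marks_true: dict[tuple[str, str], np.ndarray] = {}
    for ct in cts:
        cat = categories[ct]
        marks_true[(ct, K4)] = (cat == 0) | (cat == 1)
        marks_true[(ct, K27)] = (cat == 0) | (cat == 2)
        marks_true[(ct, K9)] = k9k20[ct].copy()
        marks_true[(ct, K20)] = k9k20[ct].copy()

    # --- regions ---------------------------------------------------------
    w = config.icr_region_width
    region_rows = []
    regions: list[RegionRecord] = []
    region_signature_peaks: list[tuple[str, GenomicInterval]] = []  # (mark, peak)
    for i in np.flatnonzero(imprinted):
        cls = None
        if icr_promoter[i]:
            cls = "promoter_icr"
        elif non_icr_flag[i]:
            cls = "non_icr_germline_dmr"
        elif dmr_class[i] == "somatic":
            cls = "other"
        if cls is None:
            continue
        iv = GenomicInterval(chroms[i], max(0, int(tss[i]) - w // 2), int(tss[i]) + w // 2)
        rid = f"{cls}_{gene_ids[i]}"
        regions.append(RegionRecord(rid, iv, cls))
        sig = bool(k9k20["ESC"][i])  # promoter-region signature rides on the gene
        region_rows.append({"region_id": rid, "region_class": cls, "signature": sig})
    tail_slot = int(slots.max()) + 2
    for j in range(config.n_icr_intergenic):
        chrom = f"chr{(j % config.n_chromosomes) + 1}"
        start = (tail_slot + j // config.n_chromosomes) * config.gene_spacing
        iv = GenomicInterval(chrom, start, start + w)
        rid = f"intergenic_icr_{j:02d}"
        regions.append(RegionRecord(rid, iv, "intergenic_icr"))
        sig = bool(rng.random() < config.p_signature_icr)
        region_rows.append(
            {"region_id": rid, "region_class": "intergenic_icr", "signature": sig}
        )
        if sig:
            center = start + w // 2
            for mark in (K4, K9, K20):
                jit = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                region_signature_peaks.append(
                    (mark, _peak(chrom, center, config.peak_width, jit))
                )

    # --- interval realization -------------------------------------------
    def realize(ct: str, mark: str, enriched: np.ndarray) -> list[GenomicInterval]:
        out = []
        jitters = rng.integers(
            -config.peak_jitter, config.peak_jitter + 1, size=n
        )
        for i in np.flatnonzero(enriched):
            out.append(
                _peak(chroms[i], int(tss[i]), config.peak_width, int(jitters[i]))
            )
        # Decoy intervals in the guaranteed-empty zone of each gene slot.
        noise = rng.random(n) < config.noise_rate
        for i in np.flatnonzero(noise):
            start = int(slots[i]) * config.gene_spacing + 1000
            out.append(GenomicInterval(chroms[i], start, start + 500))
        return out

    callsets: dict[tuple[str, str, str], EnrichmentCallSet] = {}
    discordant: dict[str, list[str]] = {K4: [], K27: [], K9: []}
    for ct in cts:
        for mark in MARKS:
            method = HMM if mark == K20 else WI
            ivs = realize(ct, mark, marks_true[(ct, mark)])
            if ct == "ESC" and mark in (K4, K9, K20):
                ivs.extend(p for m, p in region_signature_peaks if m == mark)
            callsets[(ct, mark, method)] = EnrichmentCallSet(mark, ct, method, ivs)
    # Second calling method for the pluripotent state (K4/K27/K9): per-gene
    # flips at the configured discordance rate.
    for mark in (K4, K27, K9):
        flips = rng.random(n) < config.p_method_discordance
        flipped = marks_true[("ESC", mark)] ^ flips
        ivs = realize("ESC", mark, flipped)
        if mark in (K4, K9):
            ivs.extend(p for m, p in region_signature_peaks if m == mark)
        callsets[("ESC", mark, HMM)] = EnrichmentCallSet(mark, "ESC", HMM, ivs)
        discordant[mark] = [gene_ids[i] for i in np.flatnonzero(flips)]

    # --- expression tables ----------------------------------------------
    thr = config.expression_threshold
    expression: dict[str, dict[str, float]] = {}
    missing_expression: dict[str, tuple[str, ...]] = {}
    for ct in cts:
        values = np.where(
            expr[ct],
            thr + rng.gamma(shape=2.0, scale=4.0 * thr, size=n),
            rng.uniform(0.0, thr * 0.996, size=n),
        )
        missing = rng.random(n) < config.p_missing_expression
        expression[ct] = {
            gene_ids[i]: float(values[i]) for i in range(n) if not missing[i]
        }
        missing_expression[ct] = tuple(gene_ids[i] for i in np.flatnonzero(missing))

    # --- DMR annotations (imprinted genes only, as in curated lists) -----
    dmr: dict[str, DMRAnnotation] = {}
    for i in range(n_imp):
        dmr[gene_ids[i]] = DMRAnnotation(
            gene_id=gene_ids[i],
            promoter_dmr=str(dmr_class[i]),
            icr=bool(icr_promoter[i]),
            icr_location="promoter" if icr_promoter[i] else "n/a",
            non_icr_germline_flag=bool(non_icr_flag[i]),
        )

    # Query list: most by canonical id, every fifth via an accession alias.
    queries = [
        f"NM_{100000 + i}" if i % 5 == 4 else gene_ids[i] for i in range(n_imp)
    ]

    bundle = SyntheticBundle(
        gene_table=gene_table,
        callsets=callsets,
        expression=expression,
        dmr=dmr,
        regions=regions,
        imprinted_queries=queries,
        config_json=config.to_json(),
    )

    states_rows = []
    for ct in cts:
        cat = categories[ct]
        for i in range(n):
            states_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "cell_type": ct,
                    "imprinted": bool(imprinted[i]),
                    "expression": EXPRESSED if expr[ct][i] else REPRESSED,
                    "category": _CATEGORIES[int(cat[i])],
                    K4: bool(marks_true[(ct, K4)][i]),
                    K27: bool(marks_true[(ct, K27)][i]),
                    K9: bool(marks_true[(ct, K9)][i]),
                    K20: bool(marks_true[(ct, K20)][i]),
                }
            )
    truth = SyntheticTruth(
        config=config,
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "imprinted": imprinted,
                "dmr_class": dmr_class,
                "icr": icr_promoter,
                "non_icr_flag": non_icr_flag,
            }
        ),
        states=pd.DataFrame(states_rows),
        transitions=pd.DataFrame(
            transitions_rows, columns=["gene_id", "to_cell_type", "transition_class"]
        ),
        regions=pd.DataFrame(
            region_rows, columns=["region_id", "region_class", "signature"]
        ),
        discordant={m: tuple(v) for m, v in discordant.items()},
        missing_expression=missing_expression,
    )
    return bundle, truth


def recover_parameters(
    state_table: pd.DataFrame, truth: SyntheticTruth
) -> pd.DataFrame:
    """Compare pipeline-estimated conditional frequencies to the generating
    probabilities.

    Estimates are empirical frequencies over the relevant conditioning
    groups of the *pipeline output* (never the truth record); the truth
    supplies only the configured probabilities and a consistency check that
    the table and truth come from the same bundle. Returns one row per
    parameter: configured value, estimate, group size, binomial SE at the
    configured value, absolute error, and a within-3-SE flag (exact match
    required where the SE is zero).
    """
    known = set(truth.genes["gene_id"])
    if not set(state_table["gene_id"]) <= known:
        raise ValidationError("state table does not match the truth record")
    cfg = truth.config

    esc = state_table[state_table["cell_type"] == "ESC"]
    imp = esc[esc["imprinted"]]
    pair = imp[K9] & imp[K20]
    bivalent = imp[K4] & imp[K27]
    expr_known = imp["expression"].isin([EXPRESSED, REPRESSED])

    groups: list[tuple[str, float, pd.Series, pd.Series]] = [
        (
            "p_k9k20_given_germline_dmr",
            cfg.p_k9k20_given_germline_dmr,
            (imp["promoter_dmr"] == "germline") & imp["icr"],
            pair,
        ),
        (
            "p_k9k20_given_somatic_dmr",
            cfg.p_k9k20_given_somatic_dmr,
            imp["promoter_dmr"] == "somatic",
            pair,
        ),
        (
            "p_k9k20_given_no_dmr",
            cfg.p_k9k20_given_no_dmr,
            imp["promoter_dmr"] == "none",
            pair,
        ),
        (
            "p_expressed_dmr",
            cfg.p_expressed_dmr,
            imp["promoter_dmr"].isin(["germline", "somatic"]) & expr_known,
            imp["expression"] == EXPRESSED,
        ),
        (
            "p_expressed_no_dmr",
            cfg.p_expressed_no_dmr,
            (imp["promoter_dmr"] == "none") & expr_known,
            imp["expression"] == EXPRESSED,
        ),
        (
            "p_bivalent_given_repressed",
            cfg.p_bivalent_given_repressed,
            imp["expression"] == REPRESSED,
            bivalent,
        ),
        (
            "p_bivalent_given_expressed",
            cfg.p_bivalent_given_expressed,
            imp["expression"] == EXPRESSED,
            bivalent,
        ),
    ]
    rows = []
    for name, p, mask, indicator in groups:
        m = int(mask.sum())
        est = float(indicator[mask].mean()) if m else float("nan")
        se = float(np.sqrt(p * (1 - p) / m)) if m else float("nan")
        err = abs(est - p) if m else float("nan")
        within = bool(m and (err <= 3 * se if se > 0 else err == 0.0))
        rows.append(
            {
                "parameter": name,
                "configured": p,
                "estimate": est,
                "group_size": m,
                "binomial_se": se,
                "abs_error": err,
                "within_3se": within,
            }
        )
    return pd.DataFrame(rows)
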