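"""End-to-end orchestration: config, full analysis run, report bundle.

A run consumes either a synthetic bundle generated on the fly from a seed
or an on-disk bundle directory, executes every analysis stage — identifier
resolution, profile distributions, DMR/expression stratification, tri-mark
scan, bivalency transitions, method concordance, contingency tests — and
writes tab-separated tables plus one JSON summary. Reports contain no
timestamps, so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotations_io import GeneRecord, ValidationError, resolve_gene_records
from .overlap import DEFAULT_FLANK, mark_vector
from .profiles import (
    BIVALENCY_TAXONOMY,
    THREE_MARK_TAXONOMY,
    ConcordanceReport,
    method_concordance,
)
from .signatures import bivalency_state, classify_transition, scan_icr_signature
from .states import DEFAULT_INTENSITY_THRESHOLD, EXPRESSED, REPRESSED
from .stats import (
    ContingencyTable,
    contingency_chi2,
    two_group_table,
    yates_chi2_2x2,
)
from .synthetic import (
    HMM,
    K4,
    K9,
    K20,
    K27,
    MARKS,
    WI,
    SyntheticBundle,
    SyntheticConfig,
    generate_bundle,
    recover_parameters,
)

logger = logging.getLogger("imprintmarks")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Every analysis-affecting parameter of a pipeline run.

    ``mode`` is ``synthetic`` (generate inputs from ``seed`` and
    ``synthetic`` overrides) or ``bundle`` (read ``bundle_dir``).
    """

    outdir: str = "results/run"
    mode: str = "synthetic"
    bundle_dir: str | None = None
    flank: int = DEFAULT_FLANK
    expression_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    seed: int = 0
    synthetic: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "bundle"):
            raise ValidationError(f"mode must be synthetic or bundle, got {self.mode!r}")
        if self.mode == "bundle" and not self.bundle_dir:
            raise ValidationError("bundle mode requires bundle_dir")
        if self.flank <= 0:
            raise ValidationError("flank must be positive")
        if self.expression_threshold <= 0:
            raise ValidationError("expression threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        names = {f.name for f in dataclass_fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        overrides = dict(self.synthetic)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("expression_threshold", self.expression_threshold)
        return SyntheticConfig(**overrides)

    def echo(self) -> dict[str, Any]:
        return {
            "package_version": __version__,
            "mode": self.mode,
            "bundle_dir": self.bundle_dir,
            "flank": self.flank,
            "expression_threshold": self.expression_threshold,
            "seed": self.seed,
            "synthetic_overrides": self.synthetic,
        }


def _write_tsv(df: pd.DataFrame, path: Path, header: Mapping[str, Any]) -> None:
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _result_row(name: str, cell_type: str, result, n_info: str) -> dict[str, Any]:
    return {
        "comparison": name,
        "cell_type": cell_type,
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
        "yates": result.yates_applied,
        "validity": result.validity.verdict,
        "validity_reason": result.validity.reason,
        "n": n_info,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle under ``config.outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.echo()

    if config.mode == "synthetic":
        syn_config = config.synthetic_config()
        logger.info("generating synthetic bundle (seed=%d)", syn_config.seed)
        bundle, _truth = generate_bundle(syn_config)
        header["synthetic_config"] = json.loads(syn_config.to_json())
    else:
        logger.info("reading bundle from %s", config.bundle_dir)
        bundle = SyntheticBundle.read(config.bundle_dir)

    flank = config.flank
    threshold = config.expression_threshold
    cell_types = bundle.cell_types()
    summary: dict[str, Any] = {"provenance": header, "cell_types": cell_types}

    # --- (g) provenance -------------------------------------------------
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True, default=str)

    # --- identifier resolution ------------------------------------------
    resolution = resolve_gene_records(bundle.imprinted_queries, bundle.gene_table)
    res_df = pd.DataFrame(
        [{"query": q, "outcome": "matched", "gene_id": r.gene_id}
         for q, r in sorted(resolution.matched.items())]
        + [{"query": q, "outcome": "not_present", "gene_id": ""}
           for q in resolution.not_present]
        + [{"query": q, "outcome": "ambiguous", "gene_id": ""}
           for q in resolution.ambiguous]
    )
    _write_tsv(res_df, outdir / "resolution.tsv", header)
    imprinted = resolution.records
    imprinted_ids = {g.gene_id for g in imprinted}
    summary["resolution"] = {
        "n_queries": len(bundle.imprinted_queries),
        "n_matched": len(resolution.matched),
        "n_not_present": len(resolution.not_present),
        "n_ambiguous": len(resolution.ambiguous),
    }
    if not imprinted:
        raise ValidationError("no imprinted query resolved against the annotation")

    # --- per-gene mark vectors, both gene sets, every cell type ---------
    all_genes = bundle.gene_table.records()
    vectors: dict[str, dict[str, dict[str, bool]]] = {}
    for ct in cell_types:
        callsets = bundle.callsets_for(ct)
        vectors[ct] = {
            g.gene_id: mark_vector(g, callsets, flank).calls for g in all_genes
        }

    def profile_counts(
        genes: Sequence[GeneRecord], ct: str, taxonomy
    ) -> tuple[dict[str, int], int]:
        counts = {label: 0 for label in taxonomy.labels}
        for g in genes:
            calls = {m: vectors[ct][g.gene_id][m] for m in taxonomy.marks}
            counts[taxonomy.classify(calls)] += 1
        return counts, len(genes)

    # --- (a) profile distributions --------------------------------------
    dist_rows = []
    dist_summary: dict[str, Any] = {}
    for ct in cell_types:
        for set_name, genes in (("imprinted", imprinted), ("all_genes", all_genes)):
            for tax_name, taxonomy in (
                ("three_mark", THREE_MARK_TAXONOMY),
                ("bivalency", BIVALENCY_TAXONOMY),
            ):
                counts, n = profile_counts(genes, ct, taxonomy)
                for label in taxonomy.labels:
                    dist_rows.append(
                        {
                            "cell_type": ct,
                            "gene_set": set_name,
                            "taxonomy": tax_name,
                            "profile": label,
                            "count": counts[label],
                            "n": n,
                            "percent": 100.0 * counts[label] / n,
                        }
                    )
                dist_summary[f"{ct}/{set_name}/{tax_name}"] = {
                    "n": n,
                    **{label: counts[label] for label in taxonomy.labels},
                }
    dist_df = pd.DataFrame(dist_rows)
    k20_note = (
        f"{K20} callsets use the more stringent HMM method; "
        "enrichment may be slightly underrepresented relative to WI-called marks"
    )
    _write_tsv(dist_df, outdir / "profile_distributions.tsv", {**header, "caveat": k20_note})
    summary["profile_distributions"] = dist_summary

    # --- state table and stratification ----------------------------------
    state = bundle.state_table(genes=imprinted, flank=flank, threshold=threshold)
    _write_tsv(state, outdir / "state_table.tsv", header)

    tests: list[dict[str, Any]] = []

    # (b) DMR stratification: per-mark enrichment in with/without-DMR genes.
    strat_rows = []
    esc_state = state[state["cell_type"] == "ESC"]
    dmr_known = esc_state[esc_state["promoter_dmr"].isin(["none", "somatic", "germline"])]
    dmr_groups = {
        "dmr": dmr_known[dmr_known["promoter_dmr"].isin(["somatic", "germline"])],
        "no_dmr": dmr_known[dmr_known["promoter_dmr"] == "none"],
    }
    for group_name, group in dmr_groups.items():
        for mark in MARKS:
            strat_rows.append(
                {
                    "group": group_name,
                    "n": len(group),
                    "mark": mark,
                    "n_enriched": int(group[mark].sum()),
                    "percent": 100.0 * group[mark].mean() if len(group) else float("nan"),
                }
            )
    strat_df = pd.DataFrame(strat_rows)
    _write_tsv(strat_df, outdir / "stratification_dmr_ESC.tsv", header)
    summary["dmr_stratification"] = {
        "n_dmr": len(dmr_groups["dmr"]),
        "n_no_dmr": len(dmr_groups["no_dmr"]),
        "n_unknown_dmr": int(len(esc_state) - len(dmr_known)),
    }
    if all(len(g) for g in dmr_groups.values()):
        obs = [
            [int(dmr_groups[g][m].sum()) for m in MARKS] for g in ("dmr", "no_dmr")
        ]
        if min(sum(r) for r in obs) > 0 and min(sum(c) for c in zip(*obs)) > 0:
            table = ContingencyTable(
                pd.DataFrame(obs).to_numpy(),
                row_labels=("dmr", "no_dmr"),
                col_labels=MARKS,
            )
            tests.append(
                _result_row(
                    "four_mark_enrichment_dmr_vs_no_dmr",
                    "ESC",
                    contingency_chi2(table),
                    f"dmr={len(dmr_groups['dmr'])},no_dmr={len(dmr_groups['no_dmr'])}",
                )
            )

    # Expression stratification of bivalency profiles, per cell type.
    expr_rows = []
    for ct in cell_types:
        ct_state = state[state["cell_type"] == ct]
        known = ct_state[ct_state["expression"].isin([EXPRESSED, REPRESSED])]
        groups = {
            status: known[known["expression"] == status]
            for status in (EXPRESSED, REPRESSED)
        }
        counts_by_status = {}
        for status, group in groups.items():
            counts = {label: 0 for label in BIVALENCY_TAXONOMY.labels}
            for row in group.itertuples(index=False):
                counts[
                    BIVALENCY_TAXONOMY.classify(
                        {K4: getattr(row, K4), K27: getattr(row, K27)}
                    )
                ] += 1
            counts_by_status[status] = counts
            for label, count in counts.items():
                expr_rows.append(
                    {
                        "cell_type": ct,
                        "expression": status,
                        "n": len(group),
                        "profile": label,
                        "count": count,
                        "percent": 100.0 * count / len(group) if len(group) else float("nan"),
                    }
                )
        obs = [
            [counts_by_status[s][label] for label in BIVALENCY_TAXONOMY.labels]
            for s in (EXPRESSED, REPRESSED)
        ]
        if min(sum(r) for r in obs) > 0:
            nonzero_cols = [j for j in range(len(obs[0])) if sum(r[j] for r in obs) > 0]
            if len(nonzero_cols) >= 2:
                table = ContingencyTable(
                    pd.DataFrame(
                        [[r[j] for j in nonzero_cols] for r in obs]
                    ).to_numpy(),
                    row_labels=(EXPRESSED, REPRESSED),
                    col_labels=tuple(
                        BIVALENCY_TAXONOMY.labels[j] for j in nonzero_cols
                    ),
                )
                tests.append(
                    _result_row(
                        "bivalency_profiles_expressed_vs_repressed",
                        ct,
                        contingency_chi2(table),
                        f"expressed={len(groups[EXPRESSED])},repressed={len(groups[REPRESSED])}",
                    )
                )
    _write_tsv(pd.DataFrame(expr_rows), outdir / "stratification_expression.tsv", header)

    # Single-profile two-group Yates tests: imprinted vs all genes per cell type.
    for ct in cell_types:
        for tax_name, taxonomy, label in (
            ("three_mark", THREE_MARK_TAXONOMY, "H3K4me3+H3K27me3"),
            ("three_mark", THREE_MARK_TAXONOMY, "H3K4me3+H3K9me3"),
        ):
            imp_counts, n_imp = profile_counts(imprinted, ct, taxonomy)
            all_counts, n_all = profile_counts(all_genes, ct, taxonomy)
            table = two_group_table(
                imp_counts[label], n_imp, all_counts[label], n_all,
                row_labels=("imprinted", "all_genes"),
            )
            tests.append(
                _result_row(
                    f"{label}_imprinted_vs_all_genes",
                    ct,
                    yates_chi2_2x2(table),
                    f"imprinted={n_imp},all_genes={n_all}",
                )
            )

    # Cross-cell-type bivalency comparisons among imprinted genes.
    biv_counts = {}
    for ct in cell_types:
        counts, n = profile_counts(imprinted, ct, BIVALENCY_TAXONOMY)
        biv_counts[ct] = (counts["H3K4me3+H3K27me3"], n)
    ref_ct = cell_types[0] if "ESC" not in cell_types else "ESC"
    for ct in cell_types:
        if ct == ref_ct:
            continue
        k1, n1 = biv_counts[ref_ct]
        k2, n2 = biv_counts[ct]
        table = two_group_table(
            k1, n1, k2, n2, row_labels=(ref_ct, ct)
        )
        tests.append(
            _result_row(
                "bivalency_imprinted_between_cell_types",
                f"{ref_ct}_vs_{ct}",
                yates_chi2_2x2(table),
                f"{ref_ct}={n1},{ct}={n2}",
            )
        )

    # --- (c) tri-mark scan ----------------------------------------------
    scan_reports, scan_summary = scan_icr_signature(
        bundle.scan_regions(),
        [bundle.callset("ESC", m) for m in (K4, K9, K20)],
        k27_callset=bundle.callset("ESC", K27),
    )
    scan_df = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "region_class": r.region_class,
                K4: r.marks[K4],
                K9: r.marks[K9],
                K20: r.marks[K20],
                "signature": r.signature,
                "H3K27me3_annotation": r.k27,
            }
            for r in scan_reports
        ]
    )
    _write_tsv(scan_df, outdir / "trimark_scan.tsv", header)
    summary["trimark"] = {
        "n_by_class": scan_summary.n_by_class,
        "signature_by_class": scan_summary.signature_by_class,
        "icr_fraction": scan_summary.icr_fraction,
        "non_icr_with_signature": list(scan_summary.non_icr_with_signature),
    }

    # --- (d) bivalency transitions (Table-1 analogue) --------------------
    transition_rows = []
    diff_cts = [ct for ct in cell_types if ct != ref_ct]
    ref_state = state[state["cell_type"] == ref_ct].set_index("gene_id")
    for ct in diff_cts:
        to_state = state[state["cell_type"] == ct].set_index("gene_id")
        for gid in ref_state.index:
            from_biv = bivalency_state(
                bool(ref_state.loc[gid, K4]), bool(ref_state.loc[gid, K27])
            )
            if from_biv != "bivalent":
                continue
            rec = classify_transition(
                gid,
                ref_ct,
                ct,
                from_biv,
                bivalency_state(
                    bool(to_state.loc[gid, K4]), bool(to_state.loc[gid, K27])
                ),
                ref_state.loc[gid, "expression"],
                to_state.loc[gid, "expression"],
            )
            transition_rows.append(
                {
                    "gene_id": gid,
                    "from_cell_type": ref_ct,
                    "to_cell_type": ct,
                    "from_state": rec.from_state,
                    "to_state": rec.to_state,
                    "from_expression": rec.from_expression,
                    "to_expression": rec.to_expression,
                    "transition_class": rec.transition_class,
                    "expression_outcome": rec.expression_outcome,
                }
            )
    trans_df = pd.DataFrame(
        transition_rows,
        columns=[
            "gene_id", "from_cell_type", "to_cell_type", "from_state",
            "to_state", "from_expression", "to_expression",
            "transition_class", "expression_outcome",
        ],
    )
    _write_tsv(trans_df, outdir / "transitions.tsv", header)
    summary["transitions"] = {
        "n": len(trans_df),
        "by_class": {}
        if trans_df.empty
        else trans_df.groupby("transition_class").size().to_dict(),
    }

    # --- (e) method concordance ------------------------------------------
    conc_rows = []
    for mark in (K4, K27, K9):
        try:
            a = bundle.callset("ESC", mark, WI)
            b = bundle.callset("ESC", mark, HMM)
        except KeyError:
            continue
        rep = method_concordance(a, b, imprinted, flank)
        conc_rows.append(
            {
                "mark": mark,
                "cell_type": "ESC",
                "methods": f"{rep.method_a}_vs_{rep.method_b}",
                "n": rep.n,
                "n_discordant": rep.n_discordant,
                "percent_discordant": 100.0 * rep.fraction_discordant,
            }
        )
    conc_df = pd.DataFrame(
        conc_rows,
        columns=["mark", "cell_type", "methods", "n", "n_discordant", "percent_discordant"],
    )
    _write_tsv(conc_df, outdir / "concordance.tsv", header)
    summary["concordance"] = conc_rows

    # --- (f) all contingency tests ---------------------------------------
    tests_df = pd.DataFrame(tests)
    _write_tsv(tests_df, outdir / "contingency_tests.tsv", header)
    summary["contingency_tests"] = [
        {k: row[k] for k in ("comparison", "cell_type", "statistic", "p_value", "validity")}
        for row in tests
    ]

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    logger.info("report bundle written to %s", outdir)
    return summary
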