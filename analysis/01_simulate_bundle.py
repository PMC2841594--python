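"""Generate the default-scale synthetic input bundle and write it to disk.

The bundle emulates a mined genome-wide chromatin survey: 17,761 genes of
which 54 are imprinted, enrichment-call BED files per mark x cell type x
method, expression intensity tables, promoter-DMR/ICR annotations and an
imprinted-gene query list. Files go under scratch/ (they are inputs, not
results); a small summary of what was generated goes under results/.
"""

import json

from _common import RESULTS, SCRATCH, default_bundle

config, bundle, truth = default_bundle()
outdir = SCRATCH / "bundle"
bundle.write(outdir)

summary = {
    "seed": config.seed,
    "n_genes": len(bundle.gene_table),
    "n_imprinted_queries": len(bundle.imprinted_queries),
    "n_callsets": len(bundle.callsets),
    "n_regions": len(bundle.regions),
    "dmr_classes": truth.genes[truth.genes.imprinted].dmr_class.value_counts().to_dict(),
    "n_promoter_icrs": int(truth.genes.icr.sum()),
}
RESULTS.mkdir(exist_ok=True)
with open(RESULTS / "bundle_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1, sort_keys=True)

print(f"bundle written to {outdir}")
print(json.dumps(summary, indent=1, sort_keys=True))
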