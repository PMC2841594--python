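"""Shared setup for the analysis drivers: one default-scale synthetic bundle.

Every driver regenerates the same bundle from (default config, seed 1), so
each script is self-contained and all of them agree on the data.
"""

from pathlib import Path

from imprintmarks.annotations_io import resolve_gene_records
from imprintmarks.synthetic import SyntheticConfig, generate_bundle

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def default_bundle():
    config = SyntheticConfig(seed=SEED)
    bundle, truth = generate_bundle(config)
    return config, bundle, truth


def imprinted_records(bundle):
    return resolve_gene_records(bundle.imprinted_queries, bundle.gene_table).records
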