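import hypothesis
import numpy as np
import pytest

from imprintmarks.annotations_io import EnrichmentCallSet, GeneRecord, GenomicInterval

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


def make_gene(gene_id: str, chrom: str = "chr1", tss: int = 10_000, **kw) -> GeneRecord:
    kw.setdefault("aliases", frozenset({gene_id}))
    kw.setdefault("strand", "+")
    return GeneRecord(gene_id=gene_id, chrom=chrom, tss=tss, **kw)


def brute_force_overlaps(window: GenomicInterval, raw_intervals) -> bool:
    """Independent O(n) oracle: any raw (unmerged) interval overlapping."""
    return any(window.overlaps(iv) for iv in raw_intervals)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     span: int = 5000, max_len: int = 120):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_reference():
    from imprintmarks.annotations_io import GeneTable

    return GeneTable(
        [
            make_gene("Igf2", aliases=frozenset({"Igf2", "NM_010514", "Igf-II"})),
            make_gene("H19", chrom="chr7", tss=142_575_000,
                      aliases=frozenset({"H19", "NR_001592"})),
            make_gene("Peg3", chrom="chr7", tss=6_700_000,
                      aliases=frozenset({"Peg3", "Pw1", "NM_008817"})),
            # Gene sharing an alias with Peg3's "Pw1" to exercise ambiguity.
            make_gene("FakePw1", chrom="chr2", tss=500_000,
                      aliases=frozenset({"FakePw1", "Pw1"})),
        ]
    )
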