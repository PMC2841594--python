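"""Interval parsing/merging and identifier resolution."""

import gzip

import pytest
from hypothesis import given
from hypothesis import strategies as st

from imprintmarks.annotations_io import (
    EnrichmentCallSet,
    GeneRecord,
    GeneTable,
    GenomicInterval,
    ParseError,
    ValidationError,
    add_manual_records,
    parse_enrichment_intervals,
    read_enrichment_bed,
    read_gene_table,
    resolve_gene_records,
    write_enrichment_bed,
    write_gene_table,
)

from conftest import make_gene


def _parse(lines, **kw):
    return parse_enrichment_intervals(lines, "H3K4me3", "ESC", "WI", **kw)


class TestParsing:
    def test_single_line(self):
        cs = _parse(["chr7\t100\t200"])
        assert list(cs.intervals()) == [GenomicInterval("chr7", 100, 200)]

    def test_overlapping_inputs_are_merged(self):
        cs = _parse(["chr1\t0\t100", "chr1\t50\t150"])
        assert list(cs.intervals()) == [GenomicInterval("chr1", 0, 150)]

    def test_adjacent_intervals_are_merged(self):
        cs = _parse(["chr1\t0\t100", "chr1\t100\t150"])
        assert list(cs.intervals()) == [GenomicInterval("chr1", 0, 150)]

    def test_empty_stream_is_valid(self):
        assert len(_parse([])) == 0

    def test_extra_columns_ignored_and_order_irrelevant(self):
        a = _parse(["chr2\t5\t9\tpeak1\t3.2", "chr1\t1\t4"])
        b = _parse(["chr1\t1\t4", "chr2\t5\t9"])
        assert a == b

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            _parse(["chr1\t0\t10", "chr1\t5"])

    def test_non_integer_coordinate(self):
        with pytest.raises(ParseError, match="line 1"):
            _parse(["chr1\tx\t10"])

    def test_end_not_after_start_rejected(self):
        with pytest.raises(ParseError, match="exceed"):
            _parse(["chr1\t10\t10"])

    def test_one_based_dialect_flag(self):
        # 1-based inclusive [101, 200] is 0-based half-open [100, 200).
        cs = _parse(["chr1\t101\t200"], one_based=True)
        assert list(cs.intervals()) == [GenomicInterval("chr1", 100, 200)]

    def test_comment_and_track_lines_skipped(self):
        cs = _parse(["# header", "track name=x", "chr1\t0\t5"])
        assert len(cs) == 1


class TestRoundTrip:
    def test_write_then_reparse_identical(self, tmp_path, rng):
        from conftest import random_intervals

        cs = EnrichmentCallSet("H3K9me3", "ESC", "WI", random_intervals(rng, 200))
        path = tmp_path / "calls.bed"
        write_enrichment_bed(cs, path)
        again = read_enrichment_bed(path, "H3K9me3", "ESC", "WI")
        assert cs == again

    def test_gzip_input(self, tmp_path):
        path = tmp_path / "calls.bed.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr1\t10\t20\n")
        cs = read_enrichment_bed(path, "H3K4me3", "ESC", "WI")
        assert len(cs) == 1

    def test_gene_table_round_trip(self, tmp_path, small_reference):
        path = tmp_path / "genes.tsv"
        write_gene_table(small_reference, path)
        again = read_gene_table(path)
        assert sorted(again.gene_ids()) == sorted(small_reference.gene_ids())
        assert again["Peg3"].aliases == small_reference["Peg3"].aliases


interval_lists = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(0, 500),
        st.integers(1, 80),
    ).map(lambda t: GenomicInterval(t[0], t[1], t[1] + t[2])),
    max_size=40,
)


@given(interval_lists)
def test_merge_is_idempotent(ivs):
    once = EnrichmentCallSet("m", "ct", "WI", ivs)
    twice = EnrichmentCallSet("m", "ct", "WI", once.intervals())
    assert once == twice


@given(interval_lists)
def test_merged_intervals_sorted_disjoint_nonadjacent(ivs):
    cs = EnrichmentCallSet("m", "ct", "WI", ivs)
    for chrom in cs.chromosomes:
        starts, ends = cs.arrays(chrom)
        assert all(e > s for s, e in zip(starts, ends))
        # strict gaps: merged intervals neither overlap nor abut
        assert all(s2 > e1 for e1, s2 in zip(ends[:-1], starts[1:]))


class TestResolution:
    def test_alias_match(self, small_reference):
        report = resolve_gene_records(["Igf-II"], small_reference)
        assert report.matched["Igf-II"].gene_id == "Igf2"

    def test_case_insensitive_by_default(self, small_reference):
        report = resolve_gene_records(["igf2"], small_reference)
        assert report.matched["igf2"].gene_id == "Igf2"

    def test_case_sensitive_flag(self, small_reference):
        report = resolve_gene_records(["igf2"], small_reference, case_sensitive=True)
        assert report.not_present == ["igf2"]

    def test_gene_not_present(self, small_reference):
        report = resolve_gene_records(["Kcnq1ot1"], small_reference)
        assert report.not_present == ["Kcnq1ot1"]
        assert not report.matched

    def test_ambiguous_never_assigned(self, small_reference):
        report = resolve_gene_records(["Pw1"], small_reference)
        assert report.ambiguous == ["Pw1"]
        assert not report.matched

    def test_no_substring_matching(self, small_reference):
        report = resolve_gene_records(["Igf"], small_reference)
        assert report.not_present == ["Igf"]

    @given(
        st.lists(
            st.sampled_from(
                ["Igf2", "H19", "Peg3", "Pw1", "igf-ii", "Missing", "NM_008817", "x"]
            ),
            max_size=12,
        )
    )
    def test_partition_property(self, queries):
        from conftest import make_gene

        reference = GeneTable(
            [
                make_gene("Igf2", aliases=frozenset({"Igf2", "Igf-II"})),
                make_gene("Peg3", aliases=frozenset({"Peg3", "Pw1", "NM_008817"})),
                make_gene("H19"),
                make_gene("FakePw1", aliases=frozenset({"FakePw1", "Pw1"})),
            ]
        )
        report = resolve_gene_records(queries, reference)
        assert len(report.matched) + len(report.not_present) + len(
            report.ambiguous
        ) == len(set(queries))


class TestManualRecords:
    def test_manual_addition_resolves(self, small_reference):
        airn = make_gene("Airn", chrom="chr17", tss=12_740_000)
        extended = add_manual_records(small_reference, [airn])
        report = resolve_gene_records(["Airn"], extended)
        assert report.matched["Airn"].gene_id == "Airn"
        assert report.matched["Airn"].provenance == "manual"
        # original table untouched
        assert "Airn" not in small_reference

    def test_duplicate_id_rejected(self, small_reference):
        with pytest.raises(ValidationError, match="duplicate"):
            add_manual_records(small_reference, [make_gene("Igf2")])

    def test_empty_addition_is_identity(self, small_reference):
        extended = add_manual_records(small_reference, [])
        assert sorted(extended.gene_ids()) == sorted(small_reference.gene_ids())


class TestInvariants:
    def test_interval_validation(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 10)

    def test_gene_id_always_in_aliases(self):
        g = GeneRecord("Abc", frozenset({"NM_1"}), "chr1", 100, "+")
        assert "Abc" in g.aliases
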