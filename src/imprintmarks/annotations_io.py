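"""Readers, validators and identifier resolution for annotation inputs.

This module formalizes the data-extraction stage of a mined-chromatin
analysis: BED-like enrichment-call files (one per histone mark x cell type x
calling method), a gene annotation table with identifier aliases, and the
resolution of query gene lists against that table.

Conventions fixed here and relied on everywhere downstream:

* coordinates are 0-based, half-open (BED); a ``one_based`` reader flag
  converts 1-based inclusive input on the fly;
* enrichment intervals are merged on load — overlapping *or* book-ended
  (``end == next start``) intervals become one — and kept sorted per
  chromosome, so interval counts are deterministic;
* alias lookup is exact and case-insensitive by default, never substring,
  and a query hitting more than one record is reported as ambiguous rather
  than silently assigned.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "EnrichmentCallSet",
    "GeneTable",
    "ResolutionReport",
    "ParseError",
    "ValidationError",
    "parse_enrichment_intervals",
    "read_enrichment_bed",
    "write_enrichment_bed",
    "resolve_gene_records",
    "add_manual_records",
    "read_gene_table",
    "write_gene_table",
]


class ParseError(ValueError):
    """A malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """An input value violating a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must be > start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap under half-open semantics (book-ends do not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """One gene: canonical id, alias set, strand-aware TSS coordinate.

    ``tss`` is the transcription start site itself (already strand-aware, as
    stored in the annotation table); ``aliases`` always contains ``gene_id``.
    """

    gene_id: str
    aliases: frozenset[str]
    chrom: str
    tss: int
    strand: str
    species: str = "mouse"
    provenance: str = "source"  # "manual" for hand-curated additions

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"tss must be >= 0, got {self.tss}")
        if self.gene_id not in self.aliases:
            object.__setattr__(self, "aliases", self.aliases | {self.gene_id})


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals already sorted by start; merges overlaps and book-ends."""
    if len(starts) == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlap or adjacency
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class EnrichmentCallSet:
    """Enrichment calls for one mark in one cell type by one method.

    Intervals are stored per chromosome as sorted, merged (pairwise
    non-overlapping, non-adjacent) numpy start/end arrays; construction from
    any iterable of intervals normalizes them, so input order is irrelevant.
    """

    def __init__(
        self,
        mark: str,
        cell_type: str,
        method: str,
        intervals: Iterable[GenomicInterval] = (),
    ):
        if not mark or not cell_type or not method:
            raise ValidationError("mark, cell_type and method must be non-empty")
        self.mark = mark
        self.cell_type = cell_type
        self.method = method
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(per_chrom):
            pairs = sorted(per_chrom[chrom])
            starts = np.asarray([p[0] for p in pairs], dtype=np.int64)
            ends = np.asarray([p[1] for p in pairs], dtype=np.int64)
            self._chroms[chrom] = _merge_sorted(starts, ends)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        """(starts, ends) for ``chrom``, or None if absent."""
        return self._chroms.get(chrom)

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self._chroms:
            starts, ends = self._chroms[chrom]
            for s, e in zip(starts, ends):
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(se[0]) for se in self._chroms.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnrichmentCallSet):
            return NotImplemented
        return (
            self.mark == other.mark
            and self.cell_type == other.cell_type
            and self.method == other.method
            and self.chromosomes == other.chromosomes
            and all(
                np.array_equal(self._chroms[c][0], other._chroms[c][0])
                and np.array_equal(self._chroms[c][1], other._chroms[c][1])
                for c in self._chroms
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EnrichmentCallSet({self.mark}, {self.cell_type}, {self.method}, "
            f"{len(self)} intervals)"
        )


def parse_enrichment_intervals(
    stream: Iterable[str],
    mark: str,
    cell_type: str,
    method: str,
    one_based: bool = False,
) -> EnrichmentCallSet:
    """Parse BED3+ lines into a merged, sorted call set.

    Lines must be tab-delimited with at least chrom/start/end; extra columns
    are ignored, as are blank lines and ``#``/``track``/``browser`` headers.
    ``one_based=True`` declares 1-based inclusive input coordinates, which
    are converted to the 0-based half-open convention.
    """
    intervals: list[GenomicInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"expected >=3 tab-delimited columns, got {len(fields)}", lineno
            )
        chrom = fields[0]
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", lineno) from None
        if one_based:
            start -= 1
        if start < 0:
            raise ParseError(f"negative start coordinate {start}", lineno)
        if end <= start:
            raise ParseError(f"end ({end}) must exceed start ({start})", lineno)
        intervals.append(GenomicInterval(chrom, start, end))
    return EnrichmentCallSet(mark, cell_type, method, intervals)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_enrichment_bed(
    path: str | Path,
    mark: str,
    cell_type: str,
    method: str,
    one_based: bool = False,
) -> EnrichmentCallSet:
    with _open_text(path) as handle:
        return parse_enrichment_intervals(handle, mark, cell_type, method, one_based)


def write_enrichment_bed(callset: EnrichmentCallSet, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for iv in callset.intervals():
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


@dataclass
class ResolutionReport:
    """Outcome of resolving query names against a gene table.

    ``matched``, ``not_present`` and ``ambiguous`` jointly partition the
    query set; a query matching aliases of more than one record is listed in
    ``ambiguous`` and never assigned.
    """

    matched: dict[str, GeneRecord] = field(default_factory=dict)
    not_present: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)

    @property
    def records(self) -> list[GeneRecord]:
        return list(self.matched.values())


class GeneTable:
    """Reference collection of :class:`GeneRecord` with an alias index."""

    def __init__(self, records: Iterable[GeneRecord] = ()):
        self._records: dict[str, GeneRecord] = {}
        self._alias_index: dict[str, set[str]] = {}
        for rec in records:
            self._add(rec)

    def _add(self, rec: GeneRecord) -> None:
        if rec.gene_id in self._records:
            raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
        self._records[rec.gene_id] = rec
        for alias in rec.aliases:
            self._alias_index.setdefault(alias.casefold(), set()).add(rec.gene_id)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    def records(self) -> list[GeneRecord]:
        return list(self._records.values())

    def gene_ids(self) -> list[str]:
        return list(self._records)

    def lookup(self, name: str, case_sensitive: bool = False) -> set[str]:
        """Gene ids whose id or aliases match ``name`` exactly."""
        hits = self._alias_index.get(name.casefold(), set())
        if case_sensitive:
            hits = {g for g in hits if name in self._records[g].aliases}
        return set(hits)


def resolve_gene_records(
    query_names: Sequence[str],
    reference: GeneTable,
    case_sensitive: bool = False,
) -> ResolutionReport:
    """Resolve query names by exact id/alias lookup.

    Every distinct query lands in exactly one of matched / not_present /
    ambiguous ("Gene not present" outcomes are data, not errors); repeated
    query names are resolved once, preserving first-seen order.
    """
    report = ResolutionReport()
    seen: set[str] = set()
    for name in query_names:
        if name in seen:
            continue
        seen.add(name)
        if not name:
            raise ValidationError("query names must be non-empty")
        hits = reference.lookup(name, case_sensitive=case_sensitive)
        if len(hits) == 0:
            report.not_present.append(name)
        elif len(hits) > 1:
            report.ambiguous.append(name)
        else:
            report.matched[name] = reference[next(iter(hits))]
    return report


def add_manual_records(
    reference: GeneTable, records: Sequence[GeneRecord]
) -> GeneTable:
    """Return a new table extended with hand-curated records.

    Mirrors the manual addition of genes absent from every source file (for
    instance unconfirmed non-coding RNAs); each added record carries
    ``provenance="manual"``. Duplicate gene ids are an error.
    """
    merged = GeneTable(reference.records())
    for rec in records:
        merged._add(replace(rec, provenance="manual"))
    return merged


_GENE_TABLE_COLUMNS = ["gene_id", "aliases", "chrom", "tss", "strand", "species"]


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a tab-delimited gene annotation table (optionally gzipped).

    Header columns: gene_id, aliases (pipe-separated), chrom, tss, strand,
    species. An optional ``provenance`` column is honoured.
    """
    with _open_text(path) as handle:
        header_line = handle.readline()
        if not header_line:
            raise ParseError("empty gene table", 1)
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _GENE_TABLE_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"missing columns: {missing}", 1)
        idx = {c: header.index(c) for c in header}
        records = []
        for lineno, raw in enumerate(handle, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(fields)}", lineno
                )
            try:
                tss = int(fields[idx["tss"]])
            except ValueError:
                raise ParseError(
                    f"non-integer tss {fields[idx['tss']]!r}", lineno
                ) from None
            aliases = frozenset(
                a for a in fields[idx["aliases"]].split("|") if a
            )
            records.append(
                GeneRecord(
                    gene_id=fields[idx["gene_id"]],
                    aliases=aliases,
                    chrom=fields[idx["chrom"]],
                    tss=tss,
                    strand=fields[idx["strand"]],
                    species=fields[idx["species"]],
                    provenance=fields[idx["provenance"]]
                    if "provenance" in idx
                    else "source",
                )
            )
    return GeneTable(records)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(_GENE_TABLE_COLUMNS + ["provenance"]) + "\n")
        for rec in table.records():
            aliases = "|".join(sorted(rec.aliases))
            handle.write(
                f"{rec.gene_id}\t{aliases}\t{rec.chrom}\t{rec.tss}\t"
                f"{rec.strand}\t{rec.species}\t{rec.provenance}\n"
            )
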