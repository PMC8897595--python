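"""Repeat-annotation parsing and major-satellite region selection.

Mouse major satellites (RepeatMasker name ``GSAT_MM``) are ~234 bp AT-rich
tandem repeats forming pericentromeric arrays that can span tens of
kilobases.  This module parses RepeatMasker annotations (both the classic
``.out`` file and the UCSC ``rmsk`` table dialect), filters them by repeat
name, selects regions above a length threshold (optionally merging nearby
annotations first) and attaches genomic sequence from a FASTA file.

Coordinate conventions
----------------------
Internally every interval is **0-based, half-open** (BED-style).  The two
supported input dialects differ:

- ``out``: RepeatMasker ``.out`` files are 1-based, inclusive; strand is
  ``+`` or ``C`` (complement).
- ``ucsc_table``: the UCSC ``rmsk`` table is already 0-based half-open.

Both are normalised on parse, so the same physical interval yields the same
internal coordinates regardless of dialect.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RepeatAnnotation",
    "SatelliteRegion",
    "AnnotationParseError",
    "parse_annotations",
    "filter_by_name",
    "select_regions",
    "attach_sequences",
    "write_regions_bed",
]

DIALECTS = ("out", "ucsc_table")


class AnnotationParseError(ValueError):
    """Raised when a mandatory annotation column cannot be parsed.

    The message names the offending line number and column.
    """


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat hit, in internal 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SatelliteRegion:
    """A selected genomic interval, possibly merged from several annotations."""

    chrom: str
    start: int
    end: int
    source_annotation_ids: list[int] = field(default_factory=list)
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _parse_int(token: str, line_no: int, column: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise AnnotationParseError(
            f"line {line_no}: cannot parse column '{column}' from {token!r}"
        ) from None


def _parse_out_line(fields: Sequence[str], line_no: int) -> RepeatAnnotation:
    # .out columns: score div del ins query begin end (left) strand repeat class ...
    if len(fields) < 11:
        raise AnnotationParseError(
            f"line {line_no}: expected >= 11 whitespace-separated columns, "
            f"got {len(fields)}"
        )
    score = float(_parse_int(fields[0], line_no, "score"))
    chrom = fields[4]
    begin = _parse_int(fields[5], line_no, "begin")
    end = _parse_int(fields[6], line_no, "end")
    strand = "-" if fields[8] in ("C", "-") else "+"
    return RepeatAnnotation(
        chrom=chrom,
        start=begin - 1,  # 1-based inclusive -> 0-based half-open
        end=end,
        strand=strand,
        repeat_name=fields[9],
        repeat_class=fields[10],
        score=score,
    )


def _parse_ucsc_line(fields: Sequence[str], line_no: int) -> RepeatAnnotation:
    # rmsk columns: bin swScore milliDiv milliDel milliIns genoName genoStart
    #               genoEnd genoLeft strand repName repClass repFamily ...
    if len(fields) < 13:
        raise AnnotationParseError(
            f"line {line_no}: expected >= 13 tab-separated columns, "
            f"got {len(fields)}"
        )
    score = float(_parse_int(fields[1], line_no, "swScore"))
    return RepeatAnnotation(
        chrom=fields[5],
        start=_parse_int(fields[6], line_no, "genoStart"),
        end=_parse_int(fields[7], line_no, "genoEnd"),
        strand=fields[9],
        repeat_name=fields[10],
        repeat_class=fields[11],
        score=score,
    )


def parse_annotations(path: str | Path, dialect: str) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker annotation file into internal coordinates.

    Parameters
    ----------
    path:
        Annotation file.
    dialect:
        ``"out"`` (RepeatMasker .out, 1-based inclusive) or ``"ucsc_table"``
        (UCSC rmsk dump, 0-based half-open).

    Header and comment lines are skipped; a malformed mandatory column raises
    :class:`AnnotationParseError` naming the line and column.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    annotations: list[RepeatAnnotation] = []
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "out":
                fields = line.split()
                # .out header lines start with the literal column captions
                if fields[0] in ("SW", "score") or fields[0].startswith("---"):
                    continue
                annotations.append(_parse_out_line(fields, line_no))
            else:
                fields = line.split("\t")
                if fields[0].startswith("#") or fields[0] == "bin":
                    continue
                annotations.append(_parse_ucsc_line(fields, line_no))
    return annotations


def filter_by_name(
    annotations: Iterable[RepeatAnnotation],
    name_pattern: str = "GSAT_MM",
    glob: bool = False,
) -> list[RepeatAnnotation]:
    """Keep annotations whose repeat name matches ``name_pattern``.

    Exact string match by default; with ``glob=True`` the pattern is an
    fnmatch-style glob (e.g. ``"GSAT*"``).
    """
    if glob:
        return [a for a in annotations if fnmatch.fnmatchcase(a.repeat_name, name_pattern)]
    return [a for a in annotations if a.repeat_name == name_pattern]


def select_regions(
    annotations: Sequence[RepeatAnnotation],
    min_length: int = 20_000,
    merge_gap: int = 0,
) -> list[SatelliteRegion]:
    """Merge nearby annotations and keep regions of at least ``min_length`` bp.

    Same-chromosome annotations whose gap is <= ``merge_gap`` (overlapping or
    bookended annotations always merge) are coalesced into one region; merged
    regions shorter than ``min_length`` are discarded.  Output is sorted by
    (chrom, start) and retains the indices of the contributing annotations
    within the input sequence.

    With the default ``merge_gap=0`` only overlapping/adjacent annotations
    merge, so the operation reduces to per-annotation length filtering for
    disjoint inputs.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be non-negative")
    indexed = sorted(
        enumerate(annotations), key=lambda ia: (ia[1].chrom, ia[1].start, ia[1].end)
    )
    merged: list[SatelliteRegion] = []
    for idx, ann in indexed:
        if (
            merged
            and merged[-1].chrom == ann.chrom
            and ann.start - merged[-1].end <= merge_gap
        ):
            merged[-1].end = max(merged[-1].end, ann.end)
            merged[-1].source_annotation_ids.append(idx)
        else:
            merged.append(
                SatelliteRegion(
                    chrom=ann.chrom,
                    start=ann.start,
                    end=ann.end,
                    source_annotation_ids=[idx],
                )
            )
    return [r for r in merged if r.length >= min_length]


def attach_sequences(
    regions: Sequence[SatelliteRegion], fasta: str | Path
) -> list[SatelliteRegion]:
    """Attach uppercased genomic sequence to each region from a FASTA file.

    Regions on contigs absent from the FASTA raise ``KeyError`` listing the
    missing contig names; a region extending past its contig end raises
    ``ValueError``.  Returns new region objects; the inputs are not mutated.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    missing = sorted({r.chrom for r in regions if r.chrom not in fa})
    if missing:
        raise KeyError(f"contigs missing from FASTA: {', '.join(missing)}")
    out: list[SatelliteRegion] = []
    for r in regions:
        contig_len = len(fa[r.chrom])
        if r.end > contig_len:
            raise ValueError(
                f"region {r.region_id} extends past end of contig "
                f"{r.chrom} (length {contig_len})"
            )
        seq = str(fa[r.chrom][r.start : r.end])
        if len(seq) != r.length:
            raise ValueError(
                f"extracted sequence length {len(seq)} != region length {r.length} "
                f"for {r.region_id}"
            )
        out.append(
            SatelliteRegion(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                source_annotation_ids=list(r.source_annotation_ids),
                sequence=seq,
            )
        )
    return out


def write_regions_bed(
    regions: Sequence[SatelliteRegion], path: str | Path, name: str = "GSAT_MM"
) -> None:
    """Write regions as BED6 (name=<label>:<i>, score=length, strand='+')."""
    with open(path, "w") as handle:
        for i, r in enumerate(regions):
            handle.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}:{i}\t{r.length}\t+\n"
            )
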