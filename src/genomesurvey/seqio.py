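"""Sequence and annotation I/O plus the interval algebra shared by every stage.

All internal coordinates are 0-based half-open.  Conversion to and from
1-based-inclusive conventions (GFF3 on disk) happens only at the file
boundary, so downstream modules never see mixed conventions.

FASTA parsing and writing is delegated to Bio.SeqIO; BED and GFF3 records are
flat enough that they are split directly, which lets errors carry line
numbers.  All readers are transparent to gzip (".gz" suffix).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")
_N_RUN = re.compile(r"N+")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """An input file violates its declared format."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold: identifier plus an uppercase A/C/G/T/N nucleotide string."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scaffold name must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"scaffold {self.name!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped_length(self) -> int:
        return len(self.seq) - self.seq.count("N")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a scaffold with a free-text label."""

    scaffold: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Scaffold-grouped interval collection backed by interval trees.

    Query results are independent of insertion order; overlapping members are
    allowed.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._count = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.scaffold, IntervalTree()).addi(iv.start, iv.end, iv)
        self._count += 1

    def __len__(self) -> int:
        return self._count

    def __iter__(self) -> Iterator[GenomicInterval]:
        for scaffold in sorted(self._trees):
            for node in sorted(self._trees[scaffold]):
                yield node.data

    def __bool__(self) -> bool:
        return self._count > 0

    def scaffolds(self) -> list[str]:
        return sorted(self._trees)

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        return sorted(node.data for node in tree.overlap(start, end))

    def overlaps(self, scaffold: str, start: int, end: int) -> bool:
        tree = self._trees.get(scaffold)
        return tree is not None and bool(tree.overlap(start, end))

    def total_bp(self) -> int:
        """Summed interval lengths (overlaps counted once)."""
        return sum(len(iv) for iv in self.merged())

    def merged(self) -> "IntervalSet":
        """Union of members: overlapping/abutting intervals coalesced, labels dropped."""
        out = IntervalSet()
        for scaffold in sorted(self._trees):
            spans = sorted((n.begin, n.end) for n in self._trees[scaffold])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.add(GenomicInterval(scaffold, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.add(GenomicInterval(scaffold, cur_s, cur_e))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into an ordered list of GenomeSequence.

    Sequences are uppercased; IUPAC ambiguity codes other than N are converted
    to N (the conversion count is logged).  Duplicate scaffold names and
    malformed/empty input raise :class:`FormatError`.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: malformed FASTA header at line 1")
        fh.seek(0)
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    converted = 0
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate scaffold name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned, n_sub = _NON_ACGTN.subn("N", seq)
        converted += n_sub
        out.append(GenomeSequence(rec.id, cleaned))
    if converted:
        log.info("read_fasta(%s): converted %d non-ACGTN bases to N", path, converted)
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in seqs]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

_GFF_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF_NAME = re.compile(r"(?:^|;)\s*Name=([^;]+)")


def read_intervals(
    path: str | Path,
    format: str = "bed",
    feature_type: str = "gene",
) -> IntervalSet:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive on disk) intervals.

    GFF3 is restricted to records of ``feature_type``; the label carries the
    feature ID (falling back to Name, then to a positional tag).  BED strand
    and score columns are read but ignored.
    """
    fmt = format.lower()
    if fmt not in {"bed", "gff3", "gff"}:
        raise ValueError(f"unknown interval format {format!r}")
    out = IntervalSet()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 columns")
                    scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    if fields[2] != feature_type:
                        continue
                    scaffold = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    attrs = fields[8]
                    m = _GFF_ID.search(attrs) or _GFF_NAME.search(attrs)
                    label = m.group(1) if m else f"{scaffold}:{start}-{end}"
                if end <= start:
                    raise ValueError(f"end <= start after conversion ({start},{end})")
                out.add(GenomicInterval(scaffold, start, end, label))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if iv.label:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def interval_overlap(a: IntervalSet, b: IntervalSet, mode: str = "intersect"):
    """Interval algebra between two sets under half-open ≥1-bp-overlap semantics.

    mode="intersect" returns the overlapping sub-intervals of members of *a*
    with the union of *b*; mode="subtract" returns the parts of *a* not
    covered by *b*; mode="any_hit" returns ``{interval_of_a: bool}``.
    """
    if mode == "any_hit":
        return {iv: b.overlaps(iv.scaffold, iv.start, iv.end) for iv in a}
    if mode not in {"intersect", "subtract"}:
        raise ValueError(f"unknown overlap mode {mode!r}")
    b_merged = b.merged()
    out = IntervalSet()
    for iv in a:
        hits = b_merged.overlapping(iv.scaffold, iv.start, iv.end)
        if mode == "intersect":
            for h in hits:
                s, e = max(iv.start, h.start), min(iv.end, h.end)
                if s < e:
                    out.add(GenomicInterval(iv.scaffold, s, e, iv.label))
        else:  # subtract
            cursor = iv.start
            for h in hits:
                if h.start > cursor:
                    out.add(GenomicInterval(iv.scaffold, cursor, h.start, iv.label))
                cursor = max(cursor, h.end)
            if cursor < iv.end:
                out.add(GenomicInterval(iv.scaffold, cursor, iv.end, iv.label))
    return out


def detect_gaps(seq: GenomeSequence, min_run: int = 1) -> IntervalSet:
    """Maximal runs of N of length >= min_run, as intervals."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out = IntervalSet()
    for m in _N_RUN.finditer(seq.seq):
        if m.end() - m.start() >= min_run:
            out.add(GenomicInterval(seq.name, m.start(), m.end(), "gap"))
    return out


def assembly_gaps(seqs: Iterable[GenomeSequence], min_run: int = 1) -> IntervalSet:
    out = IntervalSet()
    for s in seqs:
        for iv in detect_gaps(s, min_run):
            out.add(iv)
    return out
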