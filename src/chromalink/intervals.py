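"""Genomic intervals, BED/BEDPE/annotation I/O and the overlap engine.

All coordinates are 0-based half-open (BED convention) throughout the
package; readers for 1-based formats would convert at the boundary.
Chromosome names are matched exactly — no "chr" aliasing — and
:func:`check_shared_chromosomes` warns when two inputs share none.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "LoopRecord",
    "PeakSet",
    "Gene",
    "GeneAnnotation",
    "BedParseError",
    "ValidationError",
    "read_bed",
    "write_bed",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "overlap_pairs",
    "subtract",
    "check_shared_chromosomes",
]


class BedParseError(ValueError):
    """Malformed line in a BED-family file; message names the line number."""


class ValidationError(ValueError):
    """Domain invariant violated (negative strength, duplicate id, ...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_width(other) >= min_bp

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def _canonical_anchor_order(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[GenomicInterval, GenomicInterval]:
    if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end):
        return a, b
    return b, a


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop: two anchors plus a nonnegative strength.

    Anchors are stored canonically ordered by (chrom, start, end) so the
    same physical loop always gets the same identity regardless of the
    order it was written in.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    loop_id: str
    strength: float

    def __post_init__(self) -> None:
        a, b = _canonical_anchor_order(self.anchor_a, self.anchor_b)
        object.__setattr__(self, "anchor_a", a)
        object.__setattr__(self, "anchor_b", b)
        if self.strength < 0:
            raise ValidationError(
                f"loop {self.loop_id}: negative strength {self.strength}"
            )

    @staticmethod
    def make_id(a: GenomicInterval, b: GenomicInterval) -> str:
        a, b = _canonical_anchor_order(a, b)
        return f"{a.chrom}:{a.start}-{a.end}|{b.chrom}:{b.start}-{b.end}"


@dataclass
class PeakSet:
    """A sample's called peaks, kept sorted by (chrom, start, end)."""

    sample_id: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    body: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: body start on '+', last base on '-'."""
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass
class GeneAnnotation:
    """Gene bodies with unique ids, queryable by id."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene_id in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


# ---------------------------------------------------------------------------
# Readers / writers. All outputs are tab-separated; header lines start '#'.
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coord(text: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise BedParseError(
            f"{path}:{lineno}: non-integer coordinate {text!r}"
        ) from None


def read_bed(path: str | Path, sample_id: str | None = None) -> PeakSet:
    """Read BED3+/narrowPeak into a :class:`PeakSet`.

    Columns 4 and 5 are kept as interval name and score when present
    (narrowPeak's extra columns beyond 5 are ignored).
    """
    intervals = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
        start = _parse_coord(cols[1], path, lineno)
        end = _parse_coord(cols[2], path, lineno)
        if start >= end:
            raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
        score = None
        if len(cols) > 4 and cols[4] not in ("", "."):
            try:
                score = float(cols[4])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-numeric score {cols[4]!r}"
                ) from None
        intervals.append(GenomicInterval(cols[0], start, end, name, score))
    return PeakSet(sample_id or Path(path).stem, intervals)


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for iv in ivs:
            name = iv.name if iv.name is not None else "."
            score = repr(iv.score) if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_bedpe_loops(path: str | Path) -> list[LoopRecord]:
    """Read a 7/8-column BEDPE of loop strengths.

    Columns: chrom1 start1 end1 chrom2 start2 end2 strength [loop_id].
    Anchors are canonicalized; a missing loop_id is synthesized from the
    anchor coordinates. Duplicate ids or negative strengths are errors.
    """
    records: list[LoopRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 7:
            raise BedParseError(f"{path}:{lineno}: fewer than 7 columns")
        a = GenomicInterval(
            cols[0],
            _parse_coord(cols[1], path, lineno),
            _parse_coord(cols[2], path, lineno),
        )
        b = GenomicInterval(
            cols[3],
            _parse_coord(cols[4], path, lineno),
            _parse_coord(cols[5], path, lineno),
        )
        try:
            strength = float(cols[6])
        except ValueError:
            raise BedParseError(
                f"{path}:{lineno}: non-numeric strength {cols[6]!r}"
            ) from None
        if strength < 0:
            raise ValidationError(f"{path}:{lineno}: negative strength {strength}")
        loop_id = (
            cols[7] if len(cols) > 7 and cols[7] not in ("", ".") else LoopRecord.make_id(a, b)
        )
        if loop_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate loop_id {loop_id!r}")
        seen.add(loop_id)
        records.append(LoopRecord(a, b, loop_id, strength))
    return records


def write_bedpe_loops(records: Sequence[LoopRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tstrength\tloop_id\n"
        )
        for r in records:
            a, b = r.anchor_a, r.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{r.strength!r}\t{r.loop_id}\n"
            )


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a 6-column BED-like gene table: chrom start end gene_id symbol strand."""
    genes = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise BedParseError(f"{path}:{lineno}: fewer than 6 columns")
        body = GenomicInterval(
            cols[0],
            _parse_coord(cols[1], path, lineno),
            _parse_coord(cols[2], path, lineno),
        )
        genes.append(Gene(cols[3], cols[4], body, cols[5]))
    return GeneAnnotation(genes)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tsymbol\tstrand\n")
        for g in ann:
            fh.write(
                f"{g.body.chrom}\t{g.body.start}\t{g.body.end}\t"
                f"{g.gene_id}\t{g.symbol}\t{g.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise BedParseError(f"{path}:{lineno}: fewer than 2 columns")
        sizes[cols[0]] = _parse_coord(cols[1], path, lineno)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tlength\n")
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------


def overlap_pairs(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> set[tuple[int, int]]:
    """All index pairs (i, j) where a[i] and b[j] overlap by >= min_bp bases.

    Backed by one interval tree per chromosome of ``b``; half-open
    abutting intervals do not overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(b):
        trees[iv.chrom].addi(iv.start, iv.end, j)
    pairs: set[tuple[int, int]] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                pairs.add((i, hit.data))
    return pairs


def subtract(a: PeakSet, b: PeakSet, min_bp: int = 1) -> PeakSet:
    """Whole-peak set difference: peaks of ``a`` overlapping nothing in ``b``.

    Peaks are never trimmed; any overlap of >= min_bp removes the whole peak.
    """
    hit_a = {i for i, _ in overlap_pairs(a.intervals, b.intervals, min_bp=min_bp)}
    kept = [iv for i, iv in enumerate(a.intervals) if i not in hit_a]
    return PeakSet(a.sample_id, kept)


def check_shared_chromosomes(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval], context: str = ""
) -> bool:
    """Warn (and return False) when two interval collections share no chromosome."""
    ca = {iv.chrom for iv in a}
    cb = {iv.chrom for iv in b}
    if ca and cb and not (ca & cb):
        warnings.warn(
            f"no chromosome name shared between inputs{f' ({context})' if context else ''}; "
            "check naming conventions (chromosomes are matched exactly)",
            stacklevel=2,
        )
        return False
    return True


class MarkIndex:
    """Fast point-in-time overlap queries against a fixed interval set.

    Used by the permutation null, where millions of membership queries are
    made against the same repressive-mark intervals: per chromosome the
    intervals are sorted by start and a running maximum of ends lets a
    single binary search decide whether a query interval hits anything.
    """

    def __init__(self, marks: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in marks:
            per_chrom[iv.chrom].append((iv.start, iv.end))
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            maxend = []
            running = 0
            for _, e in ivs:
                running = max(running, e)
                maxend.append(running)
            self._starts[chrom] = starts
            self._maxend[chrom] = maxend

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        # marks with start < end, among those need max end > start
        idx = bisect_left(starts, end)
        return idx > 0 and self._maxend[chrom][idx - 1] > start
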