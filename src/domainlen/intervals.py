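"""Genomic interval model, BED/BEDPE I/O and overlap arithmetic.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Abutting intervals therefore do not overlap, and an interval's length is
``end - start``. Strand is ignored throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalTrack",
    "AnchorPair",
    "BedParseError",
    "read_bed",
    "read_bedpe",
    "write_bed",
    "overlap_bp",
    "total_overlap_bp",
    "assign_nearest_tss",
]

#: Label used for domains on chromosomes that carry no TSS point.
UNASSIGNED = "unassigned"

_SKIP_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """A malformed line in a BED/BEDPE file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One chrom/start/end record; the atom of every track.

    ``start`` is 0-based inclusive, ``end`` exclusive, so the minimal valid
    interval is 1 bp long.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class IntervalTrack:
    """A named, sorted collection of intervals (a "feature" in the models).

    Intervals are kept sorted by ``(chrom, start, end)``; duplicates and
    mutually overlapping instances are permitted — a single domain may
    legitimately overlap several instances of the same feature.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, idx: int) -> GenomicInterval:
        return self.intervals[idx]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class AnchorPair:
    """Two linked anchors of one chromatin interaction (one BEDPE row)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    interaction_id: str | None = None


def _data_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_interval(path, lineno: int, chrom: str, start: str, end: str,
                    name: str | None = None, score: str | None = None) -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError:
        raise BedParseError(path, lineno, f"non-integer coordinates {start!r}/{end!r}") from None
    if e <= s:
        raise BedParseError(path, lineno, f"end ({e}) must exceed start ({s})")
    sc: float | None = None
    if score not in (None, "", "."):
        try:
            sc = float(score)  # type: ignore[arg-type]
        except ValueError:
            raise BedParseError(path, lineno, f"non-numeric score {score!r}") from None
    return GenomicInterval(chrom, s, e, name=name or None, score=sc)


def read_bed(path, label: str | None = None) -> IntervalTrack:
    """Read a BED3/BED5 file into a sorted :class:`IntervalTrack`.

    Columns 4 and 5, when present, become the interval name and score.
    Lines beginning with ``#``, ``track`` or ``browser`` are skipped.
    """
    intervals = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise BedParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
        name = fields[3] if len(fields) > 3 else None
        score = fields[4] if len(fields) > 4 else None
        intervals.append(_parse_interval(path, lineno, fields[0], fields[1], fields[2], name, score))
    return IntervalTrack(label=label or Path(path).stem, intervals=intervals)


def read_bedpe(path) -> list[AnchorPair]:
    """Read a BEDPE file (>=6 columns) into a list of :class:`AnchorPair`."""
    pairs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise BedParseError(path, lineno, f"expected >=6 tab-separated fields, got {len(fields)}")
        a1 = _parse_interval(path, lineno, fields[0], fields[1], fields[2])
        a2 = _parse_interval(path, lineno, fields[3], fields[4], fields[5])
        pair_id = fields[6] if len(fields) > 6 else None
        pairs.append(AnchorPair(a1, a2, interaction_id=pair_id or None))
    return pairs


def write_bed(track: IntervalTrack, path) -> None:
    """Write a track as BED3, or BED5 when any interval carries a name/score.

    Round-trips through :func:`read_bed` coordinate-exactly.
    """
    five_col = any(iv.name is not None or iv.score is not None for iv in track)
    with open(path, "w") as fh:
        for iv in track:
            if five_col:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedpe(pairs: Sequence[AnchorPair], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            pid = p.interaction_id if p.interaction_id is not None else f"pair{i}"
            fh.write(
                f"{p.anchor1.chrom}\t{p.anchor1.start}\t{p.anchor1.end}\t"
                f"{p.anchor2.chrom}\t{p.anchor2.start}\t{p.anchor2.end}\t{pid}\n"
            )


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def total_overlap_bp(domain: GenomicInterval, track: IntervalTrack) -> int:
    """Summed per-instance overlap of ``domain`` with every track instance.

    This is the sum rule: instances overlapping each other inside the domain
    are each counted, so the total may exceed the domain length. (The union
    rule would merge them first; the feature encoding here deliberately does
    not.)
    """
    return sum(overlap_bp(domain, iv) for iv in track if iv.chrom == domain.chrom)


def _point_distance(domain: GenomicInterval, point: int) -> int:
    # 0 inside the half-open interval, else distance to the nearest boundary
    if domain.start <= point < domain.end:
        return 0
    return min(abs(point - domain.start), abs(point - domain.end))


def assign_nearest_tss(domains: IntervalTrack, tss: IntervalTrack) -> dict[GenomicInterval, str]:
    """Map each domain to the name of its closest TSS point.

    TSS intervals are reduced to their midpoints (a 1-bp point ``[p, p+1)``
    maps to ``p``). Distance is 0 when the point lies inside the domain and
    otherwise the distance to the nearest domain boundary; ties break toward
    the smaller TSS coordinate. Domains on chromosomes without any TSS map
    to ``"unassigned"``.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for i, iv in enumerate(tss):
        tss_by_chrom.setdefault(iv.chrom, []).append(
            (iv.midpoint, iv.name if iv.name is not None else f"tss{i}")
        )
    for points in tss_by_chrom.values():
        points.sort()

    assignment: dict[GenomicInterval, str] = {}
    for domain in domains:
        points = tss_by_chrom.get(domain.chrom)
        if not points:
            assignment[domain] = UNASSIGNED
            continue
        best = min(points, key=lambda pn: (_point_distance(domain, pn[0]), pn[0]))
        assignment[domain] = best[1]
    return assignment


def merge_instances(track: IntervalTrack) -> IntervalTrack:
    """Union-merge overlapping/abutting instances (sensitivity-check variant
    of the sum rule)."""
    merged: list[GenomicInterval] = []
    for iv in track:  # track is sorted
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalTrack(label=track.label, intervals=merged)
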