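"""Genomic interval algebra on 0-based half-open coordinates.

Every region handled by the pipeline — ultraconserved elements, accessibility
and histone-mark peaks, TADs, regulatory domains, random background fragments —
is a :class:`GenomicInterval`, and every collection of them an
:class:`IntervalSet`.  The overlap predicate used throughout is "any shared
base" (>= 1 bp), matching the default behaviour of ``bedtools intersect``;
windowed overlap reproduces ``bedtools window``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome names and lengths; the coordinate bound for every interval."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names in assembly")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None:
                raise ValueError(f"no length for chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeAssembly":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """Half-open region ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); all pipeline
    intersections are strand-blind.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end in {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, point: int) -> bool:
        return self.start <= point < self.end

    def expanded(self, flank: int, assembly: Optional[GenomeAssembly] = None) -> "GenomicInterval":
        """Symmetric extension by ``flank`` bp, clamped to chromosome bounds."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        start = max(0, self.start - flank)
        end = self.end + flank
        if assembly is not None:
            end = min(end, assembly.length(self.chrom))
        return replace(self, start=start, end=end)

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.chrom not in assembly:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > assembly.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {assembly.length(self.chrom)}"
            )


class IntervalSet:
    """Deterministically ordered collection of :class:`GenomicInterval`.

    Iteration order is (chrom, start, end, name), so any report derived from a
    set diffs cleanly between runs.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, idx):
        return self._intervals[idx]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_length(self) -> int:
        return sum(len(iv) for iv in self._intervals)

    def validate(self, assembly: GenomeAssembly) -> "IntervalSet":
        for iv in self._intervals:
            iv.validate(assembly)
        return self


def intersect(
    a: IntervalSet | Sequence[GenomicInterval],
    b: IntervalSet | Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (a, b) pairs sharing >= 1 bp, each qualifying pair exactly once.

    Sorted sweep per chromosome; output ordered by the a-interval then the
    b-interval sort keys.
    """
    a_by = IntervalSet(a).by_chrom() if not isinstance(a, IntervalSet) else a.by_chrom()
    b_by = IntervalSet(b).by_chrom() if not isinstance(b, IntervalSet) else b.by_chrom()
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        avs, bvs = a_by[chrom], b_by[chrom]
        # sweep: for each a, advance a lower pointer past b's that end before a
        lo = 0
        for iv in avs:
            # a starts are non-decreasing, so a b ending at/before iv.start can
            # never overlap any later a either
            while lo < len(bvs) and bvs[lo].end <= iv.start:
                lo += 1
            j = lo
            while j < len(bvs) and bvs[j].start < iv.end:
                if bvs[j].end > iv.start:
                    pairs.append((iv, bvs[j]))
                j += 1
    return pairs


def window_overlap(
    a: IntervalSet,
    b: IntervalSet,
    flank: int,
    assembly: Optional[GenomeAssembly] = None,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """``intersect`` after extending each a-interval by ``flank`` bp both ways.

    Reported pairs carry the *original* a-coordinates.  ``flank=0`` reduces to
    plain intersection.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    expanded = []
    originals = {}
    for iv in a:
        ext = iv.expanded(flank, assembly)
        expanded.append(ext)
        originals[id(ext)] = iv
    pairs = intersect(IntervalSet(expanded), b)
    return [(originals[id(x)], y) for x, y in pairs]


def merge(a: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge intervals separated by <= ``gap`` bp; names/scores are dropped."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, ivs in a.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(out)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (names/scores dropped)."""
    b_merged = merge(b, 0).by_chrom()
    out: list[GenomicInterval] = []
    for iv in a:
        cuts = b_merged.get(iv.chrom, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return IntervalSet(out)


def distance_to_point(iv: GenomicInterval, point: int, chrom: Optional[str] = None) -> int:
    """Signed distance from an interval to a point on the same chromosome.

    0 inside the interval; negative when the point lies left of ``start``
    (``point - start``); for a point at or beyond the exclusive ``end`` the
    distance is ``point - end``.
    """
    if chrom is not None and chrom != iv.chrom:
        raise ValueError(
            f"point on {chrom!r} but interval on {iv.chrom!r}"
        )
    if iv.contains_point(point):
        return 0
    if point < iv.start:
        return point - iv.start
    return point - iv.end
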