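"""Derive an ultraconserved-element catalogue from pairwise alignments.

An ultraconserved non-coding element is a non-coding reference region longer
than 200 bp (i.e. >= 201 bp) whose alignment to a distant species (classically
human–chicken) shows >= 95% column identity.  The scanner reports maximal
qualifying reference intervals; overlapping qualifying windows are resolved to
the longest one (ties to the leftmost).  Gap columns count as mismatches; a
column consumes a reference coordinate only when the reference base is
non-gap, so insertions in the partner sequence penalise identity without
extending the reference span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_intervals import GenomicInterval, IntervalSet, intersect

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped sequences of equal column count, anchored on the reference.

    ``ref_start`` is the 0-based reference coordinate of the first
    reference-consuming column on ``chrom``.
    """

    chrom: str
    ref: str
    other: str
    ref_start: int = 0

    def __post_init__(self) -> None:
        if len(self.ref) != len(self.other):
            raise ValueError("aligned sequences differ in column count")
        if not self.ref:
            raise ValueError("empty alignment")

    def columns(self) -> tuple[np.ndarray, np.ndarray]:
        """(is_match, consumes_ref) boolean arrays over alignment columns."""
        ref = np.frombuffer(self.ref.upper().encode(), dtype="S1")
        other = np.frombuffer(self.other.upper().encode(), dtype="S1")
        gap = np.isin(ref, [b"-", b"."]) | np.isin(other, [b"-", b"."])
        match = (ref == other) & ~gap
        consumes = ~np.isin(ref, [b"-", b"."])
        return match, consumes

    def ref_length(self) -> int:
        return int(self.columns()[1].sum())


@dataclass(frozen=True)
class UCNERecord:
    """A catalogued ultraconserved element with its alignment identity."""

    interval: GenomicInterval
    identity: float
    name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


def _select_maximal_windows(
    match: np.ndarray,
    consumes: np.ndarray,
    min_len: int,
    min_identity: float,
) -> list[tuple[int, int]]:
    """Longest-first (ties leftmost) qualifying windows, pairwise disjoint.

    A window is addressed by the reference bases it spans; its columns run
    from the consuming column of its first base through the consuming column
    of its last base, including interior insertion columns.  Windows are
    evaluated by prefix sums, sweeping lengths from longest to shortest so
    that no window set is ever materialised.
    """
    col_idx = np.flatnonzero(consumes)  # column of each reference base
    n_ref = len(col_idx)
    if n_ref < min_len:
        return []
    match_prefix = np.concatenate([[0], np.cumsum(match)])
    chosen: list[tuple[int, int]] = []
    for length in range(n_ref, min_len - 1, -1):
        first = col_idx[: n_ref - length + 1]
        last = col_idx[length - 1 :]
        n_cols = last - first + 1
        n_match = match_prefix[last + 1] - match_prefix[first]
        offsets = np.flatnonzero(n_match >= min_identity * n_cols)
        if not len(offsets):
            continue
        # drop candidates overlapping an already-chosen (longer) window
        keep = np.ones(len(offsets), dtype=bool)
        for cs, ce in chosen:
            keep &= (offsets + length <= cs) | (offsets >= ce)
        # greedy left-to-right among same-length survivors
        next_free = -1
        for s in offsets[keep]:
            if s >= next_free:
                chosen.append((int(s), int(s) + length))
                next_free = int(s) + length
    return sorted(chosen)


def scan_ultraconserved(
    aln: PairwiseAlignment,
    min_len: int = 201,
    min_identity: float = 0.95,
    name_prefix: str = "UCNE",
) -> list[UCNERecord]:
    """Maximal ultraconserved reference intervals of the alignment.

    Enumerates every reference window of >= ``min_len`` bp with column
    identity >= ``min_identity`` (prefix-sum evaluation), then resolves
    overlaps longest-first with leftmost tie-break.  At ``min_identity=1.0``
    this returns exactly the maximal perfect-match runs.
    """
    match, consumes = aln.columns()
    chosen = _select_maximal_windows(match, consumes, min_len, min_identity)
    col_idx = np.flatnonzero(consumes)
    match_prefix = np.concatenate([[0], np.cumsum(match)])
    records = []
    for i, (s, e) in enumerate(chosen, 1):
        first, last = int(col_idx[s]), int(col_idx[e - 1])
        n_cols = last - first + 1
        n_match = int(match_prefix[last + 1] - match_prefix[first])
        start = aln.ref_start + s
        records.append(
            UCNERecord(
                interval=GenomicInterval(
                    aln.chrom, start, aln.ref_start + e, name=f"{name_prefix}_{i}"
                ),
                identity=n_match / n_cols,
                name=f"{name_prefix}_{i}",
            )
        )
    return records


def filter_noncoding(
    records: Sequence[UCNERecord], coding: IntervalSet
) -> list[UCNERecord]:
    """Drop records overlapping any coding interval by >= 1 bp."""
    record_set = IntervalSet([r.interval for r in records])
    overlapping = {iv for iv, _c in intersect(record_set, coding)}
    return [r for r in records if r.interval not in overlapping]


def catalogue_to_intervals(records: Sequence[UCNERecord]) -> IntervalSet:
    return IntervalSet([r.interval for r in records])
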