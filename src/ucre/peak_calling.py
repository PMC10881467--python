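"""Cutoff-style narrow-peak detection on step-function signal tracks.

Reproduces ``macs2 bdgpeakcall`` behaviour on pre-normalised bedGraph signal:
a peak is a maximal run of bases with value >= cutoff, after closing
sub-threshold gaps of at most ``max_gap`` bases and discarding runs shorter
than ``min_length``.  The pipeline uses cutoff 0.4 for single-cell
accessibility cluster signal and 20 for histone-mark signal, with the
narrow-peak defaults min_length=200 and max_gap=30.

No background model is involved — the tracks are already normalised, so plain
thresholding is the intended behaviour, not an approximation of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core_intervals import GenomicInterval, IntervalSet
from .tracks import SignalTrack

DEFAULT_MIN_LENGTH = 200
DEFAULT_MAX_GAP = 30


@dataclass(frozen=True)
class PeakCall:
    """A called peak: interval, leftmost-maximum summit, run maximum."""

    interval: GenomicInterval
    summit: int
    max_value: float

    def __post_init__(self) -> None:
        if not self.interval.contains_point(self.summit):
            raise ValueError("summit outside peak interval")


def call_peaks(
    track: SignalTrack,
    cutoff: float,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
    name_prefix: str = "peak",
) -> list[PeakCall]:
    """Threshold the track into narrow peaks.

    Runs whose above-cutoff segments are separated by <= ``max_gap``
    sub-threshold bases are joined; the summit is the leftmost base attaining
    the peak maximum; the carried score is the run maximum.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    peaks: list[PeakCall] = []
    counter = 0
    for chrom in track.chroms():
        # above-threshold segments in coordinate order, merging abutting runs
        segments: list[tuple[int, int]] = []
        for start, end, value in track.runs(chrom):
            if value >= cutoff:
                if segments and segments[-1][1] == start:
                    segments[-1] = (segments[-1][0], end)
                else:
                    segments.append((start, end))
        if not segments:
            continue
        # close sub-threshold gaps <= max_gap
        joined: list[tuple[int, int]] = [segments[0]]
        for seg in segments[1:]:
            if seg[0] - joined[-1][1] <= max_gap:
                joined[-1] = (joined[-1][0], seg[1])
            else:
                joined.append(seg)
        for start, end in joined:
            if end - start < min_length:
                continue
            summit = None
            max_value = None
            for rs, re, rv in track.runs(chrom):
                if re <= start or rs >= end or rv < cutoff:
                    continue
                if max_value is None or rv > max_value:
                    max_value = rv
                    summit = max(rs, start)
            counter += 1
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(
                        chrom, start, end, name=f"{name_prefix}_{counter}"
                    ),
                    summit=summit,
                    max_value=max_value,
                )
            )
    return peaks


def peaks_to_interval_set(peaks: Iterable[PeakCall]) -> IntervalSet:
    return IntervalSet(
        [
            GenomicInterval(
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
                name=p.interval.name,
                score=p.max_value,
            )
            for p in peaks
        ]
    )


def filter_low_signal_regions(
    peaks: IntervalSet,
    labels: Mapping[str, str],
    low_categories: Sequence[str] = ("Low-DNase",),
    known_categories: Optional[Sequence[str]] = None,
) -> IntervalSet:
    """Drop peaks whose category label is a configured low-signal category.

    ``labels`` maps peak name -> category (e.g. ENCODE rDHS classifications);
    a category outside ``known_categories`` (when given) is an error.
    """
    low = set(low_categories)
    known = set(known_categories) if known_categories is not None else None
    if known is not None:
        unknown = sorted({c for c in labels.values() if c not in known})
        if unknown:
            raise ValueError(f"unknown peak category labels: {unknown}")
    kept = []
    for iv in peaks:
        category = labels.get(iv.name)
        if category is not None and known is not None and category not in known:
            raise ValueError(f"unknown peak category label: {category!r}")
        if category in low:
            continue
        kept.append(iv)
    return IntervalSet(kept)
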