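"""Step-function genomic tracks (bedGraph semantics).

A track stores, per chromosome, sorted non-overlapping runs ``(start, end,
value)``; every uncovered base has value 0 (or is *missing*, for constraint
tracks queried with ``missing_as_nan=True``).  Signal tracks (accessibility,
histone marks) require non-negative values; constraint tracks do not.
"""

from __future__ import annotations

import numpy as np

from .core_intervals import GenomeAssembly, GenomicInterval


class StepTrack:
    """Per-chromosome step function with O(log n) point queries."""

    #: subclasses may forbid negative values
    require_nonnegative = False

    def __init__(self) -> None:
        # chrom -> (starts, ends, values) as numpy arrays
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls,
        runs: dict[str, list[tuple[int, int, float]]],
        assembly: GenomeAssembly | None = None,
    ) -> "StepTrack":
        track = cls()
        for chrom, chrom_runs in runs.items():
            ordered = sorted(chrom_runs)
            starts = np.array([r[0] for r in ordered], dtype=np.int64)
            ends = np.array([r[1] for r in ordered], dtype=np.int64)
            values = np.array([r[2] for r in ordered], dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"non-positive run length on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            if np.any(starts < 0):
                raise ValueError(f"negative coordinate on {chrom}")
            if cls.require_nonnegative and np.any(values < 0):
                raise ValueError(f"negative signal value on {chrom}")
            if assembly is not None and len(ends) and ends[-1] > assembly.length(chrom):
                raise ValueError(
                    f"run exceeds length of {chrom} ({assembly.length(chrom)})"
                )
            track._runs[chrom] = (starts, ends, values)
        return track

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._runs:
            return []
        starts, ends, values = self._runs[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def nonzero_runs(self, chrom: str) -> list[tuple[int, int, float]]:
        return [(s, e, v) for s, e, v in self.runs(chrom) if v != 0]

    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def values(
        self, chrom: str, start: int, end: int, missing_as_nan: bool = False
    ) -> np.ndarray:
        """Per-base values over ``[start, end)``.

        Uncovered bases are 0 by bedGraph convention, or NaN when the track is
        treated as sparse (constraint scores with missing positions).
        """
        if end <= start:
            raise ValueError("end must exceed start")
        fill = np.nan if missing_as_nan else 0.0
        out = np.full(end - start, fill, dtype=float)
        if chrom not in self._runs:
            return out
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            out[a:b] = values[i]
        return out

    def region_values(
        self, iv: GenomicInterval, missing_as_nan: bool = False
    ) -> np.ndarray:
        return self.values(iv.chrom, iv.start, iv.end, missing_as_nan=missing_as_nan)

    def canonical(self) -> "StepTrack":
        """Drop zero-value runs and merge abutting equal-value neighbours."""
        out = type(self)()
        for chrom in self.chroms():
            merged: list[tuple[int, int, float]] = []
            for s, e, v in self.runs(chrom):
                if v == 0:
                    continue
                if merged and merged[-1][1] == s and merged[-1][2] == v:
                    merged[-1] = (merged[-1][0], e, v)
                else:
                    merged.append((s, e, v))
            if merged:
                starts = np.array([r[0] for r in merged], dtype=np.int64)
                ends = np.array([r[1] for r in merged], dtype=np.int64)
                values = np.array([r[2] for r in merged], dtype=float)
                out._runs[chrom] = (starts, ends, values)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, StepTrack):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        if a.chroms() != b.chroms():
            return False
        return all(a.runs(c) == b.runs(c) for c in a.chroms())


class SignalTrack(StepTrack):
    """Non-negative coverage/enrichment signal (scATAC, ChIP, DNase)."""

    require_nonnegative = True


class ConstraintTrack(StepTrack):
    """Per-base (or per-window) intolerance scores; lower = more intolerant.

    Positions without a score are *missing*, not zero: query through
    ``values(..., missing_as_nan=True)`` and drop NaNs, counting them.
    """

    require_nonnegative = False
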