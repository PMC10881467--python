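"""Shared fixtures and brute-force oracle helpers.

The oracles here deliberately re-derive every result by direct enumeration
(all-pairs loops, per-base scans, all-window identity checks) so that the
optimised implementations are checked against independent code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from ucre.core_intervals import GenomeAssembly, GenomicInterval, IntervalSet


@pytest.fixture
def assembly() -> GenomeAssembly:
    return GenomeAssembly.from_dict({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_coord: int = 10_000,
    named: bool = False,
) -> IntervalSet:
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_coord - 1))
        end = int(rng.integers(start + 1, min(start + 500, max_coord) + 1))
        out.append(
            GenomicInterval(chrom, start, end, name=f"iv_{i}" if named else None)
        )
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# oracles


def brute_intersect(a, b):
    """All-pairs overlap enumeration."""
    return [
        (x, y)
        for x in a
        for y in b
        if x.chrom == y.chrom and x.start < y.end and y.start < x.end
    ]


def covered_bases(intervals) -> set:
    out = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            out.add((iv.chrom, pos))
    return out


def brute_call_peaks(runs, chrom_len, cutoff, min_length, max_gap):
    """Per-base threshold scan: the peak-calling oracle.

    ``runs`` is a list of (start, end, value) for one chromosome.  Returns
    (start, end, summit, max_value) tuples.
    """
    values = np.zeros(chrom_len)
    for s, e, v in runs:
        values[s:e] = v
    above = values >= cutoff
    segments = []
    pos = 0
    while pos < chrom_len:
        if above[pos]:
            start = pos
            while pos < chrom_len and above[pos]:
                pos += 1
            segments.append((start, pos))
        else:
            pos += 1
    joined = []
    for seg in segments:
        if joined and seg[0] - joined[-1][1] <= max_gap:
            joined[-1] = (joined[-1][0], seg[1])
        else:
            joined.append(list(seg))
    peaks = []
    for start, end in joined:
        if end - start < min_length:
            continue
        window = values[start:end]
        summit = start + int(np.argmax(window))
        peaks.append((start, end, summit, float(window.max())))
    return peaks


def brute_mid_ranks(values):
    """O(N^2) mid-rank computation, independent of scipy."""
    values = list(values)
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(smaller + (equal + 1) / 2.0)
    return ranks


def brute_kruskal(groups):
    """Direct Kruskal–Wallis H with tie correction from mid-ranks."""
    pooled = [v for g in groups for v in g]
    ranks = brute_mid_ranks(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        idx += len(g)
        h += len(g) * (sum(r) / len(r) - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    tie = sum(
        c**3 - c
        for c in (pooled.count(v) for v in set(pooled))
    )
    denom = 1.0 - tie / (n**3 - n)
    if denom <= 0:
        return 0.0
    return h / denom


def domain_member_oracle(x, gene, all_genes, chrom_len, up, down, max_ext):
    """Per-base basal-plus-extension membership rule."""

    def basal(g):
        if g.strand == "+":
            s, e = g.tss - up, g.tss + down
        else:
            s, e = g.tss - down, g.tss + up
        return max(0, s), min(chrom_len, e)

    bs, be = basal(gene)
    if bs <= x < be:
        return True
    others = [basal(o) for o in all_genes if o.gene_id != gene.gene_id and o.chrom == gene.chrom]
    if x < bs:
        if x < bs - max_ext:
            return False
        return all(x >= oe or os_ >= bs for os_, oe in others)
    if x >= be + max_ext:
        return False
    return all(x < os_ or oe <= be for os_, oe in others)


def oracle_scan(aln, min_len, min_identity):
    """Ultraconservation oracle: evaluate *every* reference window by prefix
    sums, then apply the longest-first / leftmost maximality rule.

    Independent of the implementation's descending-length sweep: every
    qualifying window is materialised and sorted before selection.
    """
    ref_cols = [i for i, c in enumerate(aln.ref) if c not in "-."]
    match = [
        1 if (a == b and a not in "-." and b not in "-.") else 0
        for a, b in zip(aln.ref.upper(), aln.other.upper())
    ]
    mp = [0]
    for m in match:
        mp.append(mp[-1] + m)
    n_ref = len(ref_cols)
    qualifying = []
    for s in range(n_ref - min_len + 1):
        for e in range(s + min_len, n_ref + 1):
            c0, c1 = ref_cols[s], ref_cols[e - 1] + 1
            if mp[c1] - mp[c0] >= min_identity * (c1 - c0):
                qualifying.append((s, e))
    qualifying.sort(key=lambda w: (-(w[1] - w[0]), w[0]))
    chosen = []
    for s, e in qualifying:
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    return sorted((aln.ref_start + s, aln.ref_start + e) for s, e in chosen)


def oracle_scan_vectorised(aln, min_len, min_identity):
    """Same all-window oracle with numpy-evaluated window identities, for
    alignment lengths where the pure-Python double loop is too slow."""
    ref_cols = np.array([i for i, c in enumerate(aln.ref) if c not in "-."])
    match = np.array(
        [
            1 if (a == b and a not in "-." and b not in "-.") else 0
            for a, b in zip(aln.ref.upper(), aln.other.upper())
        ]
    )
    mp = np.concatenate([[0], np.cumsum(match)])
    n_ref = len(ref_cols)
    qualifying = []
    for length in range(min_len, n_ref + 1):
        first = ref_cols[: n_ref - length + 1]
        last = ref_cols[length - 1 :]
        ok = (mp[last + 1] - mp[first]) >= min_identity * (last - first + 1)
        for s in np.flatnonzero(ok):
            qualifying.append((int(s), int(s) + length))
    qualifying.sort(key=lambda w: (-(w[1] - w[0]), w[0]))
    chosen = []
    for s, e in qualifying:
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    return sorted((aln.ref_start + s, aln.ref_start + e) for s, e in chosen)
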