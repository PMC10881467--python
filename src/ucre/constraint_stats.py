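"""Background sampling, allele-frequency spectra and constraint rank tests.

Stage 4: the observed variant spectrum inside ultraconserved elements is
compared against a background of 200 random 350 bp genomic fragments, and
per-base constraint scores (gwRVIS-style, lower = more intolerant) are
compared across three region classes — elements, their 200 bp flanks, and the
random background — with a Kruskal–Wallis rank-sum test followed by Dunn's
post-hoc test with Bonferroni correction.

The rank statistics are implemented here (mid-ranks, tie correction); SciPy's
independent implementation serves as a cross-check in the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core_intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    distance_to_point,
    merge,
    subtract,
)
from .target_assignment import (
    DISTANCE_BIN_LABELS,
    RegulatoryDomain,
    distance_bin,
)
from .variant_prioritization import BIN_ORDER, VariantRecord, classify_frequency

DEFAULT_N_FRAGMENTS = 200
DEFAULT_FRAGMENT_LENGTH = 350
DEFAULT_FLANK = 200


@dataclass(frozen=True)
class RandomFragmentSpec:
    """Specification of the random genomic background."""

    n: int = DEFAULT_N_FRAGMENTS
    length: int = DEFAULT_FRAGMENT_LENGTH
    seed: int = 0
    exclusion: Optional[IntervalSet] = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be positive")


class FragmentPlacementError(RuntimeError):
    def __init__(self, achieved: int, requested: int):
        super().__init__(
            f"could only place {achieved}/{requested} background fragments "
            "after bounded retries"
        )
        self.achieved = achieved
        self.requested = requested


def sample_fragments(
    spec: RandomFragmentSpec,
    assembly: GenomeAssembly,
    max_tries_per_fragment: int = 1000,
) -> IntervalSet:
    """``spec.n`` fragments of exactly ``spec.length`` bp, uniform over the
    genome, rejecting any that overlap the exclusion set.  Deterministic for a
    given (seed, assembly, exclusion)."""
    rng = np.random.default_rng(spec.seed)
    chroms = [c for c in assembly.chrom_names if assembly.length(c) >= spec.length]
    if not chroms:
        raise FragmentPlacementError(0, spec.n)
    weights = np.array([assembly.length(c) - spec.length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    exclusion = (
        merge(spec.exclusion, 0).by_chrom() if spec.exclusion is not None else {}
    )
    placed: list[GenomicInterval] = []
    tries = 0
    budget = max_tries_per_fragment * spec.n
    while len(placed) < spec.n and tries < budget:
        tries += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, assembly.length(chrom) - spec.length + 1))
        candidate = GenomicInterval(
            chrom, start, start + spec.length, name=f"bg_{len(placed) + 1}"
        )
        if any(candidate.overlaps(e) for e in exclusion.get(chrom, [])):
            continue
        placed.append(candidate)
    if len(placed) < spec.n:
        raise FragmentPlacementError(len(placed), spec.n)
    return IntervalSet(placed)


# ---------------------------------------------------------------------------
# allele-frequency spectra


def af_spectrum(
    variants: Sequence[VariantRecord],
    regions: IntervalSet,
) -> dict:
    """Frequency-bin counts and proportions of variants overlapping regions."""
    from .core_intervals import intersect

    var_set = IntervalSet([v.interval for v in variants])
    by_iv: dict[GenomicInterval, list[VariantRecord]] = {}
    for v in variants:
        by_iv.setdefault(v.interval, []).append(v)
    hit_ivs = {viv for viv, _r in intersect(var_set, regions)}
    counts = {b.value: 0 for b in BIN_ORDER}
    for viv in hit_ivs:
        for v in by_iv[viv]:
            counts[classify_frequency(v).value] += 1
    total = sum(counts.values())
    proportions = {
        b: (c / total if total else float("nan")) for b, c in counts.items()
    }
    return {"counts": counts, "proportions": proportions, "total": total}


def af_spectrum_comparison(
    variants: Sequence[VariantRecord],
    ucnes: IntervalSet,
    background: IntervalSet,
) -> dict:
    """Element vs background spectra with two per-bin normalisations.

    ``proportion_ratio`` divides the within-class bin proportions;
    ``density_ratio`` divides per-bp variant densities (count / total bp),
    whose expectation under a rate model with per-bin depletion equals the
    depletion factor directly.  ``density_ratio_se`` is the delta-method
    standard error of each density ratio (Poisson counts).
    """
    ucne_spec = af_spectrum(variants, ucnes)
    bg_spec = af_spectrum(variants, background)
    ucne_bp = ucnes.total_length()
    bg_bp = background.total_length()
    proportion_ratio = {}
    density_ratio = {}
    density_ratio_se = {}
    for b in (bin_.value for bin_ in BIN_ORDER):
        bgp = bg_spec["proportions"][b]
        proportion_ratio[b] = (
            ucne_spec["proportions"][b] / bgp if bgp and bgp > 0 else float("nan")
        )
        cu, cb = ucne_spec["counts"][b], bg_spec["counts"][b]
        if cb > 0 and ucne_bp and bg_bp:
            ratio = (cu / ucne_bp) / (cb / bg_bp)
            density_ratio[b] = ratio
            density_ratio_se[b] = (
                ratio * np.sqrt(1.0 / cu + 1.0 / cb) if cu > 0 else float("nan")
            )
        else:
            density_ratio[b] = float("nan")
            density_ratio_se[b] = float("nan")
    return {
        "ucne": ucne_spec,
        "background": bg_spec,
        "proportion_ratio": proportion_ratio,
        "density_ratio": density_ratio,
        "density_ratio_se": density_ratio_se,
        "background_empty": bg_spec["total"] == 0,
    }


def build_flanks(
    ucnes: IntervalSet,
    flank: int = DEFAULT_FLANK,
    assembly: Optional[GenomeAssembly] = None,
) -> IntervalSet:
    """±``flank`` bp flanking regions, excluding every element body.

    Flanks of clustered elements are merged where they collide and clipped so
    that no flank base lies inside any element; a flank at a chromosome
    boundary is truncated (possibly absent).
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    raw = []
    for iv in ucnes:
        left_start = max(0, iv.start - flank)
        if left_start < iv.start:
            raw.append(GenomicInterval(iv.chrom, left_start, iv.start))
        end = iv.end + flank
        if assembly is not None:
            end = min(end, assembly.length(iv.chrom))
        if end > iv.end:
            raw.append(GenomicInterval(iv.chrom, iv.end, end))
    return subtract(merge(IntervalSet(raw), 0), ucnes)


# ---------------------------------------------------------------------------
# rank statistics


@dataclass
class RankTestResult:
    H: float
    p: float
    pairwise: list  # of (i, j, z, p_adjusted)
    group_medians: list = field(default_factory=list)
    group_sizes: list = field(default_factory=list)


def _ranks_and_ties(groups: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    split = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    return split, tie_term, len(pooled)


def kruskal_wallis(groups: Sequence[Iterable[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H on mid-ranks with tie correction; chi-square p-value.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by
    1 - sum(t^3 - t)/(N^3 - N).  All values identical -> H = 0, p = 1.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    n = sum(len(a) for a in arrays)
    if n < 3:
        raise ValueError("need >= 3 observations in total")
    group_ranks, tie_term, N = _ranks_and_ties(arrays)
    H = 12.0 / (N * (N + 1)) * sum(
        len(r) * (r.mean() - (N + 1) / 2.0) ** 2 for r in group_ranks
    )
    correction = 1.0 - tie_term / (N**3 - N)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    H /= correction
    p = float(sps.chi2.sf(H, len(arrays) - 1))
    return float(H), p


def dunn_posthoc(
    groups: Sequence[Iterable[float]], correction: str = "bonferroni"
) -> list[tuple[int, int, float, float]]:
    """Dunn's pairwise z tests on pooled mid-ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t); two-sided normal p, multiplied by the number of
    pairs and capped at 1.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    group_ranks, tie_term, N = _ranks_and_ties(arrays)
    k = len(arrays)
    n_pairs = k * (k - 1) // 2
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            if se == 0:  # all pooled values identical
                z, p_adj = 0.0, 1.0
            else:
                z = float((group_ranks[i].mean() - group_ranks[j].mean()) / se)
                p_raw = 2.0 * float(sps.norm.sf(abs(z)))
                p_adj = min(1.0, p_raw * n_pairs)
            out.append((i, j, z, p_adj))
    return out


# ---------------------------------------------------------------------------
# constraint comparison


def region_scores(
    track,
    regions: IntervalSet,
    per_region_mean: bool = False,
) -> tuple[np.ndarray, int]:
    """Constraint observations for a region class, and missing-base count.

    Per-base mode (default): every covered base contributes one observation,
    matching a nucleotide-resolution score.  ``per_region_mean`` collapses
    each region to its mean score for sensitivity analysis.
    """
    values = []
    n_missing = 0
    for iv in regions:
        v = track.values(iv.chrom, iv.start, iv.end, missing_as_nan=True)
        missing = np.isnan(v)
        n_missing += int(missing.sum())
        v = v[~missing]
        if len(v):
            values.append(v.mean() if per_region_mean else v)
    if not values:
        return np.array([]), n_missing
    if per_region_mean:
        return np.array(values, dtype=float), n_missing
    return np.concatenate(values), n_missing


def compare_constraint(
    track,
    ucnes: IntervalSet,
    flanks: IntervalSet,
    background: IntervalSet,
    per_region_mean: bool = False,
) -> RankTestResult:
    """Kruskal–Wallis + Dunn on constraint scores across the three classes.

    Group order: 0 = elements, 1 = flanks, 2 = background.  Negative z for a
    pair (i, j) means class i has lower mean rank, i.e. lower (more
    intolerant) scores.
    """
    groups = []
    for name, regions in (("ucne", ucnes), ("flank", flanks), ("background", background)):
        sample, _missing = region_scores(track, regions, per_region_mean)
        if len(sample) == 0:
            raise ValueError(f"no constraint observations for group {name!r}")
        groups.append(sample)
    H, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups)
    return RankTestResult(
        H=H,
        p=p,
        pairwise=pairwise,
        group_medians=[float(np.median(g)) for g in groups],
        group_sizes=[len(g) for g in groups],
    )


def background_suitability(
    ucnes: IntervalSet,
    background: IntervalSet,
    domains: Sequence[RegulatoryDomain],
) -> dict:
    """TSS-distance comparability of background fragments vs elements.

    Distance = |signed distance| from each region to the nearest TSS on its
    chromosome (0 when a TSS falls inside).  Distributions are binned as in
    the target-assignment distance histogram, and compared unbinned with the
    two-group Kruskal–Wallis rank test (Wilcoxon-equivalent).
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for d in domains:
        tss_by_chrom.setdefault(d.gene.chrom, []).append(d.gene.tss)

    def distances(regions: IntervalSet) -> list[int]:
        out = []
        for iv in regions:
            sites = tss_by_chrom.get(iv.chrom)
            if not sites:
                continue
            out.append(min(abs(distance_to_point(iv, t)) for t in sites))
        return out

    d_ucne = distances(ucnes)
    d_bg = distances(background)
    bins_ucne = {label: 0 for label in DISTANCE_BIN_LABELS}
    for d in d_ucne:
        bins_ucne[distance_bin(d)] += 1
    bins_bg = {label: 0 for label in DISTANCE_BIN_LABELS}
    for d in d_bg:
        bins_bg[distance_bin(d)] += 1
    if d_ucne and d_bg:
        H, p = kruskal_wallis([d_ucne, d_bg])
    else:
        H, p = float("nan"), float("nan")
    return {
        "statistic": H,
        "p": p,
        "ucne_bins": bins_ucne,
        "background_bins": bins_bg,
        "n_ucne": len(d_ucne),
        "n_background": len(d_bg),
    }
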