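"""Background sampling, AF spectra, flanks, and rank statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from ucre import constraint_stats as cs
from ucre.core_intervals import GenomeAssembly, GenomicInterval, IntervalSet
from ucre.tracks import ConstraintTrack
from ucre.variant_prioritization import VariantRecord

from conftest import brute_kruskal, covered_bases


def test_sample_fragments_forced_placement():
    assembly = GenomeAssembly.from_dict({"chr1": 350})
    spec = cs.RandomFragmentSpec(n=1, length=350, seed=0)
    (iv,) = cs.sample_fragments(spec, assembly)
    assert (iv.start, iv.end) == (0, 350)


def test_sample_fragments_full_exclusion_errors():
    assembly = GenomeAssembly.from_dict({"chr1": 10_000})
    exclusion = IntervalSet([GenomicInterval("chr1", 0, 10_000)])
    spec = cs.RandomFragmentSpec(n=5, length=350, seed=0, exclusion=exclusion)
    with pytest.raises(cs.FragmentPlacementError) as err:
        cs.sample_fragments(spec, assembly, max_tries_per_fragment=50)
    assert err.value.achieved == 0


def test_sample_fragments_deterministic_and_seed_sensitive():
    assembly = GenomeAssembly.from_dict({"chr1": 2_000_000, "chr2": 1_000_000})
    a = cs.sample_fragments(cs.RandomFragmentSpec(n=200, length=350, seed=11), assembly)
    b = cs.sample_fragments(cs.RandomFragmentSpec(n=200, length=350, seed=11), assembly)
    c = cs.sample_fragments(cs.RandomFragmentSpec(n=200, length=350, seed=12), assembly)
    assert list(a) == list(b)
    assert list(a) != list(c)
    assert all(len(iv) == 350 for iv in a)


def test_sample_fragments_respects_exclusion():
    assembly = GenomeAssembly.from_dict({"chr1": 100_000})
    exclusion = IntervalSet([GenomicInterval("chr1", 0, 90_000)])
    frags = cs.sample_fragments(
        cs.RandomFragmentSpec(n=20, length=350, seed=3, exclusion=exclusion), assembly
    )
    assert all(iv.start >= 90_000 for iv in frags)


def _variant(pos, af=None, absent=False):
    return VariantRecord(
        interval=GenomicInterval("chr1", pos, pos + 1),
        af=af,
        observed_in_reference=not absent,
    )


def test_af_spectrum_all_ultrarare():
    regions = IntervalSet([GenomicInterval("chr1", 0, 1_000)])
    variants = [_variant(i, absent=True) for i in range(10)]
    spec = cs.af_spectrum(variants, regions)
    assert spec["proportions"] == {
        "ultrarare": 1.0, "very_rare": 0.0, "rare": 0.0,
        "low_frequency": 0.0, "common": 0.0,
    }


def test_af_spectrum_uniform_bins_and_sum_to_one():
    regions = IntervalSet([GenomicInterval("chr1", 0, 1_000)])
    afs = [None, 0.0005, 0.002, 0.02, 0.2]
    variants = [
        _variant(i * 5 + k, af=af, absent=af is None)
        for k, af in enumerate(afs)
        for i in range(4)
    ]
    spec = cs.af_spectrum(variants, regions)
    assert all(abs(p - 0.2) < 1e-12 for p in spec["proportions"].values())
    assert abs(sum(spec["proportions"].values()) - 1.0) < 1e-12


def test_af_spectrum_comparison_empty_background_flagged():
    ucnes = IntervalSet([GenomicInterval("chr1", 0, 100)])
    background = IntervalSet([GenomicInterval("chr1", 5_000, 5_100)])
    out = cs.af_spectrum_comparison([_variant(5, absent=True)], ucnes, background)
    assert out["background_empty"]


def test_build_flanks_basic():
    ucnes = IntervalSet([GenomicInterval("chr1", 1_000, 1_400, name="U")])
    flanks = cs.build_flanks(ucnes, 200)
    assert [(iv.start, iv.end) for iv in flanks] == [(800, 1_000), (1_400, 1_600)]


def test_build_flanks_chromosome_start_truncates():
    ucnes = IntervalSet([GenomicInterval("chr1", 0, 300)])
    assembly = GenomeAssembly.from_dict({"chr1": 400})
    flanks = cs.build_flanks(ucnes, 200, assembly)
    assert [(iv.start, iv.end) for iv in flanks] == [(300, 400)]


def test_build_flanks_clustered_never_covers_elements(rng):
    starts = sorted(int(s) for s in rng.integers(0, 9_000, 25))
    ucnes = IntervalSet(
        [GenomicInterval("chr1", s, s + int(rng.integers(50, 400))) for s in starts]
    )
    flanks = cs.build_flanks(ucnes, 200)
    assert covered_bases(flanks) & covered_bases(ucnes) == set()
    # every flank base is within 200 bp of some element
    for chrom, pos in covered_bases(flanks):
        assert any(
            iv.start - 200 <= pos < iv.end + 200 for iv in ucnes if iv.chrom == chrom
        )


def test_kruskal_wallis_hand_value():
    H, p = cs.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert H == pytest.approx(7.2)
    assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))


def test_kruskal_wallis_identical_values():
    H, p = cs.kruskal_wallis([[5, 5, 5], [5, 5], [5, 5, 5]])
    assert (H, p) == (0.0, 1.0)


def test_kruskal_wallis_matches_scipy_with_ties(rng):
    for _ in range(25):
        groups = [
            list(rng.integers(0, 6, size=int(rng.integers(3, 15)))) for _ in range(3)
        ]
        H, p = cs.kruskal_wallis(groups)
        try:
            want = sps.kruskal(*groups)
        except ValueError:  # scipy refuses all-identical input
            continue
        assert H == pytest.approx(want.statistic, abs=1e-10)
        assert p == pytest.approx(want.pvalue, abs=1e-10)


def test_kruskal_wallis_matches_brute_force_small_n(rng):
    # exhaustive-rank brute force on every instance with N <= 10
    for _ in range(60):
        k = int(rng.integers(2, 4))
        sizes = []
        remaining = int(rng.integers(max(k, 3), 11))
        for i in range(k - 1):
            sizes.append(1 + int(rng.integers(0, remaining - (k - i - 1))))
            remaining -= sizes[-1]
        sizes.append(remaining)
        groups = [list(rng.integers(0, 4, size=s)) for s in sizes]
        H, _p = cs.kruskal_wallis(groups)
        assert H == pytest.approx(brute_kruskal(groups), abs=1e-10)


def test_kruskal_wallis_input_validation():
    with pytest.raises(ValueError):
        cs.kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        cs.kruskal_wallis([[1], []])
    with pytest.raises(ValueError):
        cs.kruskal_wallis([[1], [2]])


def test_dunn_identical_groups():
    out = cs.dunn_posthoc([[1, 2, 3], [1, 2, 3]])
    ((i, j, z, p),) = out
    assert (i, j) == (0, 1)
    assert z == pytest.approx(0.0)
    assert p == 1.0


def test_dunn_tie_free_toy_matches_direct_formula():
    groups = [[1.0, 2.0], [3.0, 5.0, 6.0], [8.0, 9.0]]
    out = cs.dunn_posthoc(groups)
    n = 7
    mean_ranks = [1.5, 4.0, 6.5]
    sizes = [2, 3, 2]
    var_base = n * (n + 1) / 12.0
    k = 3
    for i, j, z, p_adj in out:
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        want_z = (mean_ranks[i] - mean_ranks[j]) / se
        assert z == pytest.approx(want_z, abs=1e-12)
        want_p = min(1.0, 2 * float(sps.norm.sf(abs(want_z))) * (k * (k - 1) / 2))
        assert p_adj == pytest.approx(want_p, abs=1e-12)
        assert p_adj >= 2 * float(sps.norm.sf(abs(z)))  # adjusted >= raw


def test_dunn_detects_large_shift(rng):
    groups = [
        list(rng.normal(0, 1, 40)),
        list(rng.normal(0, 1, 40)),
        list(rng.normal(3, 1, 40)),
    ]
    out = cs.dunn_posthoc(groups)
    assert min(p for _i, _j, _z, p in out) < 1e-3


def test_compare_constraint_accounting_and_direction():
    assembly = GenomeAssembly.from_dict({"chr1": 10_000})
    runs = {"chr1": [(i, i + 1, float(v)) for i, v in enumerate(
        np.concatenate([
            np.random.default_rng(0).normal(-1.0, 1, 300),   # element bases
            np.random.default_rng(1).normal(-0.5, 1, 300),   # flank bases
            np.random.default_rng(2).normal(0.0, 1, 400),    # background bases
        ])
    )]}
    track = ConstraintTrack.from_runs(runs, assembly)
    ucnes = IntervalSet([GenomicInterval("chr1", 0, 300)])
    flanks = IntervalSet([GenomicInterval("chr1", 300, 600)])
    background = IntervalSet([GenomicInterval("chr1", 600, 1_000)])
    res = cs.compare_constraint(track, ucnes, flanks, background)
    assert res.group_sizes == [300, 300, 400]  # per-base sampling
    assert res.group_medians[0] < res.group_medians[2]
    ucne_vs_bg = next(pair for pair in res.pairwise if (pair[0], pair[1]) == (0, 2))
    assert ucne_vs_bg[2] < 0  # elements have lower ranks
    assert ucne_vs_bg[3] < 0.05


def test_compare_constraint_empty_group_errors():
    assembly = GenomeAssembly.from_dict({"chr1": 1_000})
    track = ConstraintTrack.from_runs({"chr1": [(0, 500, -1.0)]}, assembly)
    ucnes = IntervalSet([GenomicInterval("chr1", 0, 100)])
    background = IntervalSet([GenomicInterval("chr1", 600, 700)])  # uncovered
    with pytest.raises(ValueError, match="background"):
        cs.compare_constraint(track, ucnes, ucnes, background)


def test_region_scores_missing_bases_counted():
    assembly = GenomeAssembly.from_dict({"chr1": 1_000})
    track = ConstraintTrack.from_runs({"chr1": [(0, 50, -1.0)]}, assembly)
    sample, n_missing = cs.region_scores(track, IntervalSet([GenomicInterval("chr1", 0, 80)]))
    assert len(sample) == 50 and n_missing == 30


def test_background_suitability_identical_sets():
    from ucre.target_assignment import GeneModel, build_domains

    assembly = GenomeAssembly.from_dict({"chr1": 1_000_000})
    domains = build_domains([GeneModel("G", "chr1", 500_000, "+")], assembly)
    regions = IntervalSet(
        [GenomicInterval("chr1", s, s + 350) for s in (10_000, 200_000, 700_000)]
    )
    out = cs.background_suitability(regions, regions, domains)
    assert out["p"] == pytest.approx(1.0)
    assert sum(out["ucne_bins"].values()) == out["n_ucne"] == 3
    assert sum(out["background_bins"].values()) == out["n_background"] == 3


def test_background_suitability_detects_shift():
    from ucre.target_assignment import GeneModel, build_domains

    assembly = GenomeAssembly.from_dict({"chr1": 10_000_000})
    domains = build_domains([GeneModel("G", "chr1", 100_000, "+")], assembly)
    near = IntervalSet(
        [GenomicInterval("chr1", 100_000 + i * 1_000, 100_350 + i * 1_000) for i in range(30)]
    )
    far = IntervalSet(
        [GenomicInterval("chr1", 5_000_000 + i * 10_000, 5_000_350 + i * 10_000) for i in range(30)]
    )
    out = cs.background_suitability(near, far, domains)
    assert out["p"] < 0.001
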