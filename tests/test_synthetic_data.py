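"""Generator determinism, planted-structure consistency, config validation."""

import filecmp
import os

import numpy as np
import pytest

from ucre import synthetic_data as sd
from ucre.core_intervals import IntervalSet


SMALL = dict(n_ucnes=40, n_genes=16, n_chroms=1, chrom_length=1_000_000)


def test_config_validation():
    with pytest.raises(ValueError, match="nested"):
        sd.SimulationConfig(frac_open=0.1, frac_marked=0.2)
    with pytest.raises(ValueError, match="depletion"):
        sd.SimulationConfig(ucne_common_depletion=1.5)
    with pytest.raises(ValueError, match="delta"):
        sd.SimulationConfig(constraint_shift=-0.1)
    with pytest.raises(ValueError, match="sum"):
        sd.SimulationConfig(bin_shares=(0.5, 0.5, 0.5, 0.0, 0.0))


def _dir_files(root):
    out = {}
    for dirpath, _dirs, files in os.walk(root):
        for f in files:
            p = os.path.join(dirpath, f)
            out[os.path.relpath(p, root)] = p
    return out


def test_bundle_byte_identical_across_runs(tmp_path):
    cfg = sd.SimulationConfig(seed=9, **SMALL)
    sd.write_bundle(sd.generate(cfg), tmp_path / "a")
    sd.write_bundle(sd.generate(cfg), tmp_path / "b")
    a, b = _dir_files(tmp_path / "a"), _dir_files(tmp_path / "b")
    assert a.keys() == b.keys()
    for rel in a:
        assert filecmp.cmp(a[rel], b[rel], shallow=False), rel


def test_different_seeds_differ(tmp_path):
    b1 = sd.generate(sd.SimulationConfig(seed=1, **SMALL))
    b2 = sd.generate(sd.SimulationConfig(seed=2, **SMALL))
    assert list(b1.ucnes) != list(b2.ucnes)


def test_bundle_round_trip_through_files(tmp_path):
    cfg = sd.SimulationConfig(seed=4, **SMALL)
    bundle = sd.generate(cfg)
    sd.write_bundle(bundle, tmp_path / "bundle")
    again = sd.load_bundle(tmp_path / "bundle")
    assert list(again.ucnes) == list(bundle.ucnes)
    assert [g.gene_id for g in again.genes] == [g.gene_id for g in bundle.genes]
    assert again.stage_expr.shape == bundle.stage_expr.shape
    assert len(again.variants) == len(bundle.variants)
    assert again.case_solved == bundle.case_solved
    assert sorted(again.scatac_tracks) == sorted(bundle.scatac_tracks)
    key = sorted(bundle.scatac_tracks)[0]
    assert again.scatac_tracks[key] == bundle.scatac_tracks[key]


def test_planted_fractions_and_nesting():
    cfg = sd.SimulationConfig(seed=2)
    bundle = sd.generate(cfg)
    states = list(bundle.truth.ucne_state.values())
    n = len(states)
    n_open = sum(s != "none" for s in states)
    n_marked = sum(s in ("marked", "active_enhancer", "sustained_adult") for s in states)
    n_active = sum(s in ("active_enhancer", "sustained_adult") for s in states)
    assert n == cfg.n_ucnes
    assert n_open == round(cfg.frac_open * n)
    assert n_marked == round(cfg.frac_marked * n)
    assert n_active == round(cfg.frac_active * n)
    # every marked element carries planted mark evidence; open ones a source
    for name, state in bundle.truth.ucne_state.items():
        if state in ("marked", "active_enhancer", "sustained_adult"):
            assert bundle.truth.marks.get(name)
        if state != "none":
            assert bundle.truth.dnase_stages.get(name) or bundle.truth.scatac_clusters.get(name)


def test_ucnes_avoid_basal_domains_and_keep_separation():
    cfg = sd.SimulationConfig(seed=6, **SMALL)
    bundle = sd.generate(cfg)
    from ucre.target_assignment import build_domains

    domains = build_domains(bundle.genes, bundle.assembly)
    for iv in bundle.ucnes:
        for d in domains:
            assert not iv.overlaps(d.basal)
    by_chrom = bundle.ucnes.by_chrom()
    for ivs in by_chrom.values():
        for a, b in zip(ivs, ivs[1:]):
            assert b.start - a.end >= cfg.ucne_min_separation


def test_constraint_track_deterministic_random_access():
    bundle = sd.generate(sd.SimulationConfig(seed=8, **SMALL))
    track = bundle.constraint
    v1 = track.values("chr1", 10_000, 12_000)
    v2 = track.values("chr1", 10_000, 12_000)
    assert np.array_equal(v1, v2)
    # a sub-query equals the corresponding slice of a larger query
    v3 = track.values("chr1", 10_500, 11_000)
    assert np.array_equal(v3, v1[500:1_000])


def test_constraint_shift_planted_in_elements():
    cfg = sd.SimulationConfig(seed=3, constraint_shift=2.0, **SMALL)
    bundle = sd.generate(cfg)
    iv = bundle.ucnes[0]
    inside = bundle.constraint.values(iv.chrom, iv.start, iv.end)
    null_track = sd.SyntheticConstraintTrack(
        seed=cfg.seed, assembly=bundle.assembly, ucnes=IntervalSet([]),
        flanks=IntervalSet([]), delta=0.0,
    )
    base = null_track.values(iv.chrom, iv.start, iv.end)
    assert np.allclose(base - inside, 2.0)


def test_null_configuration_identical_in_law():
    # delta = 0 and d = 1: element and background scores/rates share the model
    cfg = sd.SimulationConfig(
        seed=5, constraint_shift=0.0, ucne_common_depletion=1.0, **SMALL
    )
    bundle = sd.generate(cfg)
    iv = bundle.ucnes[0]
    inside = bundle.constraint.values(iv.chrom, iv.start, iv.end)
    outside = bundle.constraint.values("chr1", iv.end + 250, iv.end + 250 + len(iv))
    # same distribution: crude two-sigma mean check at these sample sizes
    assert abs(inside.mean() - outside.mean()) < 4 / np.sqrt(len(iv))


def test_variant_truth_bins_consistent_with_records():
    bundle = sd.generate(sd.SimulationConfig(seed=7, **SMALL))
    from ucre.variant_prioritization import classify_frequency

    for v in bundle.variants:
        assert bundle.truth.variant_bins[v.vid()] == classify_frequency(v).value


def test_worked_example_is_deterministic():
    a, b = sd.worked_example(), sd.worked_example()
    assert list(a.ucnes) == list(b.ucnes)
    assert a.stage_expr.equals(b.stage_expr)
    assert np.array_equal(
        a.constraint.values("chr1", 0, 5_000), b.constraint.values("chr1", 0, 5_000)
    )
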