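"""Candidate-CRE classification: open chromatin, marks, states, VISTA."""

import pytest

from ucre import ccre_annotation as ccre
from ucre.core_intervals import GenomicInterval, IntervalSet
from ucre.synthetic_data import SimulationConfig, generate

DEV = {"FW13/14", "FW15/16"}
ADULT = {"adult"}


def _ucnes(*spans):
    return IntervalSet(
        [GenomicInterval("chr1", s, e, name=f"U{i+1}") for i, (s, e) in enumerate(spans)]
    )


def test_identify_open_single_source_not_high_confidence():
    ucnes = _ucnes((100, 400), (1000, 1300))
    scatac = {("Rods", "FW13/14"): IntervalSet([GenomicInterval("chr1", 300, 600)])}
    profiles = ccre.identify_open_ucnes(ucnes, {}, scatac)
    by = {p.ucne.name: p for p in profiles}
    assert by["U1"].is_open and not by["U1"].high_confidence
    assert by["U1"].scatac_clusters == {("Rods", "FW13/14")}
    assert not by["U2"].is_open  # excluded from the active list
    assert [p.ucne.name for p in profiles if p.is_open] == ["U1"]


def test_identify_open_both_sources_high_confidence():
    ucnes = _ucnes((100, 400))
    dnase = {"E89": IntervalSet([GenomicInterval("chr1", 50, 150)])}
    scatac = {("Rods", "FW13/14"): IntervalSet([GenomicInterval("chr1", 350, 500)])}
    (p,) = ccre.identify_open_ucnes(ucnes, dnase, scatac)
    assert p.is_open and p.high_confidence


def test_annotate_marks_window_semantics():
    ucnes = _ucnes((1000, 1400))
    profiles = ccre.identify_open_ucnes(
        ucnes, {"E89": IntervalSet([GenomicInterval("chr1", 1000, 1400)])}, {}
    )
    near = {("H3K27ac", "FW13/14"): IntervalSet([GenomicInterval("chr1", 1600, 1900)])}
    counts = ccre.annotate_marks(profiles, near, flank=250)
    assert profiles[0].marks == {"H3K27ac": {"FW13/14"}}
    assert counts.loc["H3K27ac", "FW13/14"] == 1
    # 300 bp away: outside the window
    profiles2 = ccre.identify_open_ucnes(
        ucnes, {"E89": IntervalSet([GenomicInterval("chr1", 1000, 1400)])}, {}
    )
    far = {("H3K27ac", "FW13/14"): IntervalSet([GenomicInterval("chr1", 1700, 1900)])}
    ccre.annotate_marks(profiles2, far, flank=250)
    assert profiles2[0].marks == {}


def test_annotate_marks_rejects_unknown_mark():
    ucnes = _ucnes((1000, 1400))
    profiles = ccre.identify_open_ucnes(ucnes, {}, {})
    with pytest.raises(ValueError, match="H3K99me9"):
        ccre.annotate_marks(
            profiles, {("H3K99me9", "FW13/14"): IntervalSet([])}, flank=250
        )


@pytest.mark.parametrize(
    "marks,accessible,expected",
    [
        ({}, False, "none"),
        ({}, True, "open_only"),
        ({"H3K4me1": {"FW13/14"}}, True, "marked"),
        ({"H3K27me3": {"FW15/16"}}, True, "marked"),
        ({"H3K27ac": {"FW15/16"}}, True, "active_enhancer"),
        ({"H3K27ac": {"FW15/16", "adult"}}, True, "sustained_adult"),
        ({"H3K27ac": {"adult"}}, True, "marked"),  # adult-only is not developmental
    ],
)
def test_classify_enhancer_state(marks, accessible, expected):
    p = ccre.UCNEActivityProfile(ucne=GenomicInterval("chr1", 0, 300, name="U"))
    if accessible:
        p.dnase_stages.add("E89")
    p.marks = marks
    assert ccre.classify_enhancer_state(p, DEV, ADULT) == expected


def test_state_hierarchy_on_synthetic_cohort():
    bundle = generate(SimulationConfig(seed=3, n_ucnes=80, n_genes=30))
    truth = bundle.truth
    counts = {"open_only": 0, "marked": 0, "active_enhancer": 0, "sustained_adult": 0}
    for state in truth.ucne_state.values():
        if state in counts:
            counts[state] += 1
    n_open = sum(counts.values())
    n_marked = counts["marked"] + counts["active_enhancer"] + counts["sustained_adult"]
    n_active = counts["active_enhancer"] + counts["sustained_adult"]
    assert n_open >= n_marked >= n_active >= counts["sustained_adult"]


def test_mark_count_table_unique_column_bounds():
    ucnes = _ucnes((1000, 1400), (5000, 5300))
    dn = {"E89": IntervalSet([GenomicInterval("chr1", 1000, 1400),
                              GenomicInterval("chr1", 5000, 5300)])}
    profiles = ccre.identify_open_ucnes(ucnes, dn, {})
    chip = {
        ("H3K4me1", "FW13/14"): IntervalSet([GenomicInterval("chr1", 1100, 1200),
                                             GenomicInterval("chr1", 5000, 5100)]),
        ("H3K4me1", "FW15/16"): IntervalSet([GenomicInterval("chr1", 1100, 1200)]),
    }
    counts = ccre.annotate_marks(profiles, chip, flank=250)
    row = counts.loc["H3K4me1"]
    assert row["unique"] == 2  # <= sum over stages (3), >= max over stages (2)
    assert row["unique"] <= row[["FW13/14", "FW15/16"]].sum()
    assert row["unique"] >= row[["FW13/14", "FW15/16"]].max()


def test_enlarging_peaks_never_shrinks_active_list(rng):
    ucnes = _ucnes(*[(i * 1000, i * 1000 + 300) for i in range(20)])
    small = IntervalSet(
        [GenomicInterval("chr1", int(s), int(s) + 200) for s in rng.integers(0, 19_000, 8)]
    )
    big = IntervalSet(list(small) + [GenomicInterval("chr1", 0, 2_000)])
    active_small = {
        p.ucne.name
        for p in ccre.identify_open_ucnes(ucnes, {"E89": small}, {})
        if p.is_open
    }
    active_big = {
        p.ucne.name
        for p in ccre.identify_open_ucnes(ucnes, {"E89": big}, {})
        if p.is_open
    }
    assert active_small <= active_big


def test_h3k4_cooccurrence_fraction():
    ps = []
    for marks in ({"H3K27ac": {"FW13/14"}, "H3K4me1": {"FW13/14"}},
                  {"H3K27ac": {"FW13/14"}}):
        p = ccre.UCNEActivityProfile(ucne=GenomicInterval("chr1", 0, 300))
        p.dnase_stages.add("E89")
        p.marks = marks
        ccre.classify_enhancer_state(p, DEV, ADULT)
        ps.append(p)
    assert ccre.h3k4_cooccurrence_fraction(ps) == 0.5
    assert ccre.h3k4_cooccurrence_fraction([]) is None


def _label_table():
    return ccre.EnhancerLabelTable(
        [
            (GenomicInterval("chr1", 100, 300, name="e1"), "positive", ("eye",)),
            (GenomicInterval("chr1", 400, 600, name="e2"), "positive", ("eye", "limb")),
            (GenomicInterval("chr1", 700, 900, name="e3"), "negative", ()),
            (GenomicInterval("chr1", 1000, 1200, name="e4"), "negative", ()),
            (GenomicInterval("chr1", 5000, 5200, name="e5"), "positive", ("tail",)),
        ]
    )


def test_vista_correlate_half_positive():
    sets = {"q": IntervalSet([GenomicInterval("chr1", 0, 1100)])}
    (res,) = ccre.vista_correlate(sets, _label_table()).values()
    assert res.n_overlapped == 4 and res.n_positive == 2
    assert res.positive_proportion == 0.5
    # tissue mentions: eye 2, limb 1 over positives e1 + e2
    assert res.tissue_mention_fractions == {"eye": 2 / 3, "limb": 1 / 3}
    assert res.tissue_element_fractions == {"eye": 1.5 / 2, "limb": 0.5 / 2}


def test_vista_correlate_no_overlap_is_flagged_undefined():
    sets = {"q": IntervalSet([GenomicInterval("chr2", 0, 100)])}
    (res,) = ccre.vista_correlate(sets, _label_table()).values()
    assert res.undefined and res.n_overlapped == 0
    assert res.positive_proportion is None


def test_vista_label_table_validation():
    with pytest.raises(ValueError):
        ccre.EnhancerLabelTable(
            [(GenomicInterval("chr1", 0, 10), "positive", ())]
        )
    with pytest.raises(ValueError):
        ccre.EnhancerLabelTable(
            [(GenomicInterval("chr1", 0, 10), "negative", ("eye",))]
        )
    with pytest.raises(ValueError):
        ccre.EnhancerLabelTable(
            [(GenomicInterval("chr1", 0, 10), "maybe", ())]
        )


def test_vista_on_synthetic_labels_matches_brute_force():
    bundle = generate(SimulationConfig(seed=5, n_ucnes=60, n_genes=20))
    open_set = IntervalSet(
        [iv for iv in bundle.ucnes if bundle.truth.ucne_state[iv.name] != "none"]
    )
    (res,) = ccre.vista_correlate({"open": open_set}, bundle.enhancer_labels).values()
    n_over = n_pos = 0
    for iv, label, _tissues in bundle.enhancer_labels.elements:
        if any(iv.chrom == u.chrom and iv.start < u.end and u.start < iv.end for u in open_set):
            n_over += 1
            n_pos += label == "positive"
    assert (res.n_overlapped, res.n_positive) == (n_over, n_pos)
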