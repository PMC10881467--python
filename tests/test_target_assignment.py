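"""Regulatory-domain construction, target edges, filters and concordance."""

import numpy as np
import pandas as pd
import pytest

from ucre import target_assignment as ta
from ucre.ccre_annotation import UCNEActivityProfile
from ucre.core_intervals import GenomeAssembly, GenomicInterval, IntervalSet

from conftest import domain_member_oracle


def _assembly(n=10_000_000):
    return GenomeAssembly.from_dict({"chr1": n})


def test_single_gene_full_extension():
    genes = [ta.GeneModel("G", "chr1", 2_000_000, "+")]
    (d,) = ta.build_domains(genes, _assembly())
    assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
    assert (d.extended.start, d.extended.end) == (995_000, 3_001_000)


def test_minus_strand_basal_mirrored():
    genes = [ta.GeneModel("G", "chr1", 2_000_000, "-")]
    (d,) = ta.build_domains(genes, _assembly())
    assert (d.basal.start, d.basal.end) == (1_999_000, 2_005_000)


def test_extension_clamped_at_chromosome_start():
    genes = [ta.GeneModel("G", "chr1", 3_000, "+")]
    (d,) = ta.build_domains(genes, _assembly())
    assert d.basal.start == 0  # basal itself clamped
    assert d.extended.start == 0


def test_two_genes_extend_to_neighbour_basal():
    genes = [
        ta.GeneModel("A", "chr1", 2_000_000, "+"),
        ta.GeneModel("B", "chr1", 2_100_000, "+"),
    ]
    da, db = ta.build_domains(genes, _assembly())
    # A's right extension stops at B's basal start; B's left at A's basal end
    assert da.extended.end == db.basal.start == 2_095_000
    assert db.extended.start == da.basal.end == 2_001_000


def test_overlapping_basal_blocks_extension():
    genes = [
        ta.GeneModel("A", "chr1", 2_000_000, "+"),
        ta.GeneModel("B", "chr1", 2_002_000, "+"),  # B's basal overlaps A's
    ]
    da, db = ta.build_domains(genes, _assembly())
    assert da.extended.end == da.basal.end  # no right extension for A
    assert db.extended.start == db.basal.start  # no left extension for B
    assert da.extended.start == da.basal.start - 1_000_000
    assert db.extended.end == db.basal.end + 1_000_000


def test_duplicate_gene_id_rejected():
    genes = [
        ta.GeneModel("A", "chr1", 1_000_000, "+"),
        ta.GeneModel("A", "chr1", 2_000_000, "+"),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        ta.build_domains(genes, _assembly())


def test_curated_override_replaces_extended():
    genes = [ta.GeneModel("G", "chr1", 2_000_000, "+")]
    override = GenomicInterval("chr1", 100_000, 5_000_000, name="G")
    (d,) = ta.build_domains(genes, _assembly(), curated={"G": override})
    assert d.effective == override
    assert d.extended != override  # computed domain still recorded


def _oracle_check(genes, chrom_len, up, down, max_ext, probes):
    domains = ta.build_domains(genes, GenomeAssembly.from_dict({"chr1": chrom_len}),
                               up=up, down=down, max_ext=max_ext)
    for d in domains:
        for x in probes:
            member = d.extended.start <= x < d.extended.end
            want = domain_member_oracle(x, d.gene, genes, chrom_len, up, down, max_ext)
            assert member == want, (d.gene.gene_id, x)


def test_random_layouts_match_per_base_oracle(rng):
    chrom_len = 100_000
    for _ in range(20):
        n = int(rng.integers(2, 8))
        genes = [
            ta.GeneModel(
                f"g{i}", "chr1", int(rng.integers(0, chrom_len)),
                "+" if rng.random() < 0.5 else "-",
            )
            for i in range(n)
        ]
        probes = list(rng.integers(0, chrom_len, size=300))
        # add all boundary-adjacent probes
        domains = ta.build_domains(
            genes, GenomeAssembly.from_dict({"chr1": chrom_len}),
            up=500, down=100, max_ext=10_000,
        )
        for d in domains:
            for b in (d.basal.start, d.basal.end, d.extended.start, d.extended.end):
                probes.extend([max(0, b - 1), b % chrom_len])
        _oracle_check(genes, chrom_len, 500, 100, 10_000, sorted(set(map(int, probes))))


def test_equidistant_neighbours():
    # C sits exactly between A and B; its extensions meet both basal domains
    genes = [
        ta.GeneModel("A", "chr1", 1_000_000, "+"),
        ta.GeneModel("C", "chr1", 1_500_000, "+"),
        ta.GeneModel("B", "chr1", 2_000_000, "+"),
    ]
    domains = {d.gene.gene_id: d for d in ta.build_domains(genes, _assembly())}
    assert domains["C"].extended.start == domains["A"].basal.end
    assert domains["C"].extended.end == domains["B"].basal.start


def _toy_layout():
    assembly = GenomeAssembly.from_dict({"chr1": 10_000_000})
    genes = [
        ta.GeneModel("A", "chr1", 1_000_000, "+"),
        ta.GeneModel("B", "chr1", 3_500_000, "-"),
    ]
    domains = ta.build_domains(genes, assembly)
    ucnes = IntervalSet(
        [
            GenomicInterval("chr1", 900_000, 900_300, name="U1"),  # A only
            GenomicInterval("chr1", 2_800_000, 2_800_300, name="U2"),  # A and B
            GenomicInterval("chr1", 6_000_000, 6_000_300, name="U3"),  # neither
        ]
    )
    return assembly, genes, domains, ucnes


def test_assign_targets_counts_and_distances():
    _assembly_, genes, domains, ucnes = _toy_layout()
    edges = ta.assign_targets(ucnes, domains)
    by_ucne = edges.groupby("ucne")["gene"].apply(set).to_dict()
    # U2 at 2.8 Mb is beyond A's 1 Mb extension but inside B's left extension
    assert by_ucne == {"U1": {"A"}, "U2": {"B"}}
    u1 = edges[(edges.ucne == "U1") & (edges.gene == "A")].iloc[0]
    assert u1.distance == 1_000_000 - 900_300  # TSS right of the element
    assert u1.distance_bin == "50-500kb"
    hist = ta.genes_per_ucne_histogram(edges)
    assert hist.to_dict() == {1: 2}


def test_assign_targets_matches_brute_force(rng):
    chrom_len = 1_000_000
    assembly = GenomeAssembly.from_dict({"chr1": chrom_len})
    genes = [
        ta.GeneModel(f"g{i}", "chr1", int(t), "+")
        for i, t in enumerate(sorted(rng.integers(20_000, chrom_len - 20_000, 6)))
    ]
    domains = ta.build_domains(genes, assembly, up=5_000, down=1_000, max_ext=100_000)
    ucnes = IntervalSet(
        [
            GenomicInterval("chr1", int(s), int(s) + 300, name=f"u{i}")
            for i, s in enumerate(rng.integers(0, chrom_len - 300, 40))
        ]
    )
    edges = ta.assign_targets(ucnes, domains)
    got = set(zip(edges.ucne, edges.gene))
    want = {
        (u.name, d.gene.gene_id)
        for u in ucnes
        for d in domains
        if u.start < d.effective.end and d.effective.start < u.end
    }
    assert got == want


def test_single_gene_captures_all_ucnes_with_unbounded_extension(rng):
    chrom_len = 5_000_000
    assembly = GenomeAssembly.from_dict({"chr1": chrom_len})
    genes = [ta.GeneModel("G", "chr1", 2_500_000, "+")]
    domains = ta.build_domains(genes, assembly, max_ext=chrom_len)
    ucnes = IntervalSet(
        [
            GenomicInterval("chr1", int(s), int(s) + 250, name=f"u{i}")
            for i, s in enumerate(rng.integers(0, chrom_len - 250, 30))
        ]
    )
    edges = ta.assign_targets(ucnes, domains)
    assert set(edges.ucne) == {iv.name for iv in ucnes}


def test_filter_expressed_thresholds():
    edges = pd.DataFrame(
        {"ucne": ["U1"] * 4, "gene": ["a", "b", "c", "d"],
         "distance": [0] * 4, "distance_bin": ["0-5kb"] * 4}
    )
    expr = pd.DataFrame(
        {"s1": [0.6, 0.49, 0.5, 0.0], "s2": [0.0, 0.2, 0.1, 0.0]},
        index=["a", "b", "c", "x"],
    )
    kept, n_missing = ta.filter_expressed(edges, expr)
    assert set(kept.gene) == {"a", "c"}  # 0.5 exactly counts as expressed
    assert n_missing == 1  # gene d absent from the matrix
    again, _ = ta.filter_expressed(kept, expr)
    assert again.equals(kept)  # idempotent


def test_tad_consistency_half_open_boundary():
    ucnes = IntervalSet([GenomicInterval("chr1", 100, 400, name="U1")])
    genes = [ta.GeneModel("A", "chr1", 1_000, "+"), ta.GeneModel("B", "chr1", 500, "+")]
    edges = pd.DataFrame(
        {"ucne": ["U1", "U1"], "gene": ["A", "B"], "distance": [0, 0],
         "distance_bin": ["0-5kb", "0-5kb"]}
    )
    tads = ta.TADSet(IntervalSet([GenomicInterval("chr1", 0, 1_000)]))
    out, fraction = ta.tad_consistency(edges, tads, ucnes, genes)
    flags = dict(zip(out.gene, out.tad_consistent))
    assert flags == {"A": False, "B": True}  # TSS at the exclusive end is outside
    assert fraction == 0.5


def test_tad_consistency_matches_brute_force(rng):
    chrom_len = 100_000
    ucnes = IntervalSet(
        [GenomicInterval("chr1", int(s), int(s) + 200, name=f"u{i}")
         for i, s in enumerate(rng.integers(0, chrom_len - 200, 15))]
    )
    genes = [ta.GeneModel(f"g{i}", "chr1", int(t), "+")
             for i, t in enumerate(rng.integers(0, chrom_len, 10))]
    rows = [
        {"ucne": u.name, "gene": g.gene_id, "distance": 0, "distance_bin": "0-5kb"}
        for u in ucnes
        for g in genes
        if rng.random() < 0.3
    ]
    edges = pd.DataFrame(rows)
    bounds = sorted(set([0, chrom_len] + [int(b) for b in rng.integers(1, chrom_len, 6)]))
    tad_ivs = [GenomicInterval("chr1", a, b) for a, b in zip(bounds, bounds[1:])]
    tads = ta.TADSet(IntervalSet(tad_ivs))
    out, _ = ta.tad_consistency(edges, tads, ucnes, genes)
    by_name = {iv.name: iv for iv in ucnes}
    by_gene = {g.gene_id: g for g in genes}
    for row in out.itertuples(index=False):
        u, g = by_name[row.ucne], by_gene[row.gene]
        want = any(
            t.start < u.end and u.start < t.end and t.start <= g.tss < t.end
            for t in tad_ivs
        )
        assert row.tad_consistent == want


def test_tadset_rejects_overlap():
    with pytest.raises(ValueError, match="overlapping"):
        ta.TADSet(IntervalSet([GenomicInterval("chr1", 0, 100),
                               GenomicInterval("chr1", 50, 150)]))


def test_assign_signatures_single_high_cluster():
    expr = pd.DataFrame([[0.0] * 9 + [5.0]], index=["G"],
                        columns=[f"c{i}" for i in range(10)])
    sigs = ta.assign_signatures(expr)
    assert sigs["G"].clusters == frozenset({"c9"})


def test_assign_signatures_constant_gene_empty():
    expr = pd.DataFrame([[2.0] * 8, [0.0] * 8], index=["G", "Z"],
                        columns=[f"c{i}" for i in range(8)])
    sigs = ta.assign_signatures(expr)
    assert sigs["G"].clusters == frozenset()
    assert sigs["Z"].clusters == frozenset()  # all-zero gene is not an error


def test_assign_signatures_matches_brute_force(rng):
    values = rng.uniform(0, 100, size=(50, 12))
    cols = [f"c{i}" for i in range(12)]
    expr = pd.DataFrame(values, index=[f"g{i}" for i in range(50)], columns=cols)
    sigs = ta.assign_signatures(expr, pct=80)
    for i, gene in enumerate(expr.index):
        vals = sorted(values[i])
        h = (len(vals) - 1) * 0.8  # linear-interpolation percentile by hand
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        thr = vals[lo] + (h - lo) * (vals[hi] - vals[lo])
        want = frozenset(c for c, v in zip(cols, values[i]) if v > thr)
        assert sigs[gene].clusters == want


def test_assign_signatures_needs_two_clusters():
    expr = pd.DataFrame([[1.0]], index=["G"], columns=["c0"])
    with pytest.raises(ValueError):
        ta.assign_signatures(expr)


def _profile(name, span, clusters):
    p = UCNEActivityProfile(ucne=GenomicInterval("chr1", *span, name=name))
    p.scatac_clusters = {(c, "FW13/14") for c in clusters}
    return p


def test_concordance_basic_and_unmapped_error():
    edges = pd.DataFrame(
        {"ucne": ["U1", "U2"], "gene": ["A", "B"], "distance": [0, 0],
         "distance_bin": ["0-5kb"] * 2}
    )
    profiles = [
        _profile("U1", (0, 300), {"GanglionPrecursors"}),
        _profile("U2", (1000, 1300), {"Rods"}),
    ]
    sigs = {
        "A": ta.ExpressionSignature("A", frozenset({"GanglionPrecursors", "Rods"})),
        "B": ta.ExpressionSignature("B", frozenset({"MullerGlia"})),
    }
    table, fraction = ta.concordance(edges, profiles, sigs)
    assert dict(zip(table.ucne, table.concordant)) == {"U1": True, "U2": False}
    assert fraction == 0.5
    with pytest.raises(ValueError, match="unmapped"):
        ta.concordance(edges, profiles, sigs, cluster_map={"Rods": "Rods"})


def test_peak2gene_strict_threshold_and_relations():
    ucnes = IntervalSet(
        [GenomicInterval("chr1", 0, 300, name="U1"),
         GenomicInterval("chr1", 10_000, 10_300, name="U2")]
    )
    edges = pd.DataFrame(
        {"ucne": ["U1", "U1", "U2"], "gene": ["A", "B", "C"],
         "distance": [0] * 3, "distance_bin": ["0-5kb"] * 3}
    )
    linkages = [
        (GenomicInterval("chr1", 0, 300), "A", 0.8),
        (GenomicInterval("chr1", 0, 300), "B", 0.5),
        (GenomicInterval("chr1", 10_000, 10_300), "C", 0.4),  # exactly 0.4: out
    ]
    out = ta.peak2gene_compare(edges, linkages, ucnes)
    rel = dict(zip(out.ucne, out.relation))
    assert rel == {"U1": "identical", "U2": "disjoint"}
    # partial case: one shared gene, one extra
    linkages.append((GenomicInterval("chr1", 10_000, 10_300), "C", 0.6))
    linkages.append((GenomicInterval("chr1", 10_000, 10_300), "Z", 0.6))
    out = ta.peak2gene_compare(edges, linkages, ucnes)
    assert dict(zip(out.ucne, out.relation))["U2"] == "partial"


def test_disease_gene_filter():
    edges = pd.DataFrame(
        {"ucne": ["U1", "U2", "U3"], "gene": ["A", "B", "C"],
         "distance": [0] * 3, "distance_bin": ["0-5kb"] * 3}
    )
    table = pd.DataFrame(
        {"gene_id": ["B"], "panel": ["Eye"], "phenotype": ["retinal dystrophy"]}
    )
    kept = ta.disease_gene_filter(edges, table)
    assert list(kept.gene) == ["B"] and list(kept.panel) == ["Eye"]
    empty = ta.disease_gene_filter(edges, table.iloc[:0])
    assert len(empty) == 0
    with pytest.raises(ValueError, match="duplicate"):
        ta.disease_gene_filter(edges, pd.concat([table, table]))


def test_filter_chain_monotone(rng):
    _assembly_, genes, domains, ucnes = _toy_layout()
    edges = ta.assign_targets(ucnes, domains)
    expr = pd.DataFrame({"s1": [1.0, 0.0]}, index=["A", "B"])
    expressed, _ = ta.filter_expressed(edges, expr)
    assert len(expressed) <= len(edges)
    table = pd.DataFrame({"gene_id": ["A"], "panel": ["Eye"], "phenotype": ["x"]})
    disease = ta.disease_gene_filter(expressed, table)
    assert len(disease) <= len(expressed)
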