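"""Synthetic multi-omics inputs with a planted ground truth.

Generates everything the pipeline consumes — genome, gene models,
ultraconserved elements, per-cluster accessibility signal, per-mark histone
signal, DNase peak sets, TADs, stage and cluster expression matrices,
peak-to-gene linkages, a disease-gene table, a variant cohort and a
constraint-score track — together with a :class:`TruthTable` recording what
was planted, so every pipeline stage can be checked against ground truth.

Default parameters emulate the statistical structure of the retinal study
system: roughly one-third of elements open, a nested minority carrying
histone marks / H3K27ac / adult-sustained H3K27ac, most target genes
expressed, common variation depleted inside elements (factor ``d``), and
constraint scores shifted down by ``delta`` in elements and ``delta/2`` in
their flanks.

The truth table is computed from the generator's own closed-form layout
(sorted-neighbour domain boundaries, direct containment scans), not by
calling the pipeline, so agreement between the two is a real check.
"""

from __future__ import annotations

import dataclasses
import json
import os
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats
from .ccre_annotation import ACTIVATING_MARKS, DEFAULT_MARKS, EnhancerLabelTable
from .core_intervals import GenomeAssembly, GenomicInterval, IntervalSet, merge
from .target_assignment import (
    BASAL_DOWNSTREAM,
    BASAL_UPSTREAM,
    GeneModel,
    MAX_EXTENSION,
)
from .tracks import ConstraintTrack, SignalTrack
from .variant_prioritization import VariantRecord

DEFAULT_CLUSTERS = (
    "EarlyProgenitors",
    "LateProgenitors",
    "GanglionPrecursors",
    "PhotoreceptorPrecursors",
    "AmacrineHorizontalPrecursors",
    "BipolarPrecursors",
    "MullerGlia",
    "Rods",
)
DEFAULT_STAGES = ("FW13/14", "FW15/16", "FW18/20", "FW23/24")
DEFAULT_ADULT_STAGE = "adult"
DEFAULT_DNASE_STAGES = ("E74-85", "E89", "E103-125")
DEFAULT_RNA_STAGES = ("D52", "D80", "D107", "D136")
VISTA_TISSUES = ("eye", "forebrain", "hindbrain", "midbrain", "neural tube", "limb", "tail")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study system (defaults = study conditions)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 60
    n_ucnes: int = 150
    # nested activity fractions (of all elements), mirroring 1487/834/111/33
    # out of the 4351-element catalogue
    frac_open: float = 0.34
    frac_marked: float = 0.19
    frac_active: float = 0.026
    frac_adult_sustained: float = 0.008
    high_confidence_frac: float = 0.8
    stages: tuple = DEFAULT_STAGES
    adult_stage: str = DEFAULT_ADULT_STAGE
    dnase_stages: tuple = DEFAULT_DNASE_STAGES
    rna_stages: tuple = DEFAULT_RNA_STAGES
    clusters: tuple = DEFAULT_CLUSTERS
    tad_mean_size: int = 200_000
    expr_tpm_high: float = 10.0
    expressed_target_frac: float = 0.82  # 594/724
    concordant_frac: float = 0.543  # 808/1487
    p2g_identical_frac: float = 0.35
    p2g_partial_frac: float = 0.15
    disease_gene_frac: float = 0.08  # 45/594
    n_label_elements: int = 120
    label_positive_frac_open: float = 0.68  # 272/402
    label_positive_frac_other: float = 0.5
    common_variant_rate: float = 0.008  # total variants per bp, all bins
    bin_shares: tuple = (0.5, 0.15, 0.1, 0.1, 0.15)  # ultrarare..common
    ucne_common_depletion: float = 0.2  # d
    constraint_shift: float = 0.5  # delta
    n_svs: int = 5
    n_cases: int = 60
    unsolved_frac: float = 0.56  # 1802/3206
    n_variant_carriers: int = 3  # max carriers per variant
    background_peaks_per_track: float = 12.0
    ucne_min_len: int = 250
    ucne_max_len: int = 600
    ucne_min_separation: int = 1_500
    gene_min_spacing: int = 20_000

    def __post_init__(self) -> None:
        if not (
            self.frac_open
            >= self.frac_marked
            >= self.frac_active
            >= self.frac_adult_sustained
            >= 0
        ):
            raise ValueError("activity fractions must be nested")
        if abs(sum(self.bin_shares) - 1.0) > 1e-9:
            raise ValueError("bin shares must sum to 1")
        if not (0 <= self.ucne_common_depletion <= 1):
            raise ValueError("depletion d must lie in [0, 1]")
        if self.constraint_shift < 0:
            raise ValueError("constraint shift delta must be >= 0")


@dataclass
class TruthTable:
    """Planted structure, recorded independently of the pipeline code."""

    ucne_state: dict = field(default_factory=dict)  # name -> ladder state
    dnase_stages: dict = field(default_factory=dict)  # name -> set of stages
    scatac_clusters: dict = field(default_factory=dict)  # name -> set of (cluster, stage)
    marks: dict = field(default_factory=dict)  # name -> {mark: set of stages}
    high_confidence: set = field(default_factory=set)
    edges: list = field(default_factory=list)  # (ucne, gene)
    edge_tad: dict = field(default_factory=dict)  # (ucne, gene) -> bool
    gene_expressed: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)  # gene -> frozenset of clusters
    concordant: dict = field(default_factory=dict)  # ucne -> bool
    p2g_relation: dict = field(default_factory=dict)  # ucne -> relation
    disease_genes: set = field(default_factory=set)
    variant_bins: dict = field(default_factory=dict)  # vid -> bin name
    variant_ucne: dict = field(default_factory=dict)  # vid -> ucne name or None
    search_space: dict = field(default_factory=dict)  # summary counts

    def open_ucnes(self) -> set:
        return {u for u, s in self.ucne_state.items() if s != "none"}

    def to_json(self) -> dict:
        def conv(x):
            if isinstance(x, (set, frozenset)):
                return sorted(map(str, x))
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


class SyntheticConstraintTrack(ConstraintTrack):
    """Procedural per-base N(0, 1) constraint scores with planted shifts.

    Deterministic random access: base ``i`` of a chromosome draws its score
    from a block-keyed RNG, then the planted shift is subtracted (``-delta``
    inside elements, ``-delta/2`` inside flanks).  Per-base values are i.i.d.,
    which is what makes the downstream rank tests exactly calibrated under
    the null.
    """

    BLOCK = 4096

    def __init__(
        self,
        seed: int,
        assembly: GenomeAssembly,
        ucnes: IntervalSet,
        flanks: IntervalSet,
        delta: float,
    ) -> None:
        super().__init__()
        self.seed = int(seed)
        self.assembly = assembly
        self.delta = float(delta)
        self._chrom_index = {c: i for i, c in enumerate(assembly.chrom_names)}
        self._ucnes = merge(ucnes, 0).by_chrom()
        self._flanks = merge(flanks, 0).by_chrom()

    def chroms(self):
        return list(self.assembly.chrom_names)

    def _base_scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        ci = self._chrom_index[chrom]
        first, last = start // self.BLOCK, (end - 1) // self.BLOCK
        chunks = []
        for b in range(first, last + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, ci, b])
            )
            chunks.append(rng.standard_normal(self.BLOCK))
        values = np.concatenate(chunks)
        off = start - first * self.BLOCK
        return values[off : off + (end - start)]

    def values(self, chrom: str, start: int, end: int, missing_as_nan: bool = False):
        if end <= start:
            raise ValueError("end must exceed start")
        if chrom not in self._chrom_index:
            return np.full(end - start, np.nan if missing_as_nan else 0.0)
        out = self._base_scores(chrom, start, end)
        for regions, shift in ((self._ucnes, self.delta), (self._flanks, self.delta / 2)):
            for iv in regions.get(chrom, []):
                a, b = max(iv.start, start), min(iv.end, end)
                if a < b:
                    out[a - start : b - start] -= shift
        return out

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values(chrom, pos, pos + 1)[0])


@dataclass
class SyntheticBundle:
    """The full in-memory input bundle plus its truth table."""

    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list
    ucnes: IntervalSet
    scatac_tracks: dict  # (cluster, stage) -> SignalTrack
    chip_tracks: dict  # (mark, stage) -> SignalTrack
    dnase_peaks: dict  # stage -> IntervalSet
    dnase_labels: dict  # peak name -> category
    tads: IntervalSet
    stage_expr: pd.DataFrame
    cluster_expr: pd.DataFrame
    linkages: list  # (interval, gene, correlation)
    disease_table: pd.DataFrame
    enhancer_labels: EnhancerLabelTable
    variants: list
    case_solved: dict
    constraint: SyntheticConstraintTrack
    truth: TruthTable


# ---------------------------------------------------------------------------
# generation helpers


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = cfg.n_genes // cfg.n_chroms
    extra = cfg.n_genes - per_chrom * cfg.n_chroms
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        k = per_chrom + (1 if ci < extra else 0)
        margin = BASAL_UPSTREAM + 1000
        usable = cfg.chrom_length - 2 * margin
        slot = usable / k
        if slot < cfg.gene_min_spacing:
            raise ValueError("cannot place genes with the requested spacing")
        for i in range(k):
            jitter = rng.integers(0, max(1, int(slot - cfg.gene_min_spacing) + 1))
            tss = margin + int(i * slot) + int(jitter)
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(f"gene_{gid:04d}", chrom, tss, strand))
    return genes


def _basal(g: GeneModel, chrom_len: int) -> tuple[int, int]:
    if g.strand == "+":
        s, e = g.tss - BASAL_UPSTREAM, g.tss + BASAL_DOWNSTREAM
    else:
        s, e = g.tss - BASAL_DOWNSTREAM, g.tss + BASAL_UPSTREAM
    return max(0, s), min(chrom_len, e)


def _closed_form_domains(
    genes: list[GeneModel], chrom_len: int
) -> dict[str, tuple[int, int]]:
    """Sorted-neighbour extended-domain boundaries (generator's own rule)."""
    ordered = sorted(genes, key=lambda g: g.tss)
    basals = [_basal(g, chrom_len) for g in ordered]
    out = {}
    for i, g in enumerate(ordered):
        bs, be = basals[i]
        left = max(0, bs - MAX_EXTENSION, basals[i - 1][1] if i > 0 else 0)
        right = min(
            chrom_len,
            be + MAX_EXTENSION,
            basals[i + 1][0] if i + 1 < len(basals) else chrom_len,
        )
        out[g.gene_id] = (left, right)
    return out


def _place_ucnes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes_by_chrom: dict[str, list[GeneModel]],
) -> IntervalSet:
    ucnes = []
    count = 0
    per_chrom = cfg.n_ucnes // cfg.n_chroms
    extra = cfg.n_ucnes - per_chrom * cfg.n_chroms
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        k = per_chrom + (1 if ci < extra else 0)
        forbidden = [
            _basal(g, cfg.chrom_length) for g in genes_by_chrom.get(chrom, [])
        ]
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < k and tries < 200 * k:
            tries += 1
            length = int(rng.integers(cfg.ucne_min_len, cfg.ucne_max_len + 1))
            start = int(rng.integers(0, cfg.chrom_length - length))
            end = start + length
            if any(start < fe and fs < end for fs, fe in forbidden):
                continue
            sep = cfg.ucne_min_separation
            if any(start < pe + sep and ps - sep < end for ps, pe in placed):
                continue
            placed.append((start, end))
        if len(placed) < k:
            raise ValueError("cannot place the requested number of elements")
        for start, end in sorted(placed):
            count += 1
            ucnes.append(
                GenomicInterval(chrom, start, end, name=f"ucne_{count:04d}")
            )
    return IntervalSet(ucnes)


def _nonoverlapping_background(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    n: int,
    width_range: tuple[int, int],
    avoid: list[GenomicInterval],
    pad: int,
    existing: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Random peaks avoiding (padded) forbidden intervals and each other."""
    out = []
    taken = list(existing)
    tries = 0
    while len(out) < n and tries < 50 * max(1, n):
        tries += 1
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        if chrom_len <= width:
            break
        start = int(rng.integers(0, chrom_len - width))
        end = start + width
        if any(start < iv.end + pad and iv.start - pad < end for iv in avoid):
            continue
        if any(start < te and ts < end for ts, te in taken):
            continue
        out.append((start, end))
        taken.append((start, end))
    return out


def _tile_tads(cfg: SimulationConfig, rng: np.random.Generator) -> IntervalSet:
    tads = []
    count = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 0
        while pos < cfg.chrom_length:
            size = int(
                np.clip(
                    rng.exponential(cfg.tad_mean_size),
                    cfg.tad_mean_size // 4,
                    2 * cfg.tad_mean_size,
                )
            )
            end = min(cfg.chrom_length, pos + size)
            count += 1
            tads.append(GenomicInterval(chrom, pos, end, name=f"tad_{count:04d}"))
            pos = end
    return IntervalSet(tads)


# ---------------------------------------------------------------------------
# main generator


def generate(cfg: Optional[SimulationConfig] = None) -> SyntheticBundle:
    """Build the full synthetic bundle for a configuration (deterministic)."""
    cfg = cfg or SimulationConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(9)
    rng_place, rng_state, rng_tracks, rng_expr, rng_link, rng_disease, rng_var, rng_label, rng_tad = (
        np.random.default_rng(s) for s in streams
    )

    assembly = GenomeAssembly.from_dict(
        {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    )
    genes = _place_genes(cfg, rng_place)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    ucnes = _place_ucnes(cfg, rng_place, genes_by_chrom)
    truth = TruthTable()

    # ---- planted edges from the closed-form domain rule
    domains = {}
    for chrom, chrom_genes in genes_by_chrom.items():
        for gid, bounds in _closed_form_domains(chrom_genes, cfg.chrom_length).items():
            domains[gid] = (chrom, bounds[0], bounds[1])
    for iv in ucnes:
        for gid, (chrom, left, right) in domains.items():
            if chrom == iv.chrom and iv.start < right and left < iv.end:
                truth.edges.append((iv.name, gid))
    truth.edges.sort()

    # ---- activity states (nested subsets of a shuffled element order)
    names = [iv.name for iv in ucnes]
    order = list(names)
    rng_state.shuffle(order)
    n_open = int(round(cfg.frac_open * cfg.n_ucnes))
    n_marked = int(round(cfg.frac_marked * cfg.n_ucnes))
    n_active = int(round(cfg.frac_active * cfg.n_ucnes))
    n_adult = int(round(cfg.frac_adult_sustained * cfg.n_ucnes))
    open_names = order[:n_open]
    marked_names = set(order[:n_marked])
    active_names = set(order[:n_active])
    adult_names = set(order[:n_adult])
    for name in names:
        if name in adult_names:
            truth.ucne_state[name] = "sustained_adult"
        elif name in active_names:
            truth.ucne_state[name] = "active_enhancer"
        elif name in marked_names:
            truth.ucne_state[name] = "marked"
        elif name in open_names:
            truth.ucne_state[name] = "open_only"
        else:
            truth.ucne_state[name] = "none"

    by_name = {iv.name: iv for iv in ucnes}
    all_stages = list(cfg.stages)
    for name in open_names:
        both = rng_state.random() < cfg.high_confidence_frac
        use_dnase = both or rng_state.random() < 0.5
        use_scatac = both or not use_dnase
        dn, sc = set(), set()
        if use_dnase:
            k = int(rng_state.integers(1, min(2, len(cfg.dnase_stages)) + 1))
            dn = set(rng_state.choice(cfg.dnase_stages, size=k, replace=False))
        if use_scatac:
            k = int(rng_state.integers(1, 4))
            clusters = rng_state.choice(cfg.clusters, size=min(k, len(cfg.clusters)), replace=False)
            sc = {
                (str(c), all_stages[int(rng_state.integers(0, len(all_stages)))])
                for c in clusters
            }
        truth.dnase_stages[name] = dn
        truth.scatac_clusters[name] = sc
        if dn and sc:
            truth.high_confidence.add(name)

    # ---- marks for the nested subsets
    non_k27 = [m for m in DEFAULT_MARKS if m != "H3K27ac"]
    for name in marked_names:
        marks: dict[str, set] = {}
        if name in active_names:
            k = int(rng_state.integers(1, 3))
            stages = rng_state.choice(all_stages, size=k, replace=False)
            marks["H3K27ac"] = set(map(str, stages))
            if rng_state.random() < 0.95:
                co = "H3K4me1" if rng_state.random() < 0.5 else "H3K4me2"
                marks.setdefault(co, set()).add(
                    all_stages[int(rng_state.integers(0, len(all_stages)))]
                )
            if name in adult_names:
                marks["H3K27ac"].add(cfg.adult_stage)
        else:
            k = int(rng_state.integers(1, 4))
            for m in rng_state.choice(non_k27, size=k, replace=False):
                marks.setdefault(str(m), set()).add(
                    all_stages[int(rng_state.integers(0, len(all_stages)))]
                )
        truth.marks[name] = marks

    # ---- accessibility signal tracks (scATAC per cluster/stage)
    chip_stage_list = all_stages + [cfg.adult_stage]
    scatac_runs: dict[tuple, dict[str, list]] = {}
    for name in open_names:
        iv = by_name[name]
        for cluster, stage in sorted(truth.scatac_clusters.get(name, set())):
            pad_l = int(rng_tracks.integers(50, 151))
            pad_r = int(rng_tracks.integers(50, 151))
            value = float(rng_tracks.uniform(0.6, 1.5))
            run = (max(0, iv.start - pad_l), min(cfg.chrom_length, iv.end + pad_r), value)
            scatac_runs.setdefault((cluster, stage), {}).setdefault(iv.chrom, []).append(run)
    all_ucne_list = list(ucnes)
    scatac_tracks = {}
    for cluster in cfg.clusters:
        for stage in all_stages:
            key = (cluster, stage)
            runs = scatac_runs.get(key, {})
            n_bg = rng_tracks.poisson(cfg.background_peaks_per_track)
            for ci in range(cfg.n_chroms):
                chrom = f"chr{ci + 1}"
                existing = [(s, e) for s, e, _v in runs.get(chrom, [])]
                share = n_bg // cfg.n_chroms
                for s, e in _nonoverlapping_background(
                    rng_tracks, chrom, cfg.chrom_length, share, (250, 500),
                    all_ucne_list, 1, existing,
                ):
                    runs.setdefault(chrom, []).append(
                        (s, e, float(rng_tracks.uniform(0.45, 1.2)))
                    )
            if runs:
                scatac_tracks[key] = SignalTrack.from_runs(
                    {c: sorted(r) for c, r in runs.items()}, assembly
                )
            else:
                scatac_tracks[key] = SignalTrack.from_runs({}, assembly)

    # ---- histone-mark signal tracks
    chip_runs: dict[tuple, dict[str, list]] = {}
    for name in sorted(marked_names):
        iv = by_name[name]
        for mark, stages in sorted(truth.marks[name].items()):
            for stage in sorted(stages):
                # place the peak overlapping the element or within the
                # ±250 bp window used downstream
                width = int(rng_tracks.integers(300, 801))
                if rng_tracks.random() < 0.3:
                    gap = int(rng_tracks.integers(1, 201))
                    if rng_tracks.random() < 0.5:
                        start = iv.end + gap
                    else:
                        start = iv.start - gap - width
                else:
                    start = iv.start - int(rng_tracks.integers(0, 101))
                start = max(0, start)
                end = min(cfg.chrom_length, start + width)
                value = float(rng_tracks.uniform(25, 60))
                chip_runs.setdefault((mark, stage), {}).setdefault(iv.chrom, []).append(
                    (start, end, value)
                )
    chip_tracks = {}
    for mark in DEFAULT_MARKS:
        for stage in chip_stage_list:
            key = (mark, stage)
            runs = chip_runs.get(key, {})
            n_bg = rng_tracks.poisson(cfg.background_peaks_per_track / 2)
            for ci in range(cfg.n_chroms):
                chrom = f"chr{ci + 1}"
                existing = [(s, e) for s, e, _v in runs.get(chrom, [])]
                for s, e in _nonoverlapping_background(
                    rng_tracks, chrom, cfg.chrom_length, n_bg // cfg.n_chroms,
                    (300, 800), all_ucne_list, 251, existing,
                ):
                    runs.setdefault(chrom, []).append(
                        (s, e, float(rng_tracks.uniform(22, 50)))
                    )
            chip_tracks[key] = SignalTrack.from_runs(
                {c: sorted(r) for c, r in runs.items()}, assembly
            )

    # ---- DNase peak sets with rDHS-style category labels
    dnase_peaks = {}
    dnase_labels = {}
    pk = 0
    for stage in cfg.dnase_stages:
        ivs = []
        for name in sorted(open_names):
            if stage in truth.dnase_stages.get(name, set()):
                iv = by_name[name]
                pad = int(rng_tracks.integers(20, 120))
                pk += 1
                peak_name = f"dnase_{pk:05d}"
                ivs.append(
                    GenomicInterval(
                        iv.chrom,
                        max(0, iv.start - pad),
                        min(cfg.chrom_length, iv.end + pad),
                        name=peak_name,
                    )
                )
                dnase_labels[peak_name] = "High-DNase"
        for ci in range(cfg.n_chroms):
            chrom = f"chr{ci + 1}"
            existing = [(p.start, p.end) for p in ivs if p.chrom == chrom]
            for s, e in _nonoverlapping_background(
                rng_tracks, chrom, cfg.chrom_length, 6, (200, 400),
                all_ucne_list, 1, existing,
            ):
                pk += 1
                peak_name = f"dnase_{pk:05d}"
                ivs.append(GenomicInterval(chrom, s, e, name=peak_name))
                dnase_labels[peak_name] = (
                    "Low-DNase" if rng_tracks.random() < 0.5 else "High-DNase"
                )
        dnase_peaks[stage] = IntervalSet(ivs)

    # ---- TADs + per-edge co-containment flags (direct scan)
    tads = _tile_tads(cfg, rng_tad)
    tads_by_chrom = tads.by_chrom()
    gene_by_id = {g.gene_id: g for g in genes}
    for ucne, gid in truth.edges:
        iv = by_name[ucne]
        g = gene_by_id[gid]
        truth.edge_tad[(ucne, gid)] = any(
            t.start < iv.end and iv.start < t.end and t.start <= g.tss < t.end
            for t in tads_by_chrom.get(iv.chrom, [])
        )

    # ---- stage expression (TPM)
    target_genes = sorted({gid for _u, gid in truth.edges})
    open_set = set(open_names)
    open_target_genes = sorted(
        {gid for u, gid in truth.edges if u in open_set}
    )
    stage_expr = pd.DataFrame(
        rng_expr.uniform(0.0, 0.4, size=(len(genes), len(cfg.rna_stages))),
        index=[g.gene_id for g in genes],
        columns=list(cfg.rna_stages),
    )
    for gid in target_genes:
        expressed = rng_expr.random() < cfg.expressed_target_frac
        truth.gene_expressed[gid] = expressed
        if expressed:
            stage = cfg.rna_stages[int(rng_expr.integers(0, len(cfg.rna_stages)))]
            stage_expr.loc[gid, stage] = float(
                cfg.expr_tpm_high * rng_expr.uniform(1.0, 5.0)
            )

    # ---- cluster expression and planted signatures / concordance
    baseline = 0.1
    cluster_expr = pd.DataFrame(
        baseline,
        index=[g.gene_id for g in genes],
        columns=list(cfg.clusters),
        dtype=float,
    )
    signature: dict[str, set] = {g.gene_id: set() for g in genes}
    forbidden: dict[str, set] = {g.gene_id: set() for g in genes}
    edges_by_ucne: dict[str, list[str]] = {}
    for u, gid in truth.edges:
        edges_by_ucne.setdefault(u, []).append(gid)
    for name in sorted(open_names):
        targets = [
            gid
            for gid in edges_by_ucne.get(name, [])
            if truth.gene_expressed.get(gid, False)
        ]
        open_clusters = {c for c, _s in truth.scatac_clusters.get(name, set())}
        want = rng_expr.random() < cfg.concordant_frac
        if want and targets and open_clusters:
            done = False
            for gid in targets:
                usable = sorted(
                    open_clusters
                    - forbidden[gid]
                )
                already = sorted(open_clusters & signature[gid])
                if already:
                    done = True
                    break
                if usable and len(signature[gid]) < 2:
                    signature[gid].add(usable[0])
                    done = True
                    break
            # if no assignment was possible the element stays discordant
        else:
            for gid in targets:
                forbidden[gid].update(open_clusters)
    # realise signatures with distinct high values
    for gid, clusters in signature.items():
        for i, cluster in enumerate(sorted(clusters)):
            cluster_expr.loc[gid, cluster] = 40.0 + 10.0 * i
    # final concordance truth from realised structures
    for name in sorted(open_names):
        targets = edges_by_ucne.get(name, [])
        open_clusters = {c for c, _s in truth.scatac_clusters.get(name, set())}
        sig_union = set()
        for gid in targets:
            if truth.gene_expressed.get(gid, False):
                sig_union.update(signature[gid])
        truth.concordant[name] = bool(open_clusters & sig_union)
    for gid in cluster_expr.index:
        truth.signatures[gid] = frozenset(signature[gid])

    # ---- peak-to-gene linkages
    linkages = []
    non_target_pool = [g.gene_id for g in genes if g.gene_id not in set(target_genes)]
    for name in sorted(open_names):
        iv = by_name[name]
        # the comparison downstream is against expression-filtered targets
        domain_targets = sorted(
            {
                gid
                for gid in edges_by_ucne.get(name, [])
                if truth.gene_expressed.get(gid, False)
            }
        )
        u = rng_link.random()
        peak = GenomicInterval(
            iv.chrom,
            max(0, iv.start - int(rng_link.integers(0, 100))),
            min(cfg.chrom_length, iv.end + int(rng_link.integers(0, 100))),
        )
        if u < cfg.p2g_identical_frac and domain_targets:
            for gid in domain_targets:
                linkages.append((peak, gid, float(rng_link.uniform(0.45, 0.95))))
        elif u < cfg.p2g_identical_frac + cfg.p2g_partial_frac and len(domain_targets) >= 2:
            linkages.append(
                (peak, domain_targets[0], float(rng_link.uniform(0.45, 0.95)))
            )
            if non_target_pool:
                other = non_target_pool[int(rng_link.integers(0, len(non_target_pool)))]
                linkages.append((peak, other, float(rng_link.uniform(0.45, 0.95))))
        else:
            if non_target_pool and rng_link.random() < 0.6:
                other = non_target_pool[int(rng_link.integers(0, len(non_target_pool)))]
                linkages.append((peak, other, float(rng_link.uniform(0.45, 0.95))))
            elif domain_targets:
                # sub-threshold correlation: excluded downstream
                linkages.append(
                    (peak, domain_targets[0], float(rng_link.uniform(0.05, 0.4)))
                )
    # truth relations by direct evaluation of the linkage rule
    link_targets: dict[str, set] = {}
    for peak, gid, corr in linkages:
        if corr > 0.4:
            for iv in ucnes:
                if iv.chrom == peak.chrom and iv.start - 250 < peak.end and peak.start < iv.end + 250:
                    link_targets.setdefault(iv.name, set()).add(gid)
    for name in sorted(open_names):
        domain_targets = {
            gid
            for gid in edges_by_ucne.get(name, [])
            if truth.gene_expressed.get(gid, False)
        }
        lt = link_targets.get(name, set())
        if domain_targets == lt:
            truth.p2g_relation[name] = "identical"
        elif domain_targets & lt:
            truth.p2g_relation[name] = "partial"
        else:
            truth.p2g_relation[name] = "disjoint"

    # ---- disease-gene table
    expressed_targets = [g for g in target_genes if truth.gene_expressed.get(g, False)]
    n_disease = max(1, int(round(cfg.disease_gene_frac * len(expressed_targets))))
    disease_genes = sorted(
        map(str, rng_disease.choice(expressed_targets, size=min(n_disease, len(expressed_targets)), replace=False))
    )
    truth.disease_genes = set(disease_genes)
    disease_table = pd.DataFrame(
        {
            "gene_id": disease_genes,
            "panel": [
                "Eye" if rng_disease.random() < 0.7 else "DD" for _ in disease_genes
            ],
            "phenotype": ["rare eye disease" for _ in disease_genes],
        }
    )

    # ---- validated-enhancer label table
    elements = []
    open_ivs = [by_name[n] for n in open_names]
    for i in range(cfg.n_label_elements):
        if i < len(open_ivs) and rng_label.random() < 0.6:
            anchor = open_ivs[i]
            start = max(0, anchor.start - int(rng_label.integers(0, 200)))
            end = min(cfg.chrom_length, anchor.end + int(rng_label.integers(0, 200)))
            chrom = anchor.chrom
            p_pos = cfg.label_positive_frac_open
        else:
            chrom = f"chr{int(rng_label.integers(1, cfg.n_chroms + 1))}"
            width = int(rng_label.integers(300, 1500))
            start = int(rng_label.integers(0, cfg.chrom_length - width))
            end = start + width
            p_pos = cfg.label_positive_frac_other
        positive = rng_label.random() < p_pos
        tissues = ()
        if positive:
            k = int(rng_label.integers(1, 4))
            tissues = tuple(
                sorted(map(str, rng_label.choice(VISTA_TISSUES, size=k, replace=False)))
            )
        elements.append(
            (
                GenomicInterval(chrom, start, end, name=f"vista_{i + 1:04d}"),
                "positive" if positive else "negative",
                tissues,
            )
        )
    enhancer_labels = EnhancerLabelTable(elements)

    # ---- cohort cases
    case_solved = {
        f"case_{i + 1:04d}": bool(rng_var.random() >= cfg.unsolved_frac)
        for i in range(cfg.n_cases)
    }
    case_ids = sorted(case_solved)

    # ---- variants: piecewise-uniform placement, per-bin rates
    bins = ["ultrarare", "very_rare", "rare", "low_frequency", "common"]
    af_ranges = {
        "very_rare": (1e-5, 1e-3),
        "rare": (1e-3, 5e-3),
        "low_frequency": (5e-3, 5e-2),
        "common": (5e-2, 0.5),
    }
    ucne_by_chrom = ucnes.by_chrom()
    variants: list[VariantRecord] = []

    def _complement(chrom: str) -> list[tuple[int, int]]:
        out = []
        pos = 0
        for iv in ucne_by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append((pos, iv.start))
            pos = iv.end
        if pos < cfg.chrom_length:
            out.append((pos, cfg.chrom_length))
        return out

    used_positions: dict[str, set] = {}

    def _sample_positions(chrom: str, segments: list[tuple[int, int]], n: int) -> list[int]:
        # unique positions per chromosome so every SNV id is unambiguous
        lengths = np.array([e - s for s, e in segments], dtype=np.int64)
        total = int(lengths.sum())
        if total == 0 or n == 0:
            return []
        cum = np.cumsum(lengths)
        used = used_positions.setdefault(chrom, set())
        out: list[int] = []
        tries = 0
        while len(out) < n and tries < 20 * n:
            tries += 1
            off = int(rng_var.integers(0, total))
            seg = int(np.searchsorted(cum, off, side="right"))
            within = off - (int(cum[seg - 1]) if seg else 0)
            pos = segments[seg][0] + within
            if pos in used:
                continue
            used.add(pos)
            out.append(pos)
        return out

    bases = np.array(["A", "C", "G", "T"])
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        outside = _complement(chrom)
        inside = [(iv.start, iv.end) for iv in ucne_by_chrom.get(chrom, [])]
        out_bp = sum(e - s for s, e in outside)
        in_bp = sum(e - s for s, e in inside)
        for bin_name, share in zip(bins, cfg.bin_shares):
            rate = cfg.common_variant_rate * share
            in_rate = rate * (cfg.ucne_common_depletion if bin_name == "common" else 1.0)
            for segments, bp, r in ((outside, out_bp, rate), (inside, in_bp, in_rate)):
                n = int(rng_var.poisson(r * bp))
                for pos in _sample_positions(chrom, segments, n):
                    ref, alt = rng_var.choice(bases, size=2, replace=False)
                    if bin_name == "ultrarare":
                        af, observed, n_hom = None, False, 0
                    else:
                        lo, hi = af_ranges[bin_name]
                        af = float(rng_var.uniform(lo, hi))
                        observed = True
                        if bin_name in ("low_frequency", "common"):
                            n_hom = int(rng_var.poisson(3))
                        else:
                            n_hom = int(rng_var.random() < 0.1)
                    k = int(rng_var.integers(1, cfg.n_variant_carriers + 1))
                    carriers = tuple(
                        sorted(map(str, rng_var.choice(case_ids, size=k, replace=False)))
                    )
                    variants.append(
                        VariantRecord(
                            interval=GenomicInterval(chrom, int(pos), int(pos) + 1),
                            ref=str(ref),
                            alt=str(alt),
                            af=af,
                            observed_in_reference=observed,
                            n_hom=n_hom,
                            carriers=carriers,
                        )
                    )
    # a handful of structural variants, some spanning elements
    marked_ucne_ivs = [by_name[n] for n in sorted(marked_names)]
    for i in range(cfg.n_svs):
        svtype = "DUP" if rng_var.random() < 0.6 else "DEL"
        if marked_ucne_ivs and rng_var.random() < 0.5:
            anchor = marked_ucne_ivs[int(rng_var.integers(0, len(marked_ucne_ivs)))]
            start = max(0, anchor.start - int(rng_var.integers(1_000, 20_000)))
            end = min(cfg.chrom_length, anchor.end + int(rng_var.integers(1_000, 20_000)))
            chrom = anchor.chrom
        else:
            chrom = f"chr{int(rng_var.integers(1, cfg.n_chroms + 1))}"
            width = int(rng_var.integers(5_000, 200_000))
            start = int(rng_var.integers(0, cfg.chrom_length - width))
            end = start + width
        k = int(rng_var.integers(1, cfg.n_variant_carriers + 1))
        carriers = tuple(sorted(map(str, rng_var.choice(case_ids, size=k, replace=False))))
        variants.append(
            VariantRecord(
                interval=GenomicInterval(chrom, start, end),
                ref="N",
                alt=f"<{svtype}>",
                svtype=svtype,
                af=None,
                observed_in_reference=False,
                n_hom=0,
                carriers=carriers,
            )
        )
    variants.sort(key=lambda v: v.interval.sort_key())

    # ---- variant truth: bins, element membership, search-space counts
    disease_set = set(disease_genes)
    state_rank = {"none": 0, "open_only": 1, "marked": 2, "active_enhancer": 3, "sustained_adult": 4}
    n_ss_variants = 0
    ss_ucnes, ss_genes = set(), set()
    for v in variants:
        if not v.observed_in_reference:
            bin_name = "ultrarare"
        else:
            maf = min(v.af, 1 - v.af)
            if maf < 0.001:
                bin_name = "very_rare"
            elif maf < 0.005:
                bin_name = "rare"
            elif maf < 0.05:
                bin_name = "low_frequency"
            else:
                bin_name = "common"
        truth.variant_bins[v.vid()] = bin_name
        hits = [
            iv.name
            for iv in ucne_by_chrom.get(v.interval.chrom, [])
            if v.interval.start < iv.end and iv.start < v.interval.end
        ]
        truth.variant_ucne[v.vid()] = hits[0] if hits else None
        passes_rare = bin_name in ("ultrarare", "very_rare", "rare") and (v.n_hom or 0) == 0
        qualifying_hits = []
        if passes_rare:
            for hit in hits:
                if state_rank[truth.ucne_state[hit]] >= state_rank["marked"]:
                    dg = set(edges_by_ucne.get(hit, [])) & disease_set
                    if dg:
                        qualifying_hits.append((hit, dg))
        if qualifying_hits:
            n_ss_variants += 1
            for hit, dg in qualifying_hits:
                ss_ucnes.add(hit)
                ss_genes.update(dg)
    truth.search_space = {
        "variants": n_ss_variants,
        "ucnes": len(ss_ucnes),
        "genes": len(ss_genes),
    }

    # ---- constraint track
    flank_ivs = []
    for iv in ucnes:
        if iv.start > 0:
            flank_ivs.append(
                GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.start)
            )
        if iv.end < cfg.chrom_length:
            flank_ivs.append(
                GenomicInterval(iv.chrom, iv.end, min(cfg.chrom_length, iv.end + 200))
            )
    constraint = SyntheticConstraintTrack(
        seed=cfg.seed,
        assembly=assembly,
        ucnes=ucnes,
        flanks=IntervalSet(flank_ivs),
        delta=cfg.constraint_shift,
    )

    return SyntheticBundle(
        config=cfg,
        assembly=assembly,
        genes=genes,
        ucnes=ucnes,
        scatac_tracks=scatac_tracks,
        chip_tracks=chip_tracks,
        dnase_peaks=dnase_peaks,
        dnase_labels=dnase_labels,
        tads=tads,
        stage_expr=stage_expr,
        cluster_expr=cluster_expr,
        linkages=linkages,
        disease_table=disease_table,
        enhancer_labels=enhancer_labels,
        variants=variants,
        case_solved=case_solved,
        constraint=constraint,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file bundle


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_")


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every input file plus manifest.json and truth.json; returns the
    manifest."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for sub in ("scatac", "chip", "dnase"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    io_formats.write_chrom_sizes(bundle.assembly, os.path.join(outdir, "genome.chrom.sizes"))
    io_formats.write_bed(bundle.ucnes, os.path.join(outdir, "ucnes.bed"))
    io_formats.write_gene_models(bundle.genes, os.path.join(outdir, "genes.tsv"))
    io_formats.write_bed(bundle.tads, os.path.join(outdir, "tads.bed"))
    io_formats.write_expression(bundle.stage_expr, os.path.join(outdir, "expression_stage.tsv"))
    io_formats.write_expression(bundle.cluster_expr, os.path.join(outdir, "expression_cluster.tsv"))
    bundle.disease_table.to_csv(os.path.join(outdir, "disease_genes.tsv"), sep="\t", index=False)
    io_formats.write_enhancer_labels(bundle.enhancer_labels, os.path.join(outdir, "enhancer_labels.tsv"))
    io_formats.write_variants_vcf(
        bundle.variants, os.path.join(outdir, "cohort.vcf"), bundle.assembly
    )
    pd.DataFrame(
        {
            "case_id": sorted(bundle.case_solved),
            "solved": [int(bundle.case_solved[c]) for c in sorted(bundle.case_solved)],
        }
    ).to_csv(os.path.join(outdir, "cases.tsv"), sep="\t", index=False)
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "gene": gene,
            "correlation": corr,
        }
        for iv, gene, corr in bundle.linkages
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "correlation"]).to_csv(
        os.path.join(outdir, "peak2gene.tsv"), sep="\t", index=False
    )

    manifest: dict = {
        "config": dataclasses.asdict(bundle.config),
        "files": {
            "chrom_sizes": "genome.chrom.sizes",
            "ucnes": "ucnes.bed",
            "genes": "genes.tsv",
            "tads": "tads.bed",
            "expression_stage": "expression_stage.tsv",
            "expression_cluster": "expression_cluster.tsv",
            "disease_genes": "disease_genes.tsv",
            "enhancer_labels": "enhancer_labels.tsv",
            "variants": "cohort.vcf",
            "cases": "cases.tsv",
            "peak2gene": "peak2gene.tsv",
        },
        "scatac": [],
        "chip": [],
        "dnase": [],
        "constraint": {
            "model": "synthetic-normal",
            "seed": bundle.constraint.seed,
            "delta": bundle.constraint.delta,
        },
    }
    for (cluster, stage), track in sorted(bundle.scatac_tracks.items()):
        rel = f"scatac/{_slug(cluster)}__{_slug(stage)}.bedgraph"
        io_formats.write_bedgraph(track, os.path.join(outdir, rel))
        manifest["scatac"].append({"cluster": cluster, "stage": stage, "path": rel})
    for (mark, stage), track in sorted(bundle.chip_tracks.items()):
        rel = f"chip/{_slug(mark)}__{_slug(stage)}.bedgraph"
        io_formats.write_bedgraph(track, os.path.join(outdir, rel))
        manifest["chip"].append({"mark": mark, "stage": stage, "path": rel})
    for stage, peaks in sorted(bundle.dnase_peaks.items()):
        rel = f"dnase/{_slug(stage)}.bed"
        io_formats.write_bed(peaks, os.path.join(outdir, rel))
        labels_rel = f"dnase/{_slug(stage)}_labels.tsv"
        names = [iv.name for iv in peaks]
        pd.DataFrame(
            {"name": names, "category": [bundle.dnase_labels[n] for n in names]}
        ).to_csv(os.path.join(outdir, labels_rel), sep="\t", index=False)
        manifest["dnase"].append({"stage": stage, "path": rel, "labels": labels_rel})
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(bundle.truth.to_json(), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def load_bundle(outdir) -> SyntheticBundle:
    """Reconstruct the in-memory bundle from a written directory."""
    outdir = os.fspath(outdir)
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    raw_cfg = manifest["config"]
    for key in ("stages", "dnase_stages", "rna_stages", "clusters", "bin_shares"):
        raw_cfg[key] = tuple(raw_cfg[key])
    cfg = SimulationConfig(**raw_cfg)
    assembly = io_formats.read_chrom_sizes(os.path.join(outdir, "genome.chrom.sizes"))
    ucnes = io_formats.read_bed(os.path.join(outdir, "ucnes.bed"), assembly)
    genes_df = io_formats.read_gene_models(os.path.join(outdir, "genes.tsv"), assembly)
    from .target_assignment import genes_from_frame

    genes = genes_from_frame(genes_df)
    scatac_tracks = {
        (e["cluster"], e["stage"]): io_formats.read_bedgraph(
            os.path.join(outdir, e["path"]), assembly
        )
        for e in manifest["scatac"]
    }
    chip_tracks = {
        (e["mark"], e["stage"]): io_formats.read_bedgraph(
            os.path.join(outdir, e["path"]), assembly
        )
        for e in manifest["chip"]
    }
    dnase_peaks = {}
    dnase_labels = {}
    for e in manifest["dnase"]:
        dnase_peaks[e["stage"]] = io_formats.read_bed(
            os.path.join(outdir, e["path"]), assembly
        )
        labels = pd.read_csv(os.path.join(outdir, e["labels"]), sep="\t")
        dnase_labels.update(dict(zip(labels["name"], labels["category"])))
    tads = io_formats.read_bed(os.path.join(outdir, "tads.bed"), assembly)
    stage_expr = io_formats.read_expression(os.path.join(outdir, "expression_stage.tsv"))
    cluster_expr = io_formats.read_expression(os.path.join(outdir, "expression_cluster.tsv"))
    disease_table = io_formats.read_disease_genes(os.path.join(outdir, "disease_genes.tsv"))
    enhancer_labels = io_formats.read_enhancer_labels(os.path.join(outdir, "enhancer_labels.tsv"))
    variants = io_formats.read_variants(os.path.join(outdir, "cohort.vcf"))
    cases = pd.read_csv(os.path.join(outdir, "cases.tsv"), sep="\t")
    case_solved = {str(r.case_id): bool(r.solved) for r in cases.itertuples(index=False)}
    p2g = pd.read_csv(os.path.join(outdir, "peak2gene.tsv"), sep="\t")
    linkages = [
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), str(r.gene), float(r.correlation))
        for r in p2g.itertuples(index=False)
    ]
    flank_ivs = []
    for iv in ucnes:
        if iv.start > 0:
            flank_ivs.append(GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.start))
        if iv.end < assembly.length(iv.chrom):
            flank_ivs.append(
                GenomicInterval(iv.chrom, iv.end, min(assembly.length(iv.chrom), iv.end + 200))
            )
    constraint = SyntheticConstraintTrack(
        seed=int(manifest["constraint"]["seed"]),
        assembly=assembly,
        ucnes=ucnes,
        flanks=IntervalSet(flank_ivs),
        delta=float(manifest["constraint"]["delta"]),
    )
    truth = TruthTable()
    truth_path = os.path.join(outdir, "truth.json")
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            data = json.load(fh)
        truth.ucne_state = data.get("ucne_state", {})
        truth.search_space = data.get("search_space", {})
    return SyntheticBundle(
        config=cfg,
        assembly=assembly,
        genes=genes,
        ucnes=ucnes,
        scatac_tracks=scatac_tracks,
        chip_tracks=chip_tracks,
        dnase_peaks=dnase_peaks,
        dnase_labels=dnase_labels,
        tads=tads,
        stage_expr=stage_expr,
        cluster_expr=cluster_expr,
        linkages=linkages,
        disease_table=disease_table,
        enhancer_labels=enhancer_labels,
        variants=variants,
        case_solved=case_solved,
        constraint=constraint,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# worked example


def worked_example() -> SyntheticBundle:
    """Miniature hand-checkable bundle: one 100 kb chromosome, 3 genes, 5
    elements, with every downstream number verifiable by hand.

    Layout (all coordinates 0-based half-open):

    * genes: GA (+, TSS 10 000), GB (-, TSS 50 000), GC (+, TSS 90 000);
      basal domains [5 000, 11 000), [49 000, 55 000), [85 000, 91 000);
      extended domains [0, 49 000), [11 000, 85 000), [55 000, 100 000).
    * elements: U1 [20 000, 20 300), U2 [40 000, 40 350), U3 [60 000,
      60 250), U4 [80 000, 80 400), U5 [95 000, 95 300); planted targets
      {GA, GB}, {GA, GB}, {GB, GC}, {GB, GC}, {GC}.
    * open: U1 (scATAC GanglionPrecursors@FW13/14 + DNase E89, high
      confidence), U2 (DNase only), U4 (scATAC Rods@FW23/24 only).
    * marks: U1 H3K27ac@FW13/14 + H3K4me1@FW13/14 + H3K27ac@adult
      (sustained_adult); U2 H3K4me1@FW15/16 (marked); U4 none (open_only).
    * TADs [0, 45 000), [45 000, 82 000), [82 000, 100 000): U1/U2 share a
      TAD with GA's TSS but not GB's; U4 shares with GB, not GC.
    * expression: GA and GB expressed (TPM 5 and 2), GC not (0.3); GA's
      signature is {GanglionPrecursors}, so U1 is concordant, U2 and U4 not.
    * disease gene: GB.
    * variants: an ultrarare SNV in U1 (search space), an ultrarare SNV in
      U4 (open_only, excluded), a common SNV in U2, a rare SNV with one
      homozygote in U1 (excluded), an ultrarare DUP spanning U4.
    """
    chrom_len = 100_000
    assembly = GenomeAssembly.from_dict({"chr1": chrom_len})
    genes = [
        GeneModel("GA", "chr1", 10_000, "+"),
        GeneModel("GB", "chr1", 50_000, "-"),
        GeneModel("GC", "chr1", 90_000, "+"),
    ]
    ucnes = IntervalSet(
        [
            GenomicInterval("chr1", 20_000, 20_300, name="U1"),
            GenomicInterval("chr1", 40_000, 40_350, name="U2"),
            GenomicInterval("chr1", 60_000, 60_250, name="U3"),
            GenomicInterval("chr1", 80_000, 80_400, name="U4"),
            GenomicInterval("chr1", 95_000, 95_300, name="U5"),
        ]
    )
    clusters = ("GanglionPrecursors", "Rods", "MullerGlia", "EarlyProgenitors")
    scatac_tracks = {
        ("GanglionPrecursors", "FW13/14"): SignalTrack.from_runs(
            {"chr1": [(19_950, 20_400, 0.9)]}, assembly
        ),
        ("Rods", "FW23/24"): SignalTrack.from_runs(
            {"chr1": [(79_900, 80_500, 0.7)]}, assembly
        ),
    }
    chip_tracks = {
        ("H3K27ac", "FW13/14"): SignalTrack.from_runs(
            {"chr1": [(19_900, 20_450, 30.0)]}, assembly
        ),
        ("H3K4me1", "FW13/14"): SignalTrack.from_runs(
            {"chr1": [(20_350, 20_700, 25.0)]}, assembly  # 50 bp past U1: window hit
        ),
        ("H3K27ac", "adult"): SignalTrack.from_runs(
            {"chr1": [(20_000, 20_300, 28.0)]}, assembly
        ),
        ("H3K4me1", "FW15/16"): SignalTrack.from_runs(
            {"chr1": [(40_000, 40_350, 22.0)]}, assembly
        ),
    }
    dnase_peaks = {
        "E89": IntervalSet(
            [
                GenomicInterval("chr1", 19_980, 20_320, name="d1"),
                GenomicInterval("chr1", 39_990, 40_360, name="d2"),
                GenomicInterval("chr1", 70_000, 70_300, name="d3"),
            ]
        )
    }
    dnase_labels = {"d1": "High-DNase", "d2": "High-DNase", "d3": "Low-DNase"}
    tads = IntervalSet(
        [
            GenomicInterval("chr1", 0, 45_000, name="T1"),
            GenomicInterval("chr1", 45_000, 82_000, name="T2"),
            GenomicInterval("chr1", 82_000, 100_000, name="T3"),
        ]
    )
    stage_expr = pd.DataFrame(
        {"D52": [5.0, 0.1, 0.3], "D80": [0.2, 2.0, 0.2]},
        index=["GA", "GB", "GC"],
    )
    cluster_expr = pd.DataFrame(
        0.1, index=["GA", "GB", "GC"], columns=list(clusters), dtype=float
    )
    cluster_expr.loc["GA", "GanglionPrecursors"] = 40.0
    cluster_expr.loc["GB", "MullerGlia"] = 40.0
    linkages = [
        (GenomicInterval("chr1", 20_000, 20_300), "GA", 0.8),
        (GenomicInterval("chr1", 20_000, 20_300), "GB", 0.6),
        (GenomicInterval("chr1", 40_000, 40_350), "GA", 0.4),  # excluded: not > 0.4
        (GenomicInterval("chr1", 80_000, 80_400), "GC", 0.9),
    ]
    disease_table = pd.DataFrame(
        {"gene_id": ["GB"], "panel": ["Eye"], "phenotype": ["retinal dystrophy"]}
    )
    enhancer_labels = EnhancerLabelTable(
        [
            (GenomicInterval("chr1", 20_100, 20_500, name="v1"), "positive", ("eye",)),
            (GenomicInterval("chr1", 40_100, 40_300, name="v2"), "negative", ()),
            (GenomicInterval("chr1", 5_000, 5_400, name="v3"), "positive", ("limb",)),
        ]
    )
    variants = [
        VariantRecord(GenomicInterval("chr1", 20_100, 20_101), "T", "C",
                      af=None, observed_in_reference=False, n_hom=0,
                      carriers=("case_0001",)),
        VariantRecord(GenomicInterval("chr1", 80_050, 80_051), "G", "A",
                      af=None, observed_in_reference=False, n_hom=0,
                      carriers=("case_0002",)),
        VariantRecord(GenomicInterval("chr1", 40_100, 40_101), "A", "G",
                      af=0.2, observed_in_reference=True, n_hom=12,
                      carriers=("case_0001", "case_0003")),
        VariantRecord(GenomicInterval("chr1", 20_200, 20_201), "C", "T",
                      af=0.004, observed_in_reference=True, n_hom=1,
                      carriers=("case_0003",)),
        VariantRecord(GenomicInterval("chr1", 79_000, 81_000), "N", "<DUP>",
                      svtype="DUP", af=None, observed_in_reference=False,
                      n_hom=0, carriers=("case_0002",)),
    ]
    case_solved = {"case_0001": False, "case_0002": False, "case_0003": True}
    flank_ivs = IntervalSet(
        [GenomicInterval("chr1", max(0, iv.start - 200), iv.start) for iv in ucnes]
        + [GenomicInterval("chr1", iv.end, min(chrom_len, iv.end + 200)) for iv in ucnes]
    )
    constraint = SyntheticConstraintTrack(
        seed=7, assembly=assembly, ucnes=ucnes, flanks=flank_ivs, delta=1.0
    )
    cfg = SimulationConfig(
        seed=7,
        n_chroms=1,
        chrom_length=chrom_len,
        n_genes=3,
        n_ucnes=5,
        clusters=clusters,
        rna_stages=("D52", "D80"),
        constraint_shift=1.0,
    )
    truth = TruthTable(
        ucne_state={
            "U1": "sustained_adult",
            "U2": "marked",
            "U3": "none",
            "U4": "open_only",
            "U5": "none",
        },
        dnase_stages={"U1": {"E89"}, "U2": {"E89"}},
        scatac_clusters={
            "U1": {("GanglionPrecursors", "FW13/14")},
            "U4": {("Rods", "FW23/24")},
        },
        high_confidence={"U1"},  # the only element with both sources
        edges=[
            ("U1", "GA"), ("U1", "GB"),
            ("U2", "GA"), ("U2", "GB"),
            ("U3", "GB"), ("U3", "GC"),
            ("U4", "GB"), ("U4", "GC"),
            ("U5", "GC"),
        ],
        edge_tad={
            ("U1", "GA"): True, ("U1", "GB"): False,
            ("U2", "GA"): True, ("U2", "GB"): False,
            ("U3", "GB"): True, ("U3", "GC"): False,
            ("U4", "GB"): True, ("U4", "GC"): False,
            ("U5", "GC"): True,
        },
        gene_expressed={"GA": True, "GB": True, "GC": False},
        concordant={"U1": True, "U2": False, "U4": False},
        disease_genes={"GB"},
        search_space={"variants": 1, "ucnes": 1, "genes": 1},
    )
    return SyntheticBundle(
        config=cfg,
        assembly=assembly,
        genes=genes,
        ucnes=ucnes,
        scatac_tracks=scatac_tracks,
        chip_tracks=chip_tracks,
        dnase_peaks=dnase_peaks,
        dnase_labels=dnase_labels,
        tads=tads,
        stage_expr=stage_expr,
        cluster_expr=cluster_expr,
        linkages=linkages,
        disease_table=disease_table,
        enhancer_labels=enhancer_labels,
        variants=variants,
        case_solved=case_solved,
        constraint=constraint,
        truth=truth,
    )
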