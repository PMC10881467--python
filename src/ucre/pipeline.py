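"""End-to-end orchestration: annotate -> targets -> variants -> constraint.

Runs the full analysis on an input bundle (synthetic or loaded from files),
writing every intermediate table plus a machine-readable
:class:`RunReport`.  All thresholds default to the study values: peak-calling
cutoffs 0.4 (accessibility) / 20 (marks), ±250 bp mark window, TPM >= 0.5
expression filter, 80th-percentile signatures, peak-to-gene correlation
> 0.4, MAF < 0.5% with no homozygotes, 200 random 350 bp background
fragments, 200 bp constraint flanks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import ccre_annotation as ccre
from . import constraint_stats as cstats
from . import target_assignment as ta
from . import variant_prioritization as vp
from .core_intervals import IntervalSet
from .peak_calling import call_peaks, filter_low_signal_regions, peaks_to_interval_set
from .synthetic_data import SyntheticBundle


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds; defaults reproduce the described analysis."""

    accessibility_cutoff: float = 0.4
    mark_cutoff: float = 20.0
    peak_min_length: int = 200
    peak_max_gap: int = 30
    mark_flank: int = 250
    tpm_min: float = 0.5
    signature_percentile: float = 80.0
    p2g_corr_min: float = 0.4
    fragment_n: int = 200
    fragment_length: int = 350
    constraint_flank: int = 200
    low_dnase_category: str = "Low-DNase"
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Stage-by-stage counts and statistics of one pipeline run."""

    config_hash: str = ""
    seed: int = 0
    version: str = ""
    n_ucnes: int = 0
    n_open: int = 0
    n_high_confidence: int = 0
    n_marked: int = 0
    n_active_enhancer: int = 0
    n_sustained_adult: int = 0
    n_any_assessed_mark: int = 0
    n_any_activating_mark: int = 0
    n_edges: int = 0
    n_target_genes: int = 0
    n_expressed_genes: int = 0
    n_tad_consistent_genes: int = 0
    tad_consistent_fraction: float = float("nan")
    concordant_fraction: float = float("nan")
    n_disease_genes: int = 0
    variant_bin_counts: dict = field(default_factory=dict)
    n_rare_variants: int = 0
    n_ucne_hits: int = 0
    search_space: dict = field(default_factory=dict)
    spectrum: dict = field(default_factory=dict)
    constraint: dict = field(default_factory=dict)
    background_suitability: dict = field(default_factory=dict)
    vista: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        def conv(x):
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating, float)):
                return float(x)
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _write(df: pd.DataFrame, outdir: Optional[str], name: str) -> None:
    if outdir is not None:
        df.to_csv(os.path.join(outdir, name), sep="\t", index=False)


def annotate_stage(bundle: SyntheticBundle, config: PipelineConfig, outdir=None):
    """Stage 1: peak calling, accessibility overlap, mark overlay, states."""
    scatac_peaks = {}
    for key, track in bundle.scatac_tracks.items():
        calls = call_peaks(
            track,
            cutoff=config.accessibility_cutoff,
            min_length=config.peak_min_length,
            max_gap=config.peak_max_gap,
        )
        scatac_peaks[key] = peaks_to_interval_set(calls)
    chip_peaks = {}
    for key, track in bundle.chip_tracks.items():
        calls = call_peaks(
            track,
            cutoff=config.mark_cutoff,
            min_length=config.peak_min_length,
            max_gap=config.peak_max_gap,
        )
        chip_peaks[key] = peaks_to_interval_set(calls)
    dnase_peaks = {
        stage: filter_low_signal_regions(
            peaks, bundle.dnase_labels, low_categories=(config.low_dnase_category,)
        )
        for stage, peaks in bundle.dnase_peaks.items()
    }
    profiles = ccre.identify_open_ucnes(bundle.ucnes, dnase_peaks, scatac_peaks)
    open_profiles = [p for p in profiles if p.is_open]
    mark_table = ccre.annotate_marks(
        open_profiles,
        chip_peaks,
        flank=config.mark_flank,
        assembly=bundle.assembly,
    )
    dev_stages = set(bundle.config.stages)
    adult_stages = {bundle.config.adult_stage}
    for p in profiles:
        ccre.classify_enhancer_state(p, dev_stages, adult_stages)
    if outdir is not None:
        rows = [
            {
                "ucne": p.ucne.name,
                "state": p.enhancer_state,
                "high_confidence": p.high_confidence,
                "dnase_stages": ",".join(sorted(p.dnase_stages)),
                "scatac": ",".join(
                    f"{c}@{s}" for c, s in sorted(p.scatac_clusters)
                ),
                "marks": ";".join(
                    f"{m}:{','.join(sorted(st))}" for m, st in sorted(p.marks.items())
                ),
            }
            for p in profiles
        ]
        _write(pd.DataFrame(rows), outdir, "activity_profiles.tsv")
        mark_table.to_csv(os.path.join(outdir, "mark_counts.tsv"), sep="\t")
    return profiles, mark_table


def targets_stage(bundle: SyntheticBundle, profiles, config: PipelineConfig, outdir=None):
    """Stage 2: domains, edges, expression/TAD filters, concordance, P2G."""
    domains = ta.build_domains(bundle.genes, bundle.assembly)
    active_ucnes = IntervalSet([p.ucne for p in profiles if p.is_open])
    edges = ta.assign_targets(active_ucnes, domains)
    expressed_edges, n_missing = ta.filter_expressed(
        edges, bundle.stage_expr, tpm_min=config.tpm_min
    )
    tads = ta.TADSet(bundle.tads)
    flagged_edges, tad_fraction = ta.tad_consistency(
        expressed_edges, tads, bundle.ucnes, bundle.genes
    )
    signatures = ta.assign_signatures(
        bundle.cluster_expr, pct=config.signature_percentile
    )
    concordance_table, concordant_fraction = ta.concordance(
        expressed_edges, profiles, signatures
    )
    p2g = ta.peak2gene_compare(
        expressed_edges,
        bundle.linkages,
        bundle.ucnes,
        corr_min=config.p2g_corr_min,
        flank=config.mark_flank,
        assembly=bundle.assembly,
    )
    disease_edges = ta.disease_gene_filter(flagged_edges, bundle.disease_table)
    if outdir is not None:
        _write(flagged_edges, outdir, "edges.tsv")
        _write(concordance_table, outdir, "concordance.tsv")
        _write(p2g, outdir, "peak2gene_comparison.tsv")
        _write(disease_edges, outdir, "disease_edges.tsv")
        ta.genes_per_ucne_histogram(edges).rename("n_ucnes").to_csv(
            os.path.join(outdir, "genes_per_ucne.tsv"), sep="\t", index_label="n_genes"
        )
        ta.distance_histogram(edges).rename("count").to_csv(
            os.path.join(outdir, "distance_bins.tsv"), sep="\t", index_label="bin"
        )
    return {
        "domains": domains,
        "edges": edges,
        "expressed_edges": flagged_edges,
        "n_missing_genes": n_missing,
        "tad_fraction": tad_fraction,
        "signatures": signatures,
        "concordance_table": concordance_table,
        "concordant_fraction": concordant_fraction,
        "p2g": p2g,
        "disease_edges": disease_edges,
    }


def variants_stage(bundle: SyntheticBundle, profiles, targets, config: PipelineConfig, outdir=None):
    """Stage 3: frequency filter, element overlap, search-space definition."""
    rare = vp.rare_filter(bundle.variants)
    hits = vp.overlap_active_ucnes(rare, profiles, targets["expressed_edges"])
    disease_genes = set(bundle.disease_table["gene_id"])
    space = vp.define_search_space(hits, disease_genes, bundle.case_solved)
    bin_counts = {b.value: 0 for b in vp.BIN_ORDER}
    for v in bundle.variants:
        bin_counts[vp.classify_frequency(v).value] += 1
    if outdir is not None:
        _write(vp.hits_table(hits), outdir, "ucne_variant_hits.tsv")
        _write(vp.hits_table(space.hits), outdir, "search_space.tsv")
    return {
        "rare": rare,
        "hits": hits,
        "search_space": space,
        "bin_counts": bin_counts,
    }


def constraint_stage(bundle: SyntheticBundle, targets, config: PipelineConfig, outdir=None):
    """Stage 4: background sampling, AF spectra, constraint rank tests."""
    spec = cstats.RandomFragmentSpec(
        n=config.fragment_n,
        length=config.fragment_length,
        seed=config.seed,
        exclusion=bundle.ucnes,
    )
    background = cstats.sample_fragments(spec, bundle.assembly)
    flanks = cstats.build_flanks(
        bundle.ucnes, flank=config.constraint_flank, assembly=bundle.assembly
    )
    spectrum = cstats.af_spectrum_comparison(bundle.variants, bundle.ucnes, background)
    result = cstats.compare_constraint(
        bundle.constraint, bundle.ucnes, flanks, background
    )
    suitability = cstats.background_suitability(
        bundle.ucnes, background, targets["domains"]
    )
    if outdir is not None:
        rows = [
            {
                "bin": b,
                "ucne_count": spectrum["ucne"]["counts"][b],
                "ucne_proportion": spectrum["ucne"]["proportions"][b],
                "background_count": spectrum["background"]["counts"][b],
                "background_proportion": spectrum["background"]["proportions"][b],
                "proportion_ratio": spectrum["proportion_ratio"][b],
                "density_ratio": spectrum["density_ratio"][b],
            }
            for b in (bin_.value for bin_ in vp.BIN_ORDER)
        ]
        _write(pd.DataFrame(rows), outdir, "af_spectrum.tsv")
    return {
        "background": background,
        "flanks": flanks,
        "spectrum": spectrum,
        "constraint": result,
        "suitability": suitability,
    }


def run(
    bundle: SyntheticBundle,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
) -> RunReport:
    """Execute all stages in order and assemble the run report."""
    config = config or PipelineConfig()
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    profiles, _mark_table = annotate_stage(bundle, config, outdir)
    targets = targets_stage(bundle, profiles, config, outdir)
    variants = variants_stage(bundle, profiles, targets, config, outdir)
    constraint = constraint_stage(bundle, targets, config, outdir)
    vista = ccre.vista_correlate(
        {
            "all_ucnes": bundle.ucnes,
            "open_ucnes": IntervalSet([p.ucne for p in profiles if p.is_open]),
        },
        bundle.enhancer_labels,
    )
    open_profiles = [p for p in profiles if p.is_open]
    states = ccre.state_counts(profiles)
    marked = ccre.marked_counts(open_profiles)
    expressed_edges = targets["expressed_edges"]
    report = RunReport(
        config_hash=config.hash(),
        seed=config.seed,
        version=__version__,
        n_ucnes=len(bundle.ucnes),
        n_open=states["open"],
        n_high_confidence=sum(p.high_confidence for p in profiles),
        n_marked=states["marked"],
        n_active_enhancer=states["active_enhancer"],
        n_sustained_adult=states["sustained_adult"],
        n_any_assessed_mark=marked["any_assessed_mark"],
        n_any_activating_mark=marked["any_activating_mark"],
        n_edges=len(expressed_edges),
        n_target_genes=int(targets["edges"]["gene"].nunique()) if len(targets["edges"]) else 0,
        n_expressed_genes=int(expressed_edges["gene"].nunique()) if len(expressed_edges) else 0,
        n_tad_consistent_genes=(
            int(expressed_edges.groupby("gene")["tad_consistent"].any().sum())
            if len(expressed_edges)
            else 0
        ),
        tad_consistent_fraction=targets["tad_fraction"],
        concordant_fraction=targets["concordant_fraction"],
        n_disease_genes=int(targets["disease_edges"]["gene"].nunique())
        if len(targets["disease_edges"])
        else 0,
        variant_bin_counts=variants["bin_counts"],
        n_rare_variants=len(variants["rare"]),
        n_ucne_hits=len(variants["hits"]),
        search_space=variants["search_space"].summary(),
        spectrum={
            "proportion_ratio": constraint["spectrum"]["proportion_ratio"],
            "density_ratio": constraint["spectrum"]["density_ratio"],
            "density_ratio_se": constraint["spectrum"]["density_ratio_se"],
        },
        constraint={
            "H": constraint["constraint"].H,
            "p": constraint["constraint"].p,
            "pairwise": [
                {"i": i, "j": j, "z": z, "p_adjusted": p}
                for i, j, z, p in constraint["constraint"].pairwise
            ],
            "group_medians": constraint["constraint"].group_medians,
            "group_sizes": constraint["constraint"].group_sizes,
        },
        background_suitability=constraint["suitability"],
        vista={
            name: {
                "n_overlapped": v.n_overlapped,
                "n_positive": v.n_positive,
                "positive_proportion": v.positive_proportion,
                "tissue_mention_fractions": v.tissue_mention_fractions,
            }
            for name, v in vista.items()
        },
    )
    if outdir is not None:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
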