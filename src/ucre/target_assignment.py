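"""Target-gene assignment by basal-plus-extension regulatory domains.

Stage 2: each gene receives a strand-aware basal domain (5 kb upstream, 1 kb
downstream of the TSS) extended in each direction up to 1 Mb or to the nearest
other gene's basal-domain boundary, whichever is closer (the GREAT-style
association rule).  A putatively active element targets every gene whose
extended (or curated) domain it overlaps by >= 1 bp.  Edges are then filtered
by retinal expression (TPM >= 0.5 in >= 1 stage), checked for TAD
co-containment, compared against correlation-based peak-to-gene links, scored
for cell-type concordance via 80th-percentile expression signatures, and
intersected with a disease-gene table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ccre_annotation import UCNEActivityProfile
from .core_intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    distance_to_point,
    intersect,
    window_overlap,
)

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000
TPM_MIN = 0.5
SIGNATURE_PERCENTILE = 80.0
P2G_CORR_MIN = 0.4

#: |TSS - element| magnitude bins for the distance distribution
DISTANCE_BINS = [(0, 5_000), (5_000, 50_000), (50_000, 500_000), (500_000, None)]
DISTANCE_BIN_LABELS = ["0-5kb", "5-50kb", "50-500kb", ">500kb"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: GeneModel
    basal: GenomicInterval
    extended: GenomicInterval
    curated: Optional[GenomicInterval] = None

    @property
    def effective(self) -> GenomicInterval:
        """Curated override when present, otherwise the extended domain."""
        return self.curated if self.curated is not None else self.extended


@dataclass
class TADSet:
    """Validated topologically-associating-domain calls."""

    tads: IntervalSet

    def __post_init__(self) -> None:
        for chrom, ivs in self.tads.by_chrom().items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping TADs on {chrom}: {a.start}-{a.end} and "
                        f"{b.start}-{b.end}"
                    )


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


def _basal_interval(gene: GeneModel, assembly: GenomeAssembly, up: int, down: int) -> GenomicInterval:
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    start = max(0, start)
    end = min(end, assembly.length(gene.chrom))
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id)


def build_domains(
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    up: int = BASAL_UPSTREAM,
    down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
    curated: Optional[Mapping[str, GenomicInterval]] = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domain per gene.

    The extension on each side stops at the nearer of (a) the closest other
    gene's basal-domain boundary on that side and (b) ``max_ext`` bp from the
    basal boundary, clamped to the chromosome; when a foreign basal domain
    overlaps the gene's own basal domain on a side, that side does not extend
    at all.  Basal domains are never truncated by neighbours.  ``curated``
    maps gene_id to a replacement for the *extended* interval.
    """
    if up <= 0 or down <= 0 or max_ext <= 0:
        raise ValueError("domain parameters must be positive")
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    basal = {g.gene_id: _basal_interval(g, assembly, up, down) for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    domains = []
    for g in genes:
        b = basal[g.gene_id]
        others = [basal[o.gene_id] for o in by_chrom[g.chrom] if o.gene_id != g.gene_id]
        left_blocked = any(o.start < b.start < o.end for o in others)
        right_blocked = any(o.start < b.end <= o.end and o.end > b.end for o in others)
        if left_blocked:
            ext_start = b.start
        else:
            nearest_left = max((o.end for o in others if o.end <= b.start), default=0)
            ext_start = max(0, b.start - max_ext, nearest_left)
        if right_blocked:
            ext_end = b.end
        else:
            chrom_len = assembly.length(g.chrom)
            nearest_right = min(
                (o.start for o in others if o.start >= b.end), default=chrom_len
            )
            ext_end = min(chrom_len, b.end + max_ext, nearest_right)
        extended = GenomicInterval(g.chrom, ext_start, ext_end, name=g.gene_id)
        cur = None
        if curated and g.gene_id in curated:
            cur = curated[g.gene_id]
        domains.append(RegulatoryDomain(gene=g, basal=b, extended=extended, curated=cur))
    return domains


def assign_targets(
    active_ucnes: IntervalSet,
    domains: Sequence[RegulatoryDomain],
) -> pd.DataFrame:
    """Edge table: one row per (element, gene) domain overlap.

    Columns: ucne, gene, distance (signed TSS-to-element distance, 0 when the
    TSS falls inside the element), distance_bin (on the unsigned magnitude).
    """
    domain_ivs = IntervalSet([d.effective for d in domains])
    by_gene = {d.gene.gene_id: d for d in domains}
    rows = []
    for uiv, div in intersect(active_ucnes, domain_ivs):
        d = by_gene[div.name]
        dist = distance_to_point(uiv, d.gene.tss)
        rows.append(
            {
                "ucne": uiv.name,
                "gene": d.gene.gene_id,
                "distance": dist,
                "distance_bin": distance_bin(abs(dist)),
            }
        )
    return pd.DataFrame(rows, columns=["ucne", "gene", "distance", "distance_bin"])


def distance_bin(magnitude: int) -> str:
    for (lo, hi), label in zip(DISTANCE_BINS, DISTANCE_BIN_LABELS):
        if hi is None or magnitude < hi:
            return label
    raise AssertionError("unreachable")


def genes_per_ucne_histogram(edges: pd.DataFrame) -> pd.Series:
    """Number of elements with exactly k target genes."""
    if not len(edges):
        return pd.Series(dtype=int)
    return edges.groupby("ucne")["gene"].nunique().value_counts().sort_index()


def distance_histogram(edges: pd.DataFrame) -> pd.Series:
    counts = {label: 0 for label in DISTANCE_BIN_LABELS}
    for label in edges["distance_bin"]:
        counts[label] += 1
    return pd.Series(counts)


def filter_expressed(
    edges: pd.DataFrame,
    stage_expr: pd.DataFrame,
    tpm_min: float = TPM_MIN,
) -> tuple[pd.DataFrame, int]:
    """Edges whose gene reaches TPM >= ``tpm_min`` in >= 1 stage.

    Non-expression is TPM < 0.5, so exactly 0.5 counts as expressed.  Genes
    absent from the matrix are dropped; their count is returned alongside.
    """
    if not len(edges):
        return edges.copy(), 0
    genes = edges["gene"].unique()
    present = [g for g in genes if g in stage_expr.index]
    n_missing = len(genes) - len(present)
    expressed = {
        g for g in present if float(stage_expr.loc[g].max()) >= tpm_min
    }
    return edges[edges["gene"].isin(expressed)].reset_index(drop=True), n_missing


def tad_consistency(
    edges: pd.DataFrame,
    tads: TADSet,
    ucnes: IntervalSet,
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, float]:
    """Flag edges whose element and target TSS share a TAD.

    An edge is consistent when some TAD overlaps the element by >= 1 bp and
    contains the TSS (half-open, so a TSS at the exclusive TAD end is
    outside).  The summary fraction is over unique target genes.
    """
    ucne_by_name = {iv.name: iv for iv in ucnes}
    gene_by_id = {g.gene_id: g for g in genes}
    tad_by_chrom = tads.tads.by_chrom()
    flags = []
    for row in edges.itertuples(index=False):
        uiv = ucne_by_name[row.ucne]
        g = gene_by_id[row.gene]
        ok = False
        for tad in tad_by_chrom.get(uiv.chrom, []):
            if tad.overlaps(uiv) and g.chrom == tad.chrom and tad.contains_point(g.tss):
                ok = True
                break
        flags.append(ok)
    out = edges.copy()
    out["tad_consistent"] = flags
    if len(out):
        per_gene = out.groupby("gene")["tad_consistent"].any()
        fraction = float(per_gene.sum() / len(per_gene))
    else:
        fraction = float("nan")
    return out, fraction


@dataclass(frozen=True)
class ExpressionSignature:
    gene_id: str
    clusters: frozenset


def assign_signatures(
    cluster_expr: pd.DataFrame,
    pct: float = SIGNATURE_PERCENTILE,
) -> dict[str, ExpressionSignature]:
    """Per-gene cell-cluster signature by within-gene percentile ranking.

    The threshold is the ``pct``-th percentile (linear interpolation) of the
    gene's values across clusters; the signature is the clusters strictly
    above it.  A constant gene (including all-zero) has an empty signature.
    """
    if cluster_expr.shape[1] < 2:
        raise ValueError("need >= 2 clusters to rank expression")
    out = {}
    values = cluster_expr.to_numpy(dtype=float)
    thresholds = np.percentile(values, pct, axis=1)
    cols = np.array(cluster_expr.columns)
    for i, gene in enumerate(cluster_expr.index):
        above = cols[values[i] > thresholds[i]]
        out[str(gene)] = ExpressionSignature(str(gene), frozenset(map(str, above)))
    return out


def concordance(
    edges: pd.DataFrame,
    profiles: Sequence[UCNEActivityProfile],
    signatures: Mapping[str, ExpressionSignature],
    cluster_map: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, float]:
    """Open-chromatin / expression-signature concordance per element.

    An element is concordant when the set of clusters in which it is open
    (scATAC evidence, translated through ``cluster_map`` when accessibility
    and expression use different vocabularies) intersects the union of its
    target genes' signature clusters.  Returns the per-element table and the
    concordant fraction over elements with >= 1 target.
    """
    prof_by_name = {p.ucne.name: p for p in profiles}
    rows = []
    for ucne, grp in edges.groupby("ucne", sort=True):
        prof = prof_by_name[str(ucne)]
        open_clusters = set()
        for cluster in prof.open_clusters:
            if cluster_map is not None:
                if cluster not in cluster_map:
                    raise ValueError(f"unmapped accessibility cluster {cluster!r}")
                cluster = cluster_map[cluster]
            open_clusters.add(cluster)
        target_clusters = set()
        for gene in grp["gene"].unique():
            sig = signatures.get(str(gene))
            if sig is not None:
                target_clusters.update(sig.clusters)
        rows.append(
            {
                "ucne": str(ucne),
                "concordant": bool(open_clusters & target_clusters),
            }
        )
    table = pd.DataFrame(rows, columns=["ucne", "concordant"])
    fraction = float(table["concordant"].mean()) if len(table) else float("nan")
    return table, fraction


def peak2gene_compare(
    edges: pd.DataFrame,
    linkages: Sequence[tuple[GenomicInterval, str, float]],
    ucnes: IntervalSet,
    corr_min: float = P2G_CORR_MIN,
    flank: int = 250,
    assembly: Optional[GenomeAssembly] = None,
) -> pd.DataFrame:
    """Domain-derived vs correlation-derived target sets per element.

    A linkage peak qualifies when its correlation is strictly above
    ``corr_min``; its gene becomes a linkage target of every element within
    ±``flank`` bp of the peak.  Per element the relation is ``identical``,
    ``partial`` (non-empty intersection, sets differ), or ``disjoint``.
    """
    qualifying = [(iv, gene) for iv, gene, corr in linkages if corr > corr_min]
    peak_set = IntervalSet([iv for iv, _g in qualifying])
    gene_by_peak: dict[GenomicInterval, set] = {}
    for iv, gene in qualifying:
        gene_by_peak.setdefault(iv, set()).add(gene)
    linkage_targets: dict[str, set] = {}
    for uiv, piv in window_overlap(ucnes, peak_set, flank, assembly):
        linkage_targets.setdefault(uiv.name, set()).update(gene_by_peak[piv])
    rows = []
    for ucne, grp in edges.groupby("ucne", sort=True):
        domain_set = set(map(str, grp["gene"].unique()))
        link_set = linkage_targets.get(str(ucne), set())
        if domain_set == link_set:
            relation = "identical"
        elif domain_set & link_set:
            relation = "partial"
        else:
            relation = "disjoint"
        rows.append(
            {
                "ucne": str(ucne),
                "domain_targets": ",".join(sorted(domain_set)),
                "linkage_targets": ",".join(sorted(link_set)),
                "relation": relation,
            }
        )
    return pd.DataFrame(
        rows, columns=["ucne", "domain_targets", "linkage_targets", "relation"]
    )


def disease_gene_filter(
    edges: pd.DataFrame, disease_table: pd.DataFrame
) -> pd.DataFrame:
    """Edges whose gene carries a disease-panel annotation."""
    if disease_table["gene_id"].duplicated().any():
        raise ValueError("disease table has duplicate gene keys")
    table = disease_table.set_index("gene_id")
    keep = edges[edges["gene"].isin(table.index)].copy()
    keep["panel"] = [table.loc[g, "panel"] for g in keep["gene"]]
    keep["phenotype"] = [table.loc[g, "phenotype"] for g in keep["gene"]]
    return keep.reset_index(drop=True)
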