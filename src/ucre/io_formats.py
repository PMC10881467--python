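"""Readers and writers for every external file the pipeline touches.

All coordinates are converted to 0-based half-open on read (VCF positions
become ``pos - 1``) and validated against the genome assembly — out-of-bounds
coordinates are errors, never clamped.  Writers emit chromosome-then-start
sorted output so artifacts diff deterministically between runs.

Formats: BED3/BED6, narrowPeak (BED6+4), bedGraph, chrom.sizes, a VCF v4.x
subset (CHROM/POS/REF/ALT with AF, nhomalt, SVTYPE, END INFO keys; read via
pysam), the normative variant TSV schema, gene-model TSV, expression TSV,
TAD BED, disease-gene TSV and validated-enhancer label TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .core_intervals import GenomeAssembly, GenomicInterval, IntervalSet
from .tracks import ConstraintTrack, SignalTrack, StepTrack
from .variant_prioritization import VariantRecord


@dataclass(frozen=True)
class TrackBundle:
    """A labelled interval or signal payload (one mark/stage/cluster)."""

    label: str
    payload: Union[IntervalSet, StepTrack]


class FormatError(ValueError):
    """Malformed input file; message names the file and line."""


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> GenomeAssembly:
    lengths: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            name, length = fields[0], fields[1]
            try:
                lengths[name] = int(length)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad length {length!r}") from None
            order.append(name)
    return GenomeAssembly(tuple(order), lengths)


def write_chrom_sizes(assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for name in assembly.chrom_names:
            fh.write(f"{name}\t{assembly.chrom_lengths[name]}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path, assembly: Optional[GenomeAssembly] = None) -> IntervalSet:
    """BED3/BED6 reader with strict coordinate validation."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if assembly is not None:
                if chrom not in assembly:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > assembly.length(chrom):
                    raise FormatError(
                        f"{path}:{lineno}: end {end} exceeds length of {chrom}"
                    )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    """BED6 when any interval carries name/score/strand, else BED3."""
    six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_narrowpeak(peaks, path) -> None:
    """narrowPeak-style BED6+ output for peak calls.

    Columns: chrom, start, end, name, int score (10 x max value), strand,
    signalValue (run maximum), summit offset.
    """
    ordered = sorted(peaks, key=lambda p: p.interval.sort_key())
    with open(path, "w") as fh:
        for p in ordered:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{int(round(10 * p.max_value))}\t.\t{p.max_value:g}\t"
                f"{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path,
    assembly: Optional[GenomeAssembly] = None,
    track_cls: type[StepTrack] = SignalTrack,
) -> StepTrack:
    """4-column bedGraph to a step-function track; uncovered bases are 0."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad bedGraph fields") from None
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: non-positive step length {chrom}:{start}-{end}"
                )
            if assembly is not None:
                if chrom not in assembly:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > assembly.length(chrom):
                    raise FormatError(
                        f"{path}:{lineno}: end {end} exceeds length of {chrom}"
                    )
            runs.setdefault(chrom, []).append((start, end, value))
    try:
        return track_cls.from_runs(runs, assembly)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: StepTrack, path) -> None:
    """Canonical bedGraph: sorted, zero runs dropped, equal neighbours merged."""
    canon = track.canonical()
    with open(path, "w") as fh:
        for chrom in canon.chroms():
            for start, end, value in canon.runs(chrom):
                # repr keeps full float precision so read(write(t)) == t
                fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_constraint_track(path, assembly: Optional[GenomeAssembly] = None) -> ConstraintTrack:
    """Constraint scores as bedGraph (values may be negative; gaps = missing)."""
    return read_bedgraph(path, assembly, track_cls=ConstraintTrack)


# ---------------------------------------------------------------------------
# variants

VARIANT_TSV_COLUMNS = [
    "chrom",
    "pos",
    "end",
    "ref",
    "alt",
    "svtype",
    "af",
    "observed_in_reference",
    "n_hom",
    "carriers",
]


def _variant_interval(chrom: str, pos: int, end: Optional[int], ref: str, svtype) -> GenomicInterval:
    # VCF POS is 1-based; internal coordinates 0-based half-open
    start = pos - 1
    if svtype is not None and end is not None:
        stop = end
    elif len(ref) > 1:
        stop = start + len(ref)
    else:
        stop = start + 1
    return GenomicInterval(chrom, start, stop)


def read_variants_tsv(path) -> list[VariantRecord]:
    """Normative variant TSV: 1-based pos/end, NA-able af, 0/1 observed flag."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "carriers": str},
        float_precision="round_trip",
    )
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        svtype = None if pd.isna(row.svtype) else str(row.svtype)
        af = None if pd.isna(row.af) else float(row.af)
        n_hom = None if pd.isna(row.n_hom) else int(row.n_hom)
        carriers = ()
        if isinstance(row.carriers, str) and row.carriers:
            carriers = tuple(row.carriers.split(","))
        end = None if pd.isna(row.end) else int(row.end)
        records.append(
            VariantRecord(
                interval=_variant_interval(str(row.chrom), int(row.pos), end, str(row.ref), svtype),
                ref=str(row.ref),
                alt=str(row.alt),
                svtype=svtype,
                af=af,
                observed_in_reference=bool(int(row.observed_in_reference)),
                n_hom=n_hom,
                carriers=carriers,
            )
        )
    return records


def write_variants_tsv(variants: Sequence[VariantRecord], path) -> None:
    rows = []
    for v in sorted(variants, key=lambda v: v.interval.sort_key()):
        rows.append(
            {
                "chrom": v.interval.chrom,
                "pos": v.interval.start + 1,
                "end": v.interval.end,
                "ref": v.ref,
                "alt": v.alt,
                "svtype": v.svtype if v.svtype is not None else pd.NA,
                # repr keeps the full round-trip precision of the float
                "af": repr(v.af) if v.af is not None else pd.NA,
                "observed_in_reference": int(v.observed_in_reference),
                "n_hom": v.n_hom if v.n_hom is not None else pd.NA,
                "carriers": ",".join(v.carriers),
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


_VCF_HEADER_LINES = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Reference population allele frequency">',
    '##INFO=<ID=nhomalt,Number=1,Type=Integer,Description="Reference population homozygote count">',
    '##INFO=<ID=REF_ABSENT,Number=0,Type=Flag,Description="Absent from reference population database">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive) of structural variant">',
    '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Cohort case identifiers carrying the variant">',
]


def write_variants_vcf(
    variants: Sequence[VariantRecord], path, assembly: Optional[GenomeAssembly] = None
) -> None:
    """Plain-text VCF v4.2 subset used by the synthetic cohort."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if assembly is not None:
            for name in assembly.chrom_names:
                fh.write(f"##contig=<ID={name},length={assembly.chrom_lengths[name]}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.interval.sort_key()):
            info = []
            if v.svtype is not None:
                info.append(f"SVTYPE={v.svtype}")
                info.append(f"END={v.interval.end}")
                alt = f"<{v.svtype}>"
            else:
                alt = v.alt
            if not v.observed_in_reference:
                info.append("REF_ABSENT")
            elif v.af is not None:
                info.append(f"AF={v.af:.9g}")
            if v.n_hom is not None:
                info.append(f"nhomalt={v.n_hom}")
            if v.carriers:
                info.append("CARRIERS=" + ",".join(v.carriers))
            fh.write(
                f"{v.interval.chrom}\t{v.interval.start + 1}\t.\t{v.ref}\t{alt}\t"
                f".\t.\t{';'.join(info) or '.'}\n"
            )


def read_variants(path) -> list[VariantRecord]:
    """Read variants from VCF (``.vcf``) or the normative TSV schema.

    A VCF record with neither an AF key nor the absence flag is returned with
    ``af=None`` and ``observed_in_reference=True`` — the frequency-unknown
    state, which downstream classification refuses to default.
    """
    path = os.fspath(path)
    if path.endswith((".tsv", ".txt")):
        return read_variants_tsv(path)
    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            svtype = info.get("SVTYPE")
            end = info.get("END", rec.stop if svtype else None)
            af = info.get("AF")
            if isinstance(af, tuple):
                af = af[0] if af else None
            absent = bool(info.get("REF_ABSENT", False))
            n_hom = info.get("nhomalt")
            carriers = info.get("CARRIERS", ())
            if isinstance(carriers, str):
                carriers = (carriers,)
            alt = rec.alts[0] if rec.alts else "N"
            records.append(
                VariantRecord(
                    interval=_variant_interval(rec.chrom, rec.pos, end, rec.ref, svtype),
                    ref=rec.ref,
                    alt=alt,
                    svtype=svtype,
                    af=None if absent else (float(af) if af is not None else None),
                    observed_in_reference=not absent,
                    n_hom=int(n_hom) if n_hom is not None else None,
                    carriers=tuple(carriers),
                )
            )
    return records


# ---------------------------------------------------------------------------
# gene models, expression, annotation tables


def read_gene_models(path, assembly: Optional[GenomeAssembly] = None) -> pd.DataFrame:
    """TSV with columns gene_id, chrom, tss, strand (tss is 0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene-model columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be + or -")
    if assembly is not None:
        for row in df.itertuples(index=False):
            if row.chrom not in assembly:
                raise FormatError(f"{path}: unknown chromosome {row.chrom!r}")
            if not (0 <= row.tss < assembly.length(row.chrom)):
                raise FormatError(
                    f"{path}: TSS {row.tss} outside {row.chrom}"
                )
    return df[required]


def write_gene_models(genes, path) -> None:
    rows = [
        {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    df.sort_values(["chrom", "tss", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Genes x conditions matrix; first column = gene_id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate condition labels")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def read_disease_genes(path) -> pd.DataFrame:
    """TSV with columns gene_id, panel, phenotype; unique gene keys."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "panel", "phenotype"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate disease gene entries")
    return df


def read_enhancer_labels(path):
    """Validated-enhancer TSV: chrom, start, end, name, label, tissues."""
    from .ccre_annotation import EnhancerLabelTable

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str}, keep_default_na=False)
    elements = []
    for row in df.itertuples(index=False):
        tissues = tuple(t for t in str(row.tissues).split(",") if t)
        elements.append(
            (
                GenomicInterval(row.chrom, int(row.start), int(row.end), name=row.name),
                row.label,
                tissues,
            )
        )
    return EnhancerLabelTable(elements)


def write_enhancer_labels(table, path) -> None:
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "name": iv.name or ".",
            "label": label,
            "tissues": ",".join(tissues),
        }
        for iv, label, tissues in sorted(table.elements, key=lambda e: e[0].sort_key())
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "label", "tissues"]).to_csv(
        path, sep="\t", index=False
    )
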