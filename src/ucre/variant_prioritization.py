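"""Rare-variant filtering and prioritization within active UCNEs.

Cohort variants are binned by reference-population allele frequency
(ultrarare = absent from the reference database; very rare < 0.1%;
rare 0.1–0.5%; low frequency 0.5–5%; common >= 5%), filtered to
MAF < 0.5% with no reference homozygotes, intersected with putatively
active ultraconserved elements, and narrowed to the primary search space:
variants in histone-marked elements whose target genes carry a rare-disease
association.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .ccre_annotation import STATE_ORDER, UCNEActivityProfile
from .core_intervals import GenomicInterval, IntervalSet, intersect


class FrequencyBin(str, enum.Enum):
    ULTRARARE = "ultrarare"
    VERY_RARE = "very_rare"
    RARE = "rare"
    LOW_FREQUENCY = "low_frequency"
    COMMON = "common"


BIN_ORDER = [
    FrequencyBin.ULTRARARE,
    FrequencyBin.VERY_RARE,
    FrequencyBin.RARE,
    FrequencyBin.LOW_FREQUENCY,
    FrequencyBin.COMMON,
]


@dataclass(frozen=True)
class VariantRecord:
    """One cohort variant.

    ``interval`` is 0-based half-open: length 1 for an SNV, the replaced span
    for an indel, the affected span for an SV.  ``af`` is the reference-
    population alternate-allele frequency; ``observed_in_reference=False``
    encodes *absence* from the reference database (the ultrarare bin), which
    is distinct from an unknown frequency (``af is None`` while observed).
    """

    interval: GenomicInterval
    ref: str = "N"
    alt: str = "N"
    svtype: Optional[str] = None
    af: Optional[float] = None
    observed_in_reference: bool = True
    n_hom: Optional[int] = 0
    carriers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")
        if not self.observed_in_reference and self.af is not None:
            raise ValueError("absent-from-reference variant cannot carry an AF")
        if self.n_hom is not None and self.n_hom < 0:
            raise ValueError("negative homozygote count")

    @property
    def is_sv(self) -> bool:
        return self.svtype is not None

    @property
    def frequency_known(self) -> bool:
        return (not self.observed_in_reference) or self.af is not None

    @property
    def maf(self) -> Optional[float]:
        """Minor allele frequency: alternate AF folded at 0.5."""
        if self.af is None:
            return None
        return min(self.af, 1.0 - self.af)

    def vid(self) -> str:
        iv = self.interval
        if self.is_sv:
            return f"{iv.chrom}:{iv.start + 1}-{iv.end}:{self.svtype}"
        return f"{iv.chrom}:{iv.start + 1}:{self.ref}>{self.alt}"


class FrequencyUnknownError(ValueError):
    """Raised when a variant has no usable frequency and no absence flag."""


def classify_frequency(v: VariantRecord) -> FrequencyBin:
    """Frequency bin of a variant; total over every representable frequency.

    Absent from the reference database -> ultrarare.  Otherwise binned on the
    minor allele frequency with left-closed boundaries at 0.1%, 0.5% and 5%.
    An observed variant with unknown frequency is an error, never defaulted.
    """
    if not v.observed_in_reference:
        return FrequencyBin.ULTRARARE
    maf = v.maf
    if maf is None:
        raise FrequencyUnknownError(
            f"variant {v.vid()} observed in reference but has no allele frequency"
        )
    if maf < 0.001:
        return FrequencyBin.VERY_RARE
    if maf < 0.005:
        return FrequencyBin.RARE
    if maf < 0.05:
        return FrequencyBin.LOW_FREQUENCY
    return FrequencyBin.COMMON


def rare_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Variants with MAF < 0.5% (or absent) and no reference homozygotes."""
    kept = []
    for v in variants:
        bin_ = classify_frequency(v)  # validates frequency availability
        if bin_ in (FrequencyBin.ULTRARARE, FrequencyBin.VERY_RARE, FrequencyBin.RARE):
            if (v.n_hom or 0) == 0:
                kept.append(v)
    return kept


@dataclass(frozen=True)
class VariantHit:
    """A variant overlapping a putatively active UCNE."""

    variant: VariantRecord
    ucne: str
    enhancer_state: str
    target_genes: tuple[str, ...]
    frequency_bin: FrequencyBin


def overlap_active_ucnes(
    variants: Sequence[VariantRecord],
    profiles: Sequence[UCNEActivityProfile],
    edges: Optional[pd.DataFrame] = None,
) -> list[VariantHit]:
    """Any-overlap (>= 1 bp) hits between variants and active UCNEs.

    SV spans that merely cover an element count as hits (overlap, not
    containment).  ``edges`` is the target-assignment edge table with at least
    ``ucne`` and ``gene`` columns; targets annotated per hit.
    """
    targets: dict[str, tuple[str, ...]] = {}
    if edges is not None and len(edges):
        for ucne, grp in edges.groupby("ucne"):
            targets[str(ucne)] = tuple(sorted(set(grp["gene"])))
    by_name = {p.ucne.name: p for p in profiles if p.is_open}
    ucne_set = IntervalSet([p.ucne for p in profiles if p.is_open])
    var_set = IntervalSet([v.interval for v in variants])
    var_by_iv = {}
    for v in variants:
        var_by_iv.setdefault(v.interval, []).append(v)
    hits: list[VariantHit] = []
    for viv, uiv in intersect(var_set, ucne_set):
        prof = by_name[uiv.name]
        for v in var_by_iv[viv]:
            hits.append(
                VariantHit(
                    variant=v,
                    ucne=uiv.name,
                    enhancer_state=prof.enhancer_state,
                    target_genes=targets.get(uiv.name, ()),
                    frequency_bin=classify_frequency(v),
                )
            )
    return hits


@dataclass
class SearchSpace:
    hits: list[VariantHit]
    n_variants: int
    n_ucnes: int
    n_genes: int
    n_variants_unsolved: int

    def summary(self) -> dict:
        return {
            "variants": self.n_variants,
            "ucnes": self.n_ucnes,
            "genes": self.n_genes,
            "variants_in_unsolved_cases": self.n_variants_unsolved,
        }


def define_search_space(
    hits: Sequence[VariantHit],
    disease_genes: Iterable[str],
    case_solved: Optional[Mapping[str, bool]] = None,
) -> SearchSpace:
    """Primary search space: hits in histone-marked UCNEs with disease targets.

    A hit qualifies when its UCNE's enhancer state is at least ``marked`` and
    its target-gene set intersects the disease-gene table.  Counts are
    reported overall and restricted to variants carried by >= 1 unsolved case.
    """
    disease = set(disease_genes)
    min_rank = STATE_ORDER.index("marked")
    kept = [
        h
        for h in hits
        if STATE_ORDER.index(h.enhancer_state) >= min_rank
        and disease.intersection(h.target_genes)
    ]
    genes = set()
    for h in kept:
        genes.update(g for g in h.target_genes if g in disease)
    n_unsolved = 0
    if case_solved is not None:
        seen = set()
        for h in kept:
            key = h.variant.vid()
            if key in seen:
                continue
            seen.add(key)
            if any(not case_solved.get(c, True) for c in h.variant.carriers):
                n_unsolved += 1
    n_variants = len({h.variant.vid() for h in kept})
    return SearchSpace(
        hits=kept,
        n_variants=n_variants,
        n_ucnes=len({h.ucne for h in kept}),
        n_genes=len(genes),
        n_variants_unsolved=n_unsolved,
    )


def hits_table(hits: Sequence[VariantHit]) -> pd.DataFrame:
    """Prioritized-hit table, one row per (variant, UCNE) pair."""
    rows = []
    for h in hits:
        rows.append(
            {
                "variant": h.variant.vid(),
                "bin": h.frequency_bin.value,
                "is_sv": h.variant.is_sv,
                "ucne": h.ucne,
                "enhancer_state": h.enhancer_state,
                "genes": ",".join(h.target_genes),
                "carriers": ",".join(h.variant.carriers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "bin",
            "is_sv",
            "ucne",
            "enhancer_state",
            "genes",
            "carriers",
        ],
    )
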