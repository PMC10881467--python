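"""Classify ultraconserved elements as candidate cis-regulatory elements.

Stage 1 of the pipeline: an element is *putatively active* when it overlaps
open chromatin from either bulk DNase or single-cell ATAC at any developmental
stage or cell cluster; histone-mark context is then overlaid through a
±250 bp window, and an enhancer-state ladder assigned::

    none < open_only < marked < active_enhancer < sustained_adult

where ``active_enhancer`` requires H3K27ac at a developmental stage and
``sustained_adult`` additionally requires H3K27ac at an adult stage.
Cross-tabulation against a validated-enhancer label table (VISTA-style)
reports per-set positive proportions and tissue distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    intersect,
    window_overlap,
)

#: the ten chromatin features assessed around accessible elements
DEFAULT_MARKS = (
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9/14Ac",
    "H3K9me3",
    "PolII",
    "CTCF",
)

#: subset associated with active regulation (used for the activating-only count)
ACTIVATING_MARKS = ("H3K27ac", "H3K4me1", "H3K4me2", "H3K4me3", "H3K9/14Ac")

STATE_ORDER = ["none", "open_only", "marked", "active_enhancer", "sustained_adult"]


@dataclass
class UCNEActivityProfile:
    """Per-element evidence matrix: accessibility, marks, derived state."""

    ucne: GenomicInterval
    dnase_stages: set = field(default_factory=set)
    scatac_clusters: set = field(default_factory=set)  # of (cluster, stage)
    marks: dict = field(default_factory=dict)  # mark -> set of stages
    enhancer_state: str = "none"

    @property
    def is_open(self) -> bool:
        return bool(self.dnase_stages) or bool(self.scatac_clusters)

    @property
    def high_confidence(self) -> bool:
        """Supported by both accessibility sources."""
        return bool(self.dnase_stages) and bool(self.scatac_clusters)

    @property
    def open_clusters(self) -> set:
        return {cluster for cluster, _stage in self.scatac_clusters}

    def has_mark(self, mark: str, stages: Optional[Iterable[str]] = None) -> bool:
        hit = self.marks.get(mark, set())
        if stages is None:
            return bool(hit)
        return bool(hit.intersection(stages))


def _as_cluster_key(key) -> tuple[str, str]:
    if isinstance(key, tuple):
        cluster, stage = key
        return str(cluster), str(stage)
    return str(key), ""


def identify_open_ucnes(
    ucnes: IntervalSet,
    dnase_peaks: Mapping[str, IntervalSet],
    scatac_peaks: Mapping[object, IntervalSet],
) -> list[UCNEActivityProfile]:
    """Profile every element; open = >= 1 bp overlap with any peak source.

    Returns one profile per input element (closed elements keep state
    ``none``); the putatively active list is ``[p for p in result if
    p.is_open]`` and the high-confidence subset additionally has
    ``p.high_confidence`` (both sources, Venn-style).
    """
    profiles = {iv: UCNEActivityProfile(ucne=iv) for iv in ucnes}
    for stage, peaks in dnase_peaks.items():
        for uiv, _peak in intersect(ucnes, peaks):
            profiles[uiv].dnase_stages.add(str(stage))
    for key, peaks in scatac_peaks.items():
        ckey = _as_cluster_key(key)
        for uiv, _peak in intersect(ucnes, peaks):
            profiles[uiv].scatac_clusters.add(ckey)
    out = list(profiles.values())
    for p in out:
        if p.is_open:
            p.enhancer_state = "open_only"
    return out


def annotate_marks(
    profiles: Sequence[UCNEActivityProfile],
    chip_peaks: Mapping[tuple[str, str], IntervalSet],
    flank: int = 250,
    assembly: Optional[GenomeAssembly] = None,
    vocabulary: Sequence[str] = DEFAULT_MARKS,
) -> pd.DataFrame:
    """Fill per-profile mark evidence via a ±``flank`` bp window.

    ``chip_peaks`` maps (mark, stage) to a peak set; a mark outside the
    configured vocabulary is an error.  Returns the per-mark-per-stage count
    matrix with a ``unique`` column (elements with that mark at >= 1 stage).
    """
    vocab = set(vocabulary)
    for mark, _stage in chip_peaks:
        if mark not in vocab:
            raise ValueError(
                f"unknown histone/chromatin mark {mark!r}; expected one of "
                f"{sorted(vocab)}"
            )
    ucne_set = IntervalSet([p.ucne for p in profiles])
    by_iv: dict[GenomicInterval, list[UCNEActivityProfile]] = {}
    for p in profiles:
        by_iv.setdefault(p.ucne, []).append(p)
    stages: list[str] = []
    for (mark, stage), peaks in sorted(chip_peaks.items()):
        if stage not in stages:
            stages.append(stage)
        for uiv, _peak in window_overlap(ucne_set, peaks, flank, assembly):
            for p in by_iv[uiv]:
                p.marks.setdefault(mark, set()).add(stage)
    marks_seen = sorted({m for m, _s in chip_peaks})
    counts = pd.DataFrame(0, index=marks_seen, columns=stages + ["unique"])
    for p in profiles:
        for mark, mark_stages in p.marks.items():
            for stage in mark_stages:
                if stage in counts.columns:
                    counts.loc[mark, stage] += 1
            counts.loc[mark, "unique"] += 1
    return counts


def classify_enhancer_state(
    profile: UCNEActivityProfile,
    developmental_stages: Iterable[str],
    adult_stages: Iterable[str],
    assessed_marks: Sequence[str] = DEFAULT_MARKS,
) -> str:
    """Assign the enhancer-state ladder value from accessibility and marks."""
    dev = set(developmental_stages)
    adult = set(adult_stages)
    if not profile.is_open:
        state = "none"
    elif not any(profile.marks.get(m) for m in assessed_marks):
        state = "open_only"
    elif not profile.has_mark("H3K27ac", dev):
        state = "marked"
    elif profile.has_mark("H3K27ac", adult):
        state = "sustained_adult"
    else:
        state = "active_enhancer"
    profile.enhancer_state = state
    return state


def state_counts(profiles: Sequence[UCNEActivityProfile]) -> dict[str, int]:
    """Cumulative ladder counts: each state includes the states above it."""
    ranks = [STATE_ORDER.index(p.enhancer_state) for p in profiles]
    return {
        "open": sum(r >= STATE_ORDER.index("open_only") for r in ranks),
        "marked": sum(r >= STATE_ORDER.index("marked") for r in ranks),
        "active_enhancer": sum(r >= STATE_ORDER.index("active_enhancer") for r in ranks),
        "sustained_adult": sum(r >= STATE_ORDER.index("sustained_adult") for r in ranks),
    }


def marked_counts(
    profiles: Sequence[UCNEActivityProfile],
    assessed_marks: Sequence[str] = DEFAULT_MARKS,
    activating_marks: Sequence[str] = ACTIVATING_MARKS,
) -> dict[str, int]:
    """Elements with >= 1 assessed feature, and the activating-only variant."""
    any_assessed = sum(
        1 for p in profiles if any(p.marks.get(m) for m in assessed_marks)
    )
    any_activating = sum(
        1 for p in profiles if any(p.marks.get(m) for m in activating_marks)
    )
    return {"any_assessed_mark": any_assessed, "any_activating_mark": any_activating}


def h3k4_cooccurrence_fraction(
    profiles: Sequence[UCNEActivityProfile],
) -> Optional[float]:
    """Among H3K27ac-positive elements, fraction also bearing H3K4me1/me2."""
    active = [
        p
        for p in profiles
        if p.enhancer_state in ("active_enhancer", "sustained_adult")
    ]
    if not active:
        return None
    both = sum(
        1 for p in active if p.has_mark("H3K4me1") or p.has_mark("H3K4me2")
    )
    return both / len(active)


@dataclass
class EnhancerLabelTable:
    """Validated-enhancer elements with reporter labels and tissue terms."""

    elements: list  # of (GenomicInterval, label, tissues tuple)

    def __post_init__(self) -> None:
        for iv, label, tissues in self.elements:
            if label not in ("positive", "negative"):
                raise ValueError(f"invalid enhancer label {label!r} for {iv}")
            if label == "negative" and tissues:
                raise ValueError(f"negative element {iv} carries tissue terms")
            if label == "positive" and not tissues:
                raise ValueError(f"positive element {iv} has no tissue terms")

    def interval_set(self) -> IntervalSet:
        return IntervalSet([iv for iv, _l, _t in self.elements])


@dataclass
class VistaCorrelation:
    set_name: str
    n_overlapped: int
    n_positive: int
    undefined: bool
    tissue_mention_fractions: dict[str, float]
    tissue_element_fractions: dict[str, float]

    @property
    def positive_proportion(self) -> Optional[float]:
        if self.undefined:
            return None
        return self.n_positive / self.n_overlapped


def vista_correlate(
    ucne_sets: Mapping[str, IntervalSet],
    labels: EnhancerLabelTable,
) -> dict[str, VistaCorrelation]:
    """Positive proportion and tissue distribution per query set.

    An element of the label table is *overlapped* when it shares >= 1 bp with
    any member of the query set.  The tissue distribution over positives is
    reported both per element–tissue mention (an element contributes once per
    annotated tissue) and per element (each element splits its weight evenly
    across its tissues).
    """
    out: dict[str, VistaCorrelation] = {}
    element_ivs = labels.interval_set()
    meta = {}
    for iv, label, tissues in labels.elements:
        meta.setdefault(iv, []).append((label, tissues))
    for set_name, regions in ucne_sets.items():
        overlapped_ivs = {eiv for eiv, _u in intersect(element_ivs, regions)}
        n_overlapped = 0
        n_positive = 0
        mention_counts: dict[str, float] = {}
        element_counts: dict[str, float] = {}
        for eiv in overlapped_ivs:
            for label, tissues in meta[eiv]:
                n_overlapped += 1
                if label == "positive":
                    n_positive += 1
                    for t in tissues:
                        mention_counts[t] = mention_counts.get(t, 0.0) + 1.0
                        element_counts[t] = element_counts.get(t, 0.0) + 1.0 / len(tissues)
        total_mentions = sum(mention_counts.values())
        total_elements = sum(element_counts.values())
        out[set_name] = VistaCorrelation(
            set_name=set_name,
            n_overlapped=n_overlapped,
            n_positive=n_positive,
            undefined=n_overlapped == 0,
            tissue_mention_fractions={
                t: c / total_mentions for t, c in sorted(mention_counts.items())
            }
            if total_mentions
            else {},
            tissue_element_fractions={
                t: c / total_elements for t, c in sorted(element_counts.items())
            }
            if total_elements
            else {},
        )
    return out
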