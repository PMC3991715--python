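"""Concurrent-LOH detection and overlap-pattern classification.

Two tract sets from one patient — a lower-stage sample (e.g. distant normal,
Td) and a higher-stage one (e.g. tumor, Tt) — are compared.  Concurrence
requires genomic overlap of at least 1 bp.  Overlapping pairs are classified
as Equal (same endpoints), single- or double-end Extension in the low- (Exa)
or high-stage (Exb) sample, or Partial overlap (staggered: both endpoints
differ, neither tract contains the other).  The change statistic
(Total - Equal)/Total summarises how often concurrent tract boundaries differ
between the two samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .calling import LOHTract, TractSet

__all__ = [
    "OverlapClass",
    "OverlapRecord",
    "ConcurrenceSummary",
    "overlap_length",
    "find_concurrent",
    "concurrence_rate",
    "classify_overlap",
    "overlap_summary",
]


class OverlapClass(str, Enum):
    EQUAL = "Equal"
    EXA_S = "Exa-s"  # single-end extension in the low-stage sample
    EXA_D = "Exa-d"  # double-end extension (low contains high)
    EXB_S = "Exb-s"
    EXB_D = "Exb-d"
    PARTIAL = "Pa"


def overlap_length(a: LOHTract, b: LOHTract) -> int:
    """Inclusive overlap in bp; 0 for different chromosomes or disjoint tracts."""
    if a.chrom != b.chrom:
        return 0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    return max(ov, 0)


@dataclass(frozen=True)
class OverlapRecord:
    """One concurrent low-/high-stage tract pair with length decomposition.

    ``extension_low``/``extension_high`` are the bp of each tract lying
    outside the shared region; for Pa pairs ``nonoverlap_bp`` is their sum
    (the combined non-shared footprint).
    """

    low: LOHTract
    high: LOHTract
    overlap_class: OverlapClass
    overlap_bp: int
    extension_low_bp: int
    extension_high_bp: int
    nonoverlap_bp: int = 0


def classify_overlap(low: LOHTract, high: LOHTract) -> OverlapRecord:
    """Classify an overlapping tract pair into its unique overlap pattern.

    Equal: identical endpoints.  Exa/Exb: the low/high tract is longer with
    one shared endpoint (-s) or strictly contains the other (-d).  Pa:
    staggered overlap (both endpoints differ, no containment).
    """
    ov = overlap_length(low, high)
    if ov < 1:
        raise ValueError("classify_overlap requires >= 1 bp of overlap")
    ext_low = low.length - ov
    ext_high = high.length - ov
    same_start = low.start == high.start
    same_end = low.end == high.end
    if same_start and same_end:
        cls = OverlapClass.EQUAL
    elif low.start <= high.start and low.end >= high.end:
        cls = OverlapClass.EXA_S if (same_start or same_end) else OverlapClass.EXA_D
    elif high.start <= low.start and high.end >= low.end:
        cls = OverlapClass.EXB_S if (same_start or same_end) else OverlapClass.EXB_D
    else:
        cls = OverlapClass.PARTIAL
    return OverlapRecord(
        low=low,
        high=high,
        overlap_class=cls,
        overlap_bp=ov,
        extension_low_bp=ext_low,
        extension_high_bp=ext_high,
        nonoverlap_bp=ext_low + ext_high if cls is OverlapClass.PARTIAL else 0,
    )


def _overlap_flags(setA: TractSet, setB: TractSet) -> np.ndarray:
    """Boolean flag per A-tract: overlaps >= 1 bp with any B-tract.

    Sort-based: per chromosome, B tracts sorted by start with a running
    maximum of ends answer "any B starting at or before a.end that reaches
    a.start" in O(log m) per query.
    """
    flags = np.zeros(len(setA), dtype=bool)
    by_chrom: dict[int, list[LOHTract]] = {}
    for t in setB:
        by_chrom.setdefault(t.chrom, []).append(t)
    index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ts in by_chrom.items():
        starts = np.array([t.start for t in ts])
        ends = np.array([t.end for t in ts])
        order = np.argsort(starts, kind="stable")
        index[chrom] = (starts[order], np.maximum.accumulate(ends[order]))
    for i, a in enumerate(setA):
        entry = index.get(a.chrom)
        if entry is None:
            continue
        starts_b, cummax_ends = entry
        j = int(np.searchsorted(starts_b, a.end, side="right"))
        flags[i] = j > 0 and int(cummax_ends[j - 1]) >= a.start
    return flags


def find_concurrent(
    setA: TractSet, setB: TractSet
) -> tuple[list[OverlapRecord], np.ndarray, np.ndarray]:
    """All >= 1 bp-overlapping (A, B) tract pairs plus per-tract flags.

    A is treated as the low-stage sample for classification.  A tract
    overlapping several partners yields one record per pair, but is flagged
    concurrent once (rate denominators count tracts, not pairs).
    """
    if setA.patient != setB.patient:
        raise ValueError(
            f"tract sets from different patients: {setA.patient!r} vs {setB.patient!r}"
        )
    records: list[OverlapRecord] = []
    flags_a = np.zeros(len(setA), dtype=bool)
    flags_b = np.zeros(len(setB), dtype=bool)
    b_by_chrom: dict[int, list[tuple[int, LOHTract]]] = {}
    for j, t in enumerate(setB):
        b_by_chrom.setdefault(t.chrom, []).append((j, t))
    for i, a in enumerate(setA):
        for j, b in b_by_chrom.get(a.chrom, []):
            if b.start > a.end:
                break  # B sorted by start within chromosome
            if overlap_length(a, b) >= 1:
                records.append(classify_overlap(a, b))
                flags_a[i] = True
                flags_b[j] = True
    return records, flags_a, flags_b


def concurrence_rate(setA: TractSet, setB: TractSet) -> dict[str, float]:
    """Fraction of tracts in each set with a concurrent partner in the other.

    Keys ``"A_to_B"`` and ``"B_to_A"``.  An empty set makes its own direction
    undefined; requesting it raises.
    """
    if setA.patient != setB.patient:
        raise ValueError("tract sets from different patients")
    if len(setA) == 0 or len(setB) == 0:
        raise ValueError("concurrence rate undefined for an empty tract set")
    return {
        "A_to_B": float(np.mean(_overlap_flags(setA, setB))),
        "B_to_A": float(np.mean(_overlap_flags(setB, setA))),
    }


@dataclass
class ConcurrenceSummary:
    """Overlap-pattern tallies for one patient pairing.

    ``prop_of_change`` = (Total - Equal)/Total: the fraction of concurrent
    pairs whose boundaries differ between samples.  Extension totals are the
    summed bp by which Exa/Exb tracts extend past the shared region, also
    expressed as a fraction of each sample's total tract length when those
    totals are supplied.
    """

    counts: dict[OverlapClass, int]
    total: int
    prop_of_change: float | None
    exa_extension_bp: int = 0
    exb_extension_bp: int = 0
    pa_overlap_bp: int = 0
    pa_nonoverlap_bp: int = 0
    exa_extension_frac_of_low: float | None = None
    exb_extension_frac_of_high: float | None = None
    rate_low_to_high: float | None = None
    rate_high_to_low: float | None = None

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total != sum of class counts")

    @property
    def n_single_end(self) -> int:
        return self.counts[OverlapClass.EXA_S] + self.counts[OverlapClass.EXB_S]

    @property
    def n_double_end(self) -> int:
        return self.counts[OverlapClass.EXA_D] + self.counts[OverlapClass.EXB_D]

    @classmethod
    def from_counts(cls, counts: dict[OverlapClass, int]) -> "ConcurrenceSummary":
        """Summary from per-class counts alone (length fields zero)."""
        full = {c: int(counts.get(c, 0)) for c in OverlapClass}
        total = sum(full.values())
        prop = None
        if total > 0:
            prop = (total - full[OverlapClass.EQUAL]) / total
        return cls(counts=full, total=total, prop_of_change=prop)

    def to_dict(self) -> dict:
        d = {c.value: n for c, n in self.counts.items()}
        d.update(
            total=self.total,
            prop_of_change=self.prop_of_change,
            exa_extension_bp=self.exa_extension_bp,
            exb_extension_bp=self.exb_extension_bp,
            pa_overlap_bp=self.pa_overlap_bp,
            pa_nonoverlap_bp=self.pa_nonoverlap_bp,
            exa_extension_frac_of_low=self.exa_extension_frac_of_low,
            exb_extension_frac_of_high=self.exb_extension_frac_of_high,
            rate_low_to_high=self.rate_low_to_high,
            rate_high_to_low=self.rate_high_to_low,
        )
        return d


def overlap_summary(
    records: list[OverlapRecord],
    low_total_length: int | None = None,
    high_total_length: int | None = None,
) -> ConcurrenceSummary:
    """Tally overlap classes and length decompositions over pair records.

    Pair-level counting: a tract overlapping k partners contributes k
    records.  With zero records the summary is all-zero and
    ``prop_of_change`` is None (flagged undefined).
    """
    counts = {c: 0 for c in OverlapClass}
    exa = exb = pa_ov = pa_nov = 0
    for r in records:
        counts[r.overlap_class] += 1
        if r.overlap_class in (OverlapClass.EXA_S, OverlapClass.EXA_D):
            exa += r.extension_low_bp
        elif r.overlap_class in (OverlapClass.EXB_S, OverlapClass.EXB_D):
            exb += r.extension_high_bp
        elif r.overlap_class is OverlapClass.PARTIAL:
            pa_ov += r.overlap_bp
            pa_nov += r.nonoverlap_bp
    total = len(records)
    summary = ConcurrenceSummary(
        counts=counts,
        total=total,
        prop_of_change=(total - counts[OverlapClass.EQUAL]) / total if total else None,
        exa_extension_bp=exa,
        exb_extension_bp=exb,
        pa_overlap_bp=pa_ov,
        pa_nonoverlap_bp=pa_nov,
    )
    if low_total_length:
        summary.exa_extension_frac_of_low = exa / low_total_length
    if high_total_length:
        summary.exb_extension_frac_of_high = exb / high_total_length
    return summary


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Flatten overlap records for TSV export."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient": r.low.patient,
                "low_sample": r.low.sample,
                "high_sample": r.high.sample,
                "chrom": r.low.chrom,
                "low_start": r.low.start,
                "low_end": r.low.end,
                "high_start": r.high.start,
                "high_end": r.high.end,
                "class": r.overlap_class.value,
                "overlap_bp": r.overlap_bp,
                "extension_low_bp": r.extension_low_bp,
                "extension_high_bp": r.extension_high_bp,
                "nonoverlap_bp": r.nonoverlap_bp,
            }
        )
    cols = [
        "patient", "low_sample", "high_sample", "chrom", "low_start", "low_end",
        "high_start", "high_end", "class", "overlap_bp", "extension_low_bp",
        "extension_high_bp", "nonoverlap_bp",
    ]
    return pd.DataFrame(rows, columns=cols)
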