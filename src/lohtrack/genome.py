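"""Domain model for paired-genotype LOH analysis.

Genotypes at biallelic autosomal loci are abstracted to two allele codes (A/B)
plus a no-call state, so every germline x tissue call pair falls into exactly
one of ten transition categories.  The category of interest is HET->HOM — a
locus heterozygous in germline (an *informative* marker) that has become
homozygous in a tissue sample, the elementary loss-of-heterozygosity event.

Coordinates are 1-based inclusive throughout the library; BED import/export
(see :mod:`lohtrack.io`) converts to and from 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "TransitionType",
    "TERMINATORS",
    "classify_transition",
    "classify_transitions",
    "ArmDefinition",
    "CNVSegment",
    "GeneRegion",
    "GenomeAnnotation",
    "PairedGenotypeTable",
    "assign_arm",
    "validate_annotation",
    "UnassignableLocusError",
    "AnnotationError",
]


class Genotype(IntEnum):
    """Diploid biallelic genotype call: unordered allele pair or no-call."""

    AA = 0
    AB = 1
    BB = 2
    NOCALL = 3


class TransitionType(IntEnum):
    """Category of a (germline, tissue) genotype pair.

    The ten categories partition all 4x4 call pairs.  HET_TO_HOM is the LOH
    event; MONOALLELIC_MUTATION is germline HOM -> tissue HET sharing one
    allele (AA->AB), BIALLELIC_MUTATION is germline HOM -> the opposite
    HOM (AA->BB).
    """

    HET_TO_HOM = 0
    HOM_TO_HOM = 1
    HET_TO_HET = 2
    HET_TO_UNK = 3
    UNK_TO_UNK = 4
    UNK_TO_HET = 5
    UNK_TO_HOM = 6
    HOM_TO_UNK = 7
    MONOALLELIC_MUTATION = 8
    BIALLELIC_MUTATION = 9


def _classify_pair(g: Genotype, t: Genotype) -> TransitionType:
    T = TransitionType
    g_hom = g in (Genotype.AA, Genotype.BB)
    t_hom = t in (Genotype.AA, Genotype.BB)
    if g == Genotype.AB:
        if t_hom:
            return T.HET_TO_HOM
        if t == Genotype.AB:
            return T.HET_TO_HET
        return T.HET_TO_UNK
    if g_hom:
        if t == g:
            return T.HOM_TO_HOM
        if t_hom:  # opposite homozygote
            return T.BIALLELIC_MUTATION
        if t == Genotype.AB:
            return T.MONOALLELIC_MUTATION
        return T.HOM_TO_UNK
    # germline no-call
    if t == Genotype.NOCALL:
        return T.UNK_TO_UNK
    if t == Genotype.AB:
        return T.UNK_TO_HET
    return T.UNK_TO_HOM


#: 4x4 lookup table indexed by (germline, tissue) genotype codes.
TRANSITION_TABLE = np.empty((4, 4), dtype=np.uint8)
for _g in Genotype:
    for _t in Genotype:
        TRANSITION_TABLE[_g, _t] = _classify_pair(_g, _t)

#: Transitions that break an LOH tract.  Each carries positive evidence
#: against LOH continuity (retained heterozygosity, uninformative stretch, or
#: a biallelic change).  HOM_TO_UNK / UNK_TO_HOM carry no heterozygosity
#: information and do not terminate, but they do count toward no-call QC.
TERMINATORS = frozenset(
    {
        TransitionType.HET_TO_HET,
        TransitionType.HET_TO_UNK,
        TransitionType.UNK_TO_UNK,
        TransitionType.UNK_TO_HET,
        TransitionType.BIALLELIC_MUTATION,
    }
)

IS_TERMINATOR = np.zeros(len(TransitionType), dtype=bool)
for _tt in TERMINATORS:
    IS_TERMINATOR[_tt] = True


def classify_transition(germline: Genotype, tissue: Genotype) -> TransitionType:
    """Classify a single germline/tissue call pair (total function)."""
    return TransitionType(int(TRANSITION_TABLE[int(germline), int(tissue)]))


def classify_transitions(germline: np.ndarray, tissue: np.ndarray) -> np.ndarray:
    """Vectorised transition classification for genotype code arrays."""
    g = np.asarray(germline, dtype=np.intp)
    t = np.asarray(tissue, dtype=np.intp)
    if g.shape != t.shape:
        raise ValueError("germline and tissue vectors differ in length")
    return TRANSITION_TABLE[g, t]


class UnassignableLocusError(ValueError):
    """A locus falls outside every arm of its chromosome (e.g. centromere)."""


class AnnotationError(ValueError):
    """Malformed genome annotation."""


@dataclass(frozen=True)
class ArmDefinition:
    """A chromosome arm: 1-based inclusive span plus its centromeric edge.

    ``centromere_boundary`` is the bp coordinate of the arm edge adjacent to
    the centromere (``end`` for a p arm, ``start`` for a q arm in the usual
    orientation); it anchors the centromeric exclusion zone of the
    permutation null.
    """

    chrom: int
    arm: str  # "p" | "q"
    start: int
    end: int
    centromere_boundary: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise AnnotationError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.start > self.end:
            raise AnnotationError(f"arm {self.name}: start > end")
        if self.start < 1:
            raise AnnotationError(f"arm {self.name}: start < 1")

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def centromeric_edge_is_end(self) -> bool:
        """True if the arm's ``end`` side faces the centromere."""
        return abs(self.centromere_boundary - self.end) <= abs(
            self.centromere_boundary - self.start
        )


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment call for one tissue sample (1-based inclusive)."""

    chrom: int
    start: int
    end: int
    state: str  # "loss" | "neutral" | "gain"
    sample: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV segment start > end")
        if self.state not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown CNV state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval with fragile-site and cancer-census membership flags."""

    name: str
    chrom: int
    start: int
    end: int
    is_fragile_site_collocated: bool = False
    is_cancer_census: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def dedupe_genes(genes: list[GeneRegion]) -> list[GeneRegion]:
    """Resolve duplicate gene names by retaining the longest entry."""
    best: dict[str, GeneRegion] = {}
    for g in genes:
        cur = best.get(g.name)
        if cur is None or g.length > cur.length:
            best[g.name] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start, g.name))


@dataclass
class GenomeAnnotation:
    """Chromosome arms plus gene regions, with arm-lookup helpers."""

    arms: list[ArmDefinition]
    genes: list[GeneRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arms = sorted(self.arms, key=lambda a: (a.chrom, a.start))
        self._by_chrom: dict[int, list[ArmDefinition]] = {}
        for a in self.arms:
            self._by_chrom.setdefault(a.chrom, []).append(a)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self._by_chrom)

    def arms_for(self, chrom: int) -> list[ArmDefinition]:
        return self._by_chrom.get(chrom, [])

    def arm_of(self, chrom: int, pos: int) -> ArmDefinition:
        return assign_arm(chrom, pos, self.arms_for(chrom))

    def arm_by_name(self, name: str) -> ArmDefinition:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


def assign_arm(chrom: int, pos: int, arms: list[ArmDefinition]) -> ArmDefinition:
    """Return the unique arm whose inclusive span contains ``pos``.

    Raises :class:`UnassignableLocusError` for positions in a centromeric gap
    or otherwise outside every arm of the chromosome.
    """
    for a in arms:
        if a.chrom == chrom and a.start <= pos <= a.end:
            return a
    raise UnassignableLocusError(f"position {chrom}:{pos} lies outside every arm")


def validate_annotation(
    arms: list[ArmDefinition], genes: list[GeneRegion]
) -> list[str]:
    """Report structural problems in an annotation (report-only, never raises).

    Findings cover overlapping arms on a chromosome, genes outside any
    arm-covered range, and duplicate gene names not resolved to the longest
    entry.  A well-formed annotation yields an empty list.
    """
    findings: list[str] = []
    by_chrom: dict[int, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, chrom_arms in sorted(by_chrom.items()):
        chrom_arms = sorted(chrom_arms, key=lambda a: a.start)
        for prev, cur in zip(chrom_arms, chrom_arms[1:]):
            if cur.start <= prev.end:
                findings.append(
                    f"arms {prev.name} and {cur.name} overlap on chromosome {chrom}"
                )
    seen: dict[str, GeneRegion] = {}
    for g in genes:
        try:
            assign_arm(g.chrom, g.start, arms)
            assign_arm(g.chrom, g.end, arms)
        except UnassignableLocusError:
            findings.append(f"gene {g.name} extends outside arm-covered ranges")
        if g.name in seen:
            other = seen[g.name]
            keep = g if g.length > other.length else other
            findings.append(
                f"duplicate gene name {g.name}; longest entry "
                f"({keep.chrom}:{keep.start}-{keep.end}) should be retained"
            )
        else:
            seen[g.name] = g
    return findings


@dataclass
class PairedGenotypeTable:
    """Genotype calls for one patient over a shared ordered locus panel.

    ``loci`` has columns ``chrom`` (int), ``pos`` (1-based int),
    ``variant_id`` (str) and ``vtype`` ("SNP"|"INDEL"), sorted by
    (chrom, pos) with strictly increasing positions per chromosome.
    ``germline`` and each tissue vector hold :class:`Genotype` codes
    (uint8) aligned to the panel.
    """

    patient: str
    loci: pd.DataFrame
    germline: np.ndarray
    tissues: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "variant_id"}
        missing = required - set(self.loci.columns)
        if missing:
            raise ValueError(f"loci table missing columns: {sorted(missing)}")
        if "vtype" not in self.loci.columns:
            self.loci = self.loci.assign(vtype="SNP")
        n = len(self.loci)
        self.germline = np.asarray(self.germline, dtype=np.uint8)
        if len(self.germline) != n:
            raise ValueError("germline vector length != panel size")
        for label, vec in list(self.tissues.items()):
            vec = np.asarray(vec, dtype=np.uint8)
            if len(vec) != n:
                raise ValueError(f"tissue vector {label!r} length != panel size")
            self.tissues[label] = vec
        chrom = self.loci["chrom"].to_numpy()
        pos = self.loci["pos"].to_numpy()
        if n > 1:
            same = chrom[1:] == chrom[:-1]
            if np.any(chrom[1:] < chrom[:-1]):
                raise ValueError("panel not sorted by chromosome")
            if np.any(same & (pos[1:] <= pos[:-1])):
                raise ValueError("positions not strictly increasing within chromosome")
        if (pos < 1).any():
            raise ValueError("positions must be >= 1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.tissues)

    def tissue(self, label: str) -> np.ndarray:
        try:
            return self.tissues[label]
        except KeyError:
            raise KeyError(
                f"unknown sample {label!r}; have {self.sample_labels}"
            ) from None

    def transitions(self, label: str) -> np.ndarray:
        """Per-locus transition categories for germline vs one tissue."""
        return classify_transitions(self.germline, self.tissue(label))

    def germline_het_mask(self) -> np.ndarray:
        return self.germline == Genotype.AB

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """Contiguous panel slice per chromosome, in order."""
        chrom = self.loci["chrom"].to_numpy()
        out: list[tuple[int, slice]] = []
        if len(chrom) == 0:
            return out
        bounds = np.flatnonzero(np.diff(chrom) != 0) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(chrom)]))
        for s, e in zip(starts, ends):
            out.append((int(chrom[s]), slice(int(s), int(e))))
        return out
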