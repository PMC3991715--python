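"""LOH tract calling from paired germline/tissue genotype vectors.

An LOH tract is a maximal run of HET->HOM events on one chromosome arm, within
one copy-number-state block, that is not interrupted by a terminating
transition (HET->HET, HET->UNK, UNK->UNK, UNK->HET, or a biallelic mutation).
Interior loci may be HOM->HOM, a monoallelic mutation, or one-sided no-calls:
none of those carry evidence against LOH continuity.  Tract coordinates span
the outermost supporting events, so a single-event tract has length 1 bp.

The caller proceeds per arm: CNV stratification -> run scanning -> optional
sparsity splitting of copy-neutral tracts at >gap_threshold event gaps
(array-mode input) -> QC exclusion of tracts with >20% monoallelic mutation
or >20% no-call rate across the tract span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (
    IS_TERMINATOR,
    CNVSegment,
    GenomeAnnotation,
    Genotype,
    PairedGenotypeTable,
    TransitionType,
)

__all__ = [
    "CallerParams",
    "LOHTract",
    "TractSet",
    "stratify_by_cnv",
    "scan_tracts",
    "split_sparse",
    "derive_gap_threshold",
    "qc_filter",
    "call_patient",
]

_STATE_CODE = {"neutral": 0, "loss": 1, "gain": 2}
_STATE_NAME = {v: k for k, v in _STATE_CODE.items()}


@dataclass(frozen=True)
class CallerParams:
    """Tract-caller parameters.

    ``min_events`` is the support criterion: 2 for the stringent standard,
    1 for the loose one.  ``gap_threshold_bp`` is the copy-neutral sparsity
    split distance (default 40 kb, the upper outer fence of inter-HET
    spacing on the genotyping platform).  QC bounds are exclusive: a tract
    is dropped only when a fraction strictly exceeds 0.20.
    ``cnv_min_length_bp`` drops short CNV calls before stratification and
    is intended for sequencing-derived CNV input (default 100 kb there,
    0 for array-mode segments which are taken as given).
    """

    min_events: int = 2
    gap_threshold_bp: int = 40_000
    apply_sparsity_split: bool = True
    qc_monoallelic_max: float = 0.20
    qc_nocall_max: float = 0.20
    cnv_min_length_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.gap_threshold_bp <= 0:
            raise ValueError("gap_threshold_bp must be positive")
        if self.cnv_min_length_bp < 0:
            raise ValueError("cnv_min_length_bp must be >= 0")

    @classmethod
    def array_mode(cls, **kw) -> "CallerParams":
        """Defaults for SNP-array genotypes: sparsity split on, CNV as given."""
        kw.setdefault("apply_sparsity_split", True)
        kw.setdefault("cnv_min_length_bp", 0)
        return cls(**kw)

    @classmethod
    def sequencing_mode(cls, **kw) -> "CallerParams":
        """Defaults for sequencing genotypes: dense markers need no sparsity
        split; CNV calls shorter than 100 kb are dropped."""
        kw.setdefault("apply_sparsity_split", False)
        kw.setdefault("cnv_min_length_bp", 100_000)
        return cls(**kw)


@dataclass
class LOHTract:
    """A called LOH tract spanning its outermost HET->HOM events.

    ``event_positions`` carries the supporting event coordinates through the
    calling pipeline (splitting, QC); it is excluded from equality so tracts
    compare on their observable fields.
    """

    chrom: int
    arm: str
    start: int
    end: int
    n_events: int
    copy_state: str = "neutral"
    qc_monoallelic: float = 0.0
    qc_nocall_germline: float = 0.0
    qc_nocall_tissue: float = 0.0
    patient: str = ""
    sample: str = ""
    event_positions: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")
        if self.n_events < 1:
            raise ValueError("tract must have >= 1 supporting event")

    @property
    def length(self) -> int:
        """Inclusive tract length in bp (single event -> 1 bp)."""
        return self.end - self.start + 1

    @property
    def arm_name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass
class TractSet:
    """Called tracts for one (patient, tissue sample) pairing."""

    patient: str
    sample: str
    tracts: list[LOHTract]
    params: CallerParams | None = None

    def __post_init__(self) -> None:
        self.tracts = sorted(self.tracts, key=lambda t: (t.chrom, t.start))
        for prev, cur in zip(self.tracts, self.tracts[1:]):
            if cur.chrom == prev.chrom and cur.start <= prev.end:
                raise ValueError(
                    f"overlapping tracts within sample {self.sample!r}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} / "
                    f"{cur.chrom}:{cur.start}-{cur.end}"
                )

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def __getitem__(self, i: int) -> LOHTract:
        return self.tracts[i]

    @property
    def total_length(self) -> int:
        return sum(t.length for t in self.tracts)

    def summary(self) -> dict:
        """Per-sample totals: count and tract length, overall and by copy state."""
        by_state_n = {s: 0 for s in _STATE_CODE}
        by_state_len = {s: 0 for s in _STATE_CODE}
        for t in self.tracts:
            by_state_n[t.copy_state] += 1
            by_state_len[t.copy_state] += t.length
        return {
            "patient": self.patient,
            "sample": self.sample,
            "n_tracts": len(self.tracts),
            "total_length_bp": self.total_length,
            "n_by_state": by_state_n,
            "length_by_state": by_state_len,
        }

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "chrom", "arm", "start", "end", "n_events", "copy_state", "length",
            "qc_monoallelic", "qc_nocall_germline", "qc_nocall_tissue",
            "patient", "sample",
        ]
        rows = [
            (
                t.chrom, t.arm, t.start, t.end, t.n_events, t.copy_state,
                t.length, t.qc_monoallelic, t.qc_nocall_germline,
                t.qc_nocall_tissue, t.patient, t.sample,
            )
            for t in self.tracts
        ]
        return pd.DataFrame(rows, columns=cols)


def derive_gap_threshold(het_spacings) -> float:
    """Upper outer fence Q3 + 3*IQR of inter-heterozygote spacings.

    Uses linear-interpolation quantiles.  This is how the 40 kb default
    sparsity-split distance was derived from platform HET spacing; supply
    platform-specific spacings to recalibrate it.
    """
    x = np.asarray(het_spacings, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 spacing values to derive a fence")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 + 3.0 * (q3 - q1))


def stratify_by_cnv(
    positions: np.ndarray,
    chrom: int,
    segments: list[CNVSegment],
    params: CallerParams,
    sample: str | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Partition sorted locus positions on one chromosome (or arm) into
    maximal blocks of constant copy-number state.

    Loci outside every segment are copy-neutral.  Segments shorter than
    ``params.cnv_min_length_bp`` are dropped before assignment.  Overlapping
    segments for the sample are rejected.

    Returns ``[(state, index_array), ...]`` in positional order.
    """
    positions = np.asarray(positions)
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    segs = [
        s
        for s in segments
        if s.chrom == chrom
        and (sample is None or s.sample == sample)
        and s.length >= params.cnv_min_length_bp
    ]
    segs.sort(key=lambda s: s.start)
    for prev, cur in zip(segs, segs[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"overlapping CNV segments for sample: "
                f"{prev.start}-{prev.end} / {cur.start}-{cur.end}"
            )
    state = np.zeros(positions.size, dtype=np.uint8)
    for s in segs:
        lo = np.searchsorted(positions, s.start, side="left")
        hi = np.searchsorted(positions, s.end, side="right")
        state[lo:hi] = _STATE_CODE[s.state]
    blocks: list[tuple[str, np.ndarray]] = []
    if positions.size == 0:
        return blocks
    bounds = np.flatnonzero(np.diff(state) != 0) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [state.size]))
    for s0, e0 in zip(starts, ends):
        blocks.append((_STATE_NAME[int(state[s0])], np.arange(s0, e0)))
    return blocks


def scan_tracts(
    positions: np.ndarray,
    transitions: np.ndarray,
    min_events: int,
    *,
    chrom: int = 0,
    arm: str = "",
    copy_state: str = "neutral",
    patient: str = "",
    sample: str = "",
) -> list[LOHTract]:
    """Scan one CNV-state block for maximal terminator-free HET->HOM runs.

    Runs with fewer than ``min_events`` events are discarded; tract start/end
    are the outermost event positions, copy state is inherited from the block.
    """
    positions = np.asarray(positions)
    transitions = np.asarray(transitions)
    if positions.shape != transitions.shape:
        raise ValueError("positions and transitions differ in length")
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if positions.size == 0:
        return []
    is_event = transitions == TransitionType.HET_TO_HOM
    is_term = IS_TERMINATOR[transitions]
    # loci between terminator k and k+1 share segment id; events group by it
    seg_id = np.cumsum(is_term)
    ev_idx = np.flatnonzero(is_event)
    if ev_idx.size == 0:
        return []
    ev_seg = seg_id[ev_idx]
    run_starts = np.flatnonzero(np.diff(ev_seg) != 0) + 1
    starts = np.concatenate(([0], run_starts))
    ends = np.concatenate((run_starts, [ev_idx.size]))
    tracts: list[LOHTract] = []
    for s, e in zip(starts, ends):
        n = int(e - s)
        if n < min_events:
            continue
        run_pos = positions[ev_idx[s:e]]
        tracts.append(
            LOHTract(
                chrom=chrom,
                arm=arm,
                start=int(run_pos[0]),
                end=int(run_pos[-1]),
                n_events=n,
                copy_state=copy_state,
                patient=patient,
                sample=sample,
                event_positions=np.asarray(run_pos),
            )
        )
    return tracts


def split_sparse(tracts: list[LOHTract], params: CallerParams) -> list[LOHTract]:
    """Split copy-neutral tracts at event gaps strictly above the threshold.

    The region between distant events is called not affected by LOH, a guard
    against sparse marker coverage on genotyping arrays.  Fragments are
    re-filtered by ``params.min_events``; non-neutral tracts pass through
    unchanged.  Splitting is single-pass: every qualifying gap is cut at once.
    """
    out: list[LOHTract] = []
    for t in tracts:
        if t.copy_state != "neutral" or t.event_positions is None or t.n_events < 2:
            if t.n_events >= params.min_events:
                out.append(t)
            continue
        pos = t.event_positions
        gaps = np.diff(pos)
        cut = np.flatnonzero(gaps > params.gap_threshold_bp) + 1
        if cut.size == 0:
            if t.n_events >= params.min_events:
                out.append(t)
            continue
        starts = np.concatenate(([0], cut))
        ends = np.concatenate((cut, [pos.size]))
        for s, e in zip(starts, ends):
            n = int(e - s)
            if n < params.min_events:
                continue
            frag = pos[s:e]
            out.append(
                replace(
                    t,
                    start=int(frag[0]),
                    end=int(frag[-1]),
                    n_events=n,
                    event_positions=np.asarray(frag),
                )
            )
    return out


def qc_filter(
    tract: LOHTract,
    positions: np.ndarray,
    transitions: np.ndarray,
    germline: np.ndarray,
    tissue: np.ndarray,
    params: CallerParams,
) -> tuple[bool, LOHTract]:
    """Decide whether a tract survives the quality bounds.

    Over all panel loci within the tract span [start, end]: the monoallelic
    fraction is #MONOALLELIC_MUTATION / #span loci, and no-call fractions are
    computed for germline and tissue separately.  The tract is dropped iff any
    metric *strictly* exceeds its bound; metrics are recorded either way.
    """
    positions = np.asarray(positions)
    lo = int(np.searchsorted(positions, tract.start, side="left"))
    hi = int(np.searchsorted(positions, tract.end, side="right"))
    n_span = hi - lo
    if n_span == 0:
        raise RuntimeError("tract span contains no panel loci")
    tr = np.asarray(transitions)[lo:hi]
    mono = float(np.mean(tr == TransitionType.MONOALLELIC_MUTATION))
    nc_g = float(np.mean(np.asarray(germline)[lo:hi] == Genotype.NOCALL))
    nc_t = float(np.mean(np.asarray(tissue)[lo:hi] == Genotype.NOCALL))
    scored = replace(
        tract,
        qc_monoallelic=mono,
        qc_nocall_germline=nc_g,
        qc_nocall_tissue=nc_t,
        event_positions=tract.event_positions,
    )
    keep = not (
        mono > params.qc_monoallelic_max
        or nc_g > params.qc_nocall_max
        or nc_t > params.qc_nocall_max
    )
    return keep, scored


def call_patient(
    table: PairedGenotypeTable,
    sample: str,
    annotation: GenomeAnnotation,
    cnv: list[CNVSegment] | None = None,
    params: CallerParams | None = None,
) -> TractSet:
    """Call LOH tracts for one germline/tissue pairing, per arm.

    Pipeline per arm: CNV stratification -> run scanning -> copy-neutral
    sparsity split (if enabled) -> QC exclusion.  Loci falling in a
    centromeric gap (outside every arm) are ignored.
    """
    if params is None:
        params = CallerParams()
    cnv = cnv or []
    tissue_vec = table.tissue(sample)
    transitions = table.transitions(sample)
    pos_all = table.loci["pos"].to_numpy()
    tracts: list[LOHTract] = []
    for chrom, sl in table.chrom_slices():
        pos_c = pos_all[sl]
        tr_c = transitions[sl]
        g_c = table.germline[sl]
        t_c = tissue_vec[sl]
        for arm_def in annotation.arms_for(chrom):
            lo = np.searchsorted(pos_c, arm_def.start, side="left")
            hi = np.searchsorted(pos_c, arm_def.end, side="right")
            if hi <= lo:
                continue
            pos_a = pos_c[lo:hi]
            tr_a = tr_c[lo:hi]
            blocks = stratify_by_cnv(pos_a, chrom, cnv, params, sample=sample)
            arm_tracts: list[LOHTract] = []
            for state, idx in blocks:
                arm_tracts.extend(
                    scan_tracts(
                        pos_a[idx],
                        tr_a[idx],
                        params.min_events,
                        chrom=chrom,
                        arm=arm_def.arm,
                        copy_state=state,
                        patient=table.patient,
                        sample=sample,
                    )
                )
            if params.apply_sparsity_split:
                arm_tracts = split_sparse(arm_tracts, params)
            for t in arm_tracts:
                keep, scored = qc_filter(
                    t, pos_a, tr_a, g_c[lo:hi], t_c[lo:hi], params
                )
                if keep:
                    tracts.append(scored)
    return TractSet(patient=table.patient, sample=sample, tracts=tracts, params=params)
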