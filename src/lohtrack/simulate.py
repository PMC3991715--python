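"""Synthetic paired-genotype cohorts with known LOH truth.

Generates germline/Td/Tt genotype tables over a toy multi-chromosome genome,
with planted LOH tracts and full truth records, so every pipeline stage can
be tested end to end without controlled-access data.  The generator emulates:

* marker panels drawn as a Poisson process (exponential inter-marker
  spacing), germline heterozygosity at a configurable rate;
* per-sample no-call noise (defaults 0.44% blood, 1.65% tissue) and
  monoallelic / biallelic mutation noise at low rates;
* planted Td tracts with arm-specific weights and log-uniform lengths,
  mostly copy-neutral; non-neutral tracts come with a matching CNV segment;
* a Td->Tt inheritance model: each Td tract recurs in Tt with probability
  ``inherit_prob`` and is extended at each end by an independent geometric
  draw (so Equal and single-/double-end extension patterns arise with
  computable probabilities), plus independent Tt tracts;
* T-stage cohort structure with stage-specific burden multipliers.

It does not model linkage disequilibrium, allele-frequency spectra,
subclonality, or read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calling import TractSet
from .genome import (
    ArmDefinition,
    CNVSegment,
    GeneRegion,
    GenomeAnnotation,
    Genotype,
    PairedGenotypeTable,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_annotation",
    "simulate_patient",
    "simulate_cohort",
    "match_truth",
]

_STAGES = ("T1", "T2", "T3&4")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Lengths are bp; rates are fractions in [0, 1].  No-call defaults are the
    platform averages for blood and solid-tissue samples; the remaining
    defaults are desk-scale choices documented in the methods note.
    """

    # genome
    n_chromosomes: int = 6
    p_arm_bp: int = 30_000_000
    q_arm_bp: int = 40_000_000
    centromere_gap_bp: int = 4_000_000
    # marker panel
    mean_marker_spacing_bp: float = 2_000.0
    germline_het_rate: float = 0.33
    # noise
    nocall_rate_blood: float = 0.0044
    nocall_rate_tissue: float = 0.0165
    monoallelic_rate: float = 0.002
    biallelic_rate: float = 0.0005
    # planted Td tracts
    n_td_tracts: int = 40
    tract_length_bounds: tuple[int, int] = (20_000, 2_000_000)
    arm_weights: dict[str, float] | None = None
    td_state_probs: tuple[float, float, float] = (0.99, 0.005, 0.005)
    # Td -> Tt inheritance
    inherit_prob: float = 2.0 / 3.0
    extension_prob: float = 0.3
    extension_mean_bp: float = 100_000.0
    n_independent_tt: int = 80
    # background CNV
    n_cnv_segments: int = 5
    cnv_length_bounds: tuple[int, int] = (200_000, 2_000_000)
    # genes
    gene_length_bp: int = 150_000
    gene_spacing_bp: int = 600_000
    fragile_fraction: float = 0.084
    census_fraction: float = 0.019
    # cohort
    n_patients: int = 12
    stage_fractions: tuple[float, float, float] = (0.27, 0.62, 0.11)
    stage_multipliers: tuple[float, float, float] = (1.0, 2.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "germline_het_rate", "nocall_rate_blood", "nocall_rate_tissue",
            "monoallelic_rate", "biallelic_rate", "inherit_prob",
            "extension_prob", "fragile_fraction", "census_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_marker_spacing_bp <= 0:
            raise ValueError("mean_marker_spacing_bp must be positive")
        if self.tract_length_bounds[0] < 1 or (
            self.tract_length_bounds[0] > self.tract_length_bounds[1]
        ):
            raise ValueError("invalid tract_length_bounds")
        if abs(sum(self.td_state_probs) - 1.0) > 1e-9:
            raise ValueError("td_state_probs must sum to 1")


@dataclass
class TruthSet:
    """Planted-tract truth for one patient.

    ``td``/``tt`` frames carry tract_id, chrom, arm, start, end, copy_state
    (tt also origin and parent_ids).  ``links`` records per inherited Tt
    tract the parent Td tract and the per-end extensions in bp.
    """

    td: pd.DataFrame
    tt: pd.DataFrame
    links: pd.DataFrame
    arm_weights: pd.Series
    inherit_prob: float

    @property
    def inherited_fraction(self) -> float:
        """Fraction of Td truth tracts with an inherited Tt partner."""
        if len(self.td) == 0:
            return float("nan")
        inherited_parents: set[int] = set()
        for ids in self.links["parent_id"]:
            inherited_parents.add(int(ids))
        return len(inherited_parents) / len(self.td)


def simulate_annotation(
    config: SimulationConfig, seed: int | None = None
) -> GenomeAnnotation:
    """Toy genome: p/q arms separated by a centromeric gap, genes tiled
    within arms, with configurable fractions flagged fragile-site /
    cancer-census."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arms: list[ArmDefinition] = []
    for c in range(1, config.n_chromosomes + 1):
        p_end = config.p_arm_bp
        q_start = p_end + config.centromere_gap_bp + 1
        q_end = q_start + config.q_arm_bp - 1
        arms.append(ArmDefinition(c, "p", 1, p_end, centromere_boundary=p_end))
        arms.append(ArmDefinition(c, "q", q_start, q_end, centromere_boundary=q_start))
    genes: list[GeneRegion] = []
    for arm in arms:
        k = 0
        pos = arm.start
        while pos + config.gene_length_bp - 1 <= arm.end:
            genes.append(
                GeneRegion(
                    name=f"G{arm.name}_{k:03d}",
                    chrom=arm.chrom,
                    start=pos,
                    end=pos + config.gene_length_bp - 1,
                )
            )
            k += 1
            pos += config.gene_spacing_bp
    n = len(genes)
    n_fragile = int(round(config.fragile_fraction * n))
    n_census = int(round(config.census_fraction * n))
    fragile_idx = set(rng.choice(n, size=n_fragile, replace=False).tolist())
    census_idx = set(rng.choice(n, size=n_census, replace=False).tolist())
    genes = [
        replace(
            g,
            is_fragile_site_collocated=i in fragile_idx,
            is_cancer_census=i in census_idx,
        )
        for i, g in enumerate(genes)
    ]
    return GenomeAnnotation(arms=arms, genes=genes)


def _merge_planted(rows: list[dict]) -> list[dict]:
    """Union-merge overlapping planted tracts within one sample.

    Merged rows keep the first member's copy state and concatenate ids.
    """
    rows = sorted(rows, key=lambda r: (r["chrom"], r["start"]))
    merged: list[dict] = []
    for r in rows:
        if (
            merged
            and r["chrom"] == merged[-1]["chrom"]
            and r["arm"] == merged[-1]["arm"]
            and r["start"] <= merged[-1]["end"] + 1
        ):
            last = merged[-1]
            last["end"] = max(last["end"], r["end"])
            last["member_ids"] = last["member_ids"] + r["member_ids"]
        else:
            merged.append(dict(r))
    return merged


def _merge_unresolvable(
    rows: list[dict], chrom: np.ndarray, het_pos_sorted_by_chrom: dict[int, np.ndarray]
) -> list[dict]:
    """Merge planted tracts with no informative marker between them.

    Two tracts whose separating gap contains no germline-HET locus cannot be
    distinguished by any marker-based caller; truth treats them as one.
    """
    out: list[dict] = []
    for r in sorted(rows, key=lambda r: (r["chrom"], r["start"])):
        if out and r["chrom"] == out[-1]["chrom"] and r["arm"] == out[-1]["arm"]:
            last = out[-1]
            hp = het_pos_sorted_by_chrom.get(int(r["chrom"]))
            n_between = 0
            if hp is not None:
                lo = np.searchsorted(hp, last["end"], side="right")
                hi = np.searchsorted(hp, r["start"], side="left")
                n_between = int(hi - lo)
            if r["start"] <= last["end"] + 1 or n_between == 0:
                last["end"] = max(last["end"], r["end"])
                last["member_ids"] = last["member_ids"] + r["member_ids"]
                continue
        out.append(dict(r))
    return out


def _draw_tracts(
    rng: np.random.Generator,
    count: int,
    arms: list[ArmDefinition],
    weights: np.ndarray,
    length_bounds: tuple[int, int],
    state_probs: tuple[float, float, float] | None,
) -> list[dict]:
    lo, hi = length_bounds
    out = []
    if count == 0:
        return out
    arm_idx = rng.choice(len(arms), size=count, p=weights)
    lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=count)
    ).astype(np.int64)
    states = (
        rng.choice(["neutral", "loss", "gain"], size=count, p=state_probs)
        if state_probs is not None
        else np.full(count, "neutral")
    )
    for i in range(count):
        arm = arms[int(arm_idx[i])]
        L = int(min(lengths[i], arm.length))
        start = int(rng.integers(arm.start, arm.end - L + 2))
        out.append(
            {
                "chrom": arm.chrom,
                "arm": arm.arm,
                "start": start,
                "end": start + L - 1,
                "copy_state": str(states[i]),
                "member_ids": [i],
            }
        )
    return out


def _geometric_bp(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric extension lengths on {0, 1, 2, ...} with the given mean."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(1.0 / (mean + 1.0), size=size).astype(np.int64) - 1


def simulate_patient(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    seed: int | np.random.Generator = 0,
    patient: str = "P0",
    stage_multiplier: float = 1.0,
    arm_weights: pd.Series | None = None,
) -> tuple[PairedGenotypeTable, list[CNVSegment], TruthSet]:
    """One patient: germline + Td + Tt genotype vectors, CNV calls, truth.

    Inside each planted tract, germline-heterozygous loci become homozygous
    in the tissue (allele chosen uniformly per locus); noise is injected
    afterwards.  Overlapping planted tracts are merged in truth.  Every
    non-neutral planted tract emits a covering CNV segment for its sample;
    additional background segments are placed away from planted tracts.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arms = annotation.arms
    if arm_weights is None and config.arm_weights is not None:
        arm_weights = pd.Series(config.arm_weights)
    if arm_weights is None:
        w = np.ones(len(arms))
    else:
        w = np.array([arm_weights.get(a.name, 1.0) for a in arms], dtype=float)
    w = w / w.sum()

    # --- marker panel, per arm, exponential spacings
    chrom_arr: list[np.ndarray] = []
    pos_arr: list[np.ndarray] = []
    for arm in arms:
        m = int(arm.length / config.mean_marker_spacing_bp * 1.4) + 20
        spacings = np.ceil(
            rng.exponential(config.mean_marker_spacing_bp, size=m)
        ).astype(np.int64)
        pos = arm.start - 1 + np.cumsum(spacings)
        pos = pos[pos <= arm.end]
        pos_arr.append(pos)
        chrom_arr.append(np.full(pos.size, arm.chrom, dtype=np.int64))
    chrom = np.concatenate(chrom_arr)
    pos = np.concatenate(pos_arr)
    n = pos.size

    # --- germline
    germline = np.full(n, Genotype.AA, dtype=np.uint8)
    u = rng.random(n)
    het = u < config.germline_het_rate
    germline[het] = Genotype.AB
    hom_b = (~het) & (rng.random(n) < 0.5)
    germline[hom_b] = Genotype.BB

    het_by_chrom = {
        int(c): pos[(chrom == c) & het] for c in np.unique(chrom)
    }

    # --- planted Td tracts (pre-merge ids 0..count-1)
    count_td = int(round(config.n_td_tracts * stage_multiplier))
    td_rows = _draw_tracts(
        rng, count_td, arms, w, config.tract_length_bounds, config.td_state_probs
    )
    td_merged = _merge_unresolvable(_merge_planted(td_rows), chrom, het_by_chrom)
    for tid, r in enumerate(td_merged):
        r["tract_id"] = tid

    # --- Tt: inheritance with per-end geometric extension + independents
    tt_rows: list[dict] = []
    links: list[dict] = []
    n_td = len(td_merged)
    inherit = rng.random(n_td) < config.inherit_prob
    # each end extends with probability extension_prob, by a geometric draw
    ext_l = np.where(
        rng.random(n_td) < config.extension_prob,
        _geometric_bp(rng, config.extension_mean_bp, n_td),
        0,
    )
    ext_r = np.where(
        rng.random(n_td) < config.extension_prob,
        _geometric_bp(rng, config.extension_mean_bp, n_td),
        0,
    )
    for i, r in enumerate(td_merged):
        if not inherit[i]:
            continue
        arm = annotation.arm_by_name(f"{r['chrom']}{r['arm']}")
        start = max(arm.start, r["start"] - int(ext_l[i]))
        end = min(arm.end, r["end"] + int(ext_r[i]))
        tt_rows.append(
            {
                "chrom": r["chrom"],
                "arm": r["arm"],
                "start": start,
                "end": end,
                "copy_state": r["copy_state"],
                "member_ids": [f"td{r['tract_id']}"],
            }
        )
        links.append(
            {
                "parent_id": r["tract_id"],
                "ext_left_bp": int(r["start"] - start),
                "ext_right_bp": int(end - r["end"]),
            }
        )
    count_ind = int(round(config.n_independent_tt * stage_multiplier))
    for j, r in enumerate(
        _draw_tracts(
            rng, count_ind, arms, w, config.tract_length_bounds,
            config.td_state_probs,
        )
    ):
        r["member_ids"] = [f"ind{j}"]
        tt_rows.append(r)
    tt_merged = _merge_unresolvable(_merge_planted(tt_rows), chrom, het_by_chrom)
    for tid, r in enumerate(tt_merged):
        r["tract_id"] = tid
        members = r["member_ids"]
        inherited = any(str(m).startswith("td") for m in members)
        r["origin"] = "inherited" if inherited else "independent"
        r["parent_ids"] = ",".join(str(m) for m in members)

    # --- tissue genotype vectors
    chrom_bounds = {
        int(c): (
            int(np.searchsorted(chrom, c, side="left")),
            int(np.searchsorted(chrom, c, side="right")),
        )
        for c in np.unique(chrom)
    }

    def _loci_in(r: dict) -> slice:
        lo, hi = chrom_bounds[int(r["chrom"])]
        a = lo + int(np.searchsorted(pos[lo:hi], r["start"], side="left"))
        b = lo + int(np.searchsorted(pos[lo:hi], r["end"], side="right"))
        return slice(a, b)

    def _make_tissue(truth_rows: list[dict]) -> np.ndarray:
        vec = germline.copy()
        for r in truth_rows:
            sl = _loci_in(r)
            het_idx = np.flatnonzero(het[sl]) + sl.start
            alleles = np.where(
                rng.random(het_idx.size) < 0.5, Genotype.AA, Genotype.BB
            ).astype(np.uint8)
            vec[het_idx] = alleles
        # mutation noise on germline-homozygous loci
        hom = ~het
        u2 = rng.random(n)
        mono = hom & (u2 < config.monoallelic_rate)
        bi = hom & (u2 >= config.monoallelic_rate) & (
            u2 < config.monoallelic_rate + config.biallelic_rate
        )
        vec[mono] = Genotype.AB
        flip = np.where(
            germline[bi] == Genotype.AA, Genotype.BB, Genotype.AA
        ).astype(np.uint8)
        vec[bi] = flip
        vec[rng.random(n) < config.nocall_rate_tissue] = Genotype.NOCALL
        return vec

    td_vec = _make_tissue(td_merged)
    tt_vec = _make_tissue(tt_merged)
    germline_out = germline.copy()
    germline_out[rng.random(n) < config.nocall_rate_blood] = Genotype.NOCALL

    # --- CNV segments: one per non-neutral planted tract + background
    cnv: list[CNVSegment] = []
    for sample, truth_rows in (("Td", td_merged), ("Tt", tt_merged)):
        placed: list[tuple[int, int, int]] = []
        for r in truth_rows:
            if r["copy_state"] == "neutral":
                continue
            cnv.append(
                CNVSegment(r["chrom"], r["start"], r["end"], r["copy_state"], sample)
            )
            placed.append((r["chrom"], r["start"], r["end"]))
        forbidden = placed + [
            (r["chrom"], r["start"], r["end"]) for r in truth_rows
        ]
        lo_len, hi_len = config.cnv_length_bounds
        for _ in range(config.n_cnv_segments):
            for _attempt in range(10):
                arm = arms[int(rng.integers(len(arms)))]
                L = int(rng.integers(lo_len, hi_len + 1))
                L = min(L, arm.length)
                s = int(rng.integers(arm.start, arm.end - L + 2))
                e = s + L - 1
                clash = any(
                    c == arm.chrom and s <= fe and e >= fs
                    for c, fs, fe in forbidden
                )
                if not clash:
                    state = "loss" if rng.random() < 0.5 else "gain"
                    cnv.append(CNVSegment(arm.chrom, s, e, state, sample))
                    forbidden.append((arm.chrom, s, e))
                    break

    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "variant_id": [f"v{i}" for i in range(n)],
            "vtype": "SNP",
        }
    )
    table = PairedGenotypeTable(
        patient=patient,
        loci=loci,
        germline=germline_out,
        tissues={"Td": td_vec, "Tt": tt_vec},
    )
    cols = ["tract_id", "chrom", "arm", "start", "end", "copy_state"]
    td_df = pd.DataFrame(td_merged)[cols] if td_merged else pd.DataFrame(columns=cols)
    tt_cols = cols + ["origin", "parent_ids"]
    tt_df = (
        pd.DataFrame(tt_merged)[tt_cols] if tt_merged else pd.DataFrame(columns=tt_cols)
    )
    links_df = pd.DataFrame(
        links, columns=["parent_id", "ext_left_bp", "ext_right_bp"]
    )
    truth = TruthSet(
        td=td_df,
        tt=tt_df,
        links=links_df,
        arm_weights=pd.Series(w, index=[a.name for a in arms]),
        inherit_prob=config.inherit_prob,
    )
    return table, cnv, truth


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> dict:
    """A T-stage-stratified cohort sharing one annotation and arm weights.

    Returns ``{"annotation": ..., "patients": [records]}`` where each record
    has patient id, stage, genotype table, CNV calls and truth.  Stage
    burden multipliers scale planted tract counts.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ann_seed, *patient_seeds = root.spawn(config.n_patients + 1)
    annotation = simulate_annotation(
        config, seed=int(ann_seed.generate_state(1)[0] % (2**31))
    )
    # largest-remainder apportionment of patients to stages
    n = config.n_patients
    raw = np.array(config.stage_fractions, dtype=float)
    raw = raw / raw.sum() * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    stages = [s for s, c in zip(_STAGES, counts) for _ in range(c)]
    weights = (
        pd.Series(config.arm_weights)
        if config.arm_weights is not None
        else None
    )
    patients = []
    for i, (stage, pseed) in enumerate(zip(stages, patient_seeds)):
        mult = config.stage_multipliers[_STAGES.index(stage)]
        pid = f"SYN-{i:03d}"
        table, cnv, truth = simulate_patient(
            config,
            annotation,
            seed=np.random.default_rng(pseed),
            patient=pid,
            stage_multiplier=mult,
            arm_weights=weights,
        )
        patients.append(
            {
                "patient": pid,
                "stage": stage,
                "table": table,
                "cnv": cnv,
                "truth": truth,
            }
        )
    return {"annotation": annotation, "patients": patients}


def match_truth(
    called: TractSet,
    truth_df: pd.DataFrame,
    het_chrom: np.ndarray,
    het_pos: np.ndarray,
    min_events: int = 2,
) -> dict:
    """Compare called tracts against planted truth.

    A truth tract is *callable* when it contains >= ``min_events``
    germline-HET loci; it is *recovered* when exactly one called tract lies
    within it covering all of its informative loci.  Called tracts inside no
    truth tract are false positives.  Boundary error is the bp offset of a
    called edge from its truth edge; ``boundary_gap`` is the local spacing
    between the informative markers flanking that truth edge (the resolution
    limit of any marker-based caller).
    """
    het_pos_by_chrom: dict[int, np.ndarray] = {}
    for c in np.unique(het_chrom):
        het_pos_by_chrom[int(c)] = het_pos[het_chrom == c]
    records = []
    fp = []
    assigned: dict[int, list] = {i: [] for i in truth_df.index}
    for t in called:
        hit = None
        for i, row in truth_df.iterrows():
            if (
                t.chrom == row["chrom"]
                and t.start >= row["start"]
                and t.end <= row["end"]
            ):
                hit = i
                break
        if hit is None:
            fp.append(t)
        else:
            assigned[hit].append(t)
    n_callable = n_recovered = 0
    for i, row in truth_df.iterrows():
        hp = het_pos_by_chrom.get(int(row["chrom"]), np.array([], dtype=np.int64))
        lo = int(np.searchsorted(hp, row["start"], side="left"))
        hi = int(np.searchsorted(hp, row["end"], side="right"))
        n_inf = hi - lo
        callable_ = n_inf >= min_events
        hits = assigned[i]
        recovered = False
        err_left = err_right = gap_left = gap_right = None
        if callable_:
            n_callable += 1
            if len(hits) == 1:
                t = hits[0]
                covers = t.start <= hp[lo] and t.end >= hp[hi - 1]
                recovered = covers
                err_left = int(t.start - row["start"])
                err_right = int(row["end"] - t.end)
                gap_left = int(hp[lo] - hp[lo - 1]) if lo > 0 else None
                gap_right = int(hp[hi] - hp[hi - 1]) if hi < hp.size else None
            if recovered:
                n_recovered += 1
        records.append(
            {
                "truth_id": i,
                "n_informative": n_inf,
                "callable": callable_,
                "n_called_within": len(hits),
                "recovered": recovered,
                "err_left": err_left,
                "err_right": err_right,
                "gap_left": gap_left,
                "gap_right": gap_right,
            }
        )
    return {
        "per_truth": pd.DataFrame(records),
        "false_positives": fp,
        "n_callable": n_callable,
        "n_recovered": n_recovered,
    }
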