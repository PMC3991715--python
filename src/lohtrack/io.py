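"""Readers and writers for the on-disk formats, plus ingest QC.

Formats:

* genotype TSV — header ``chrom  pos  variant_id  [vtype]`` then one column
  per sample with values in {AA, AB, BB, NC}; 1-based positions, sorted.
* VCF — biallelic diploid records; GT 0/0 -> AA, 0/1 or 1/0 -> AB,
  1/1 -> BB, missing -> NC.  Multi-allelic, non-diploid and non-autosomal
  records are skipped (counts logged).
* CNV BED-like TSV — ``chrom  start  end  state  sample`` with 0-based
  half-open coordinates.
* arm table TSV — ``chrom  arm  start  end  centromere_boundary`` (1-based
  inclusive); genes as BED4 plus per-line membership lists.
* tract TSV (1-based inclusive) and optional BED6 export.

Chromosome names are normalised by stripping a leading "chr"; everything
internal is 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import CallerParams, LOHTract, TractSet
from .genome import (
    ArmDefinition,
    CNVSegment,
    GeneRegion,
    GenomeAnnotation,
    Genotype,
    PairedGenotypeTable,
    dedupe_genes,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "read_arm_table",
    "write_arm_table",
    "read_genes_bed",
    "read_cnv_bed",
    "write_cnv_bed",
    "read_tracts",
    "write_tracts",
    "tracts_to_bed",
    "ingest_qc",
    "RunConfig",
    "write_provenance",
]

logger = logging.getLogger(__name__)

_CODE_OF = {"AA": 0, "AB": 1, "BB": 2, "NC": 3}
_NAME_OF = {v: k for k, v in _CODE_OF.items()}


def _norm_chrom(value) -> int:
    s = str(value)
    if s.lower().startswith("chr"):
        s = s[3:]
    return int(s)  # autosomes only: non-numeric names raise


def read_genotypes(
    path, patient: str, germline: str = "G", tissues: list[str] | None = None
) -> PairedGenotypeTable:
    """Read a genotype TSV into a paired table.

    ``germline`` names the germline column; ``tissues`` selects tissue
    columns (default: every non-locus column except the germline one).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    locus_cols = [c for c in ("chrom", "pos", "variant_id", "vtype") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in locus_cols]
    if germline not in sample_cols:
        raise KeyError(f"germline column {germline!r} not found in {path}")
    if tissues is None:
        tissues = [c for c in sample_cols if c != germline]
    df["chrom"] = df["chrom"].map(_norm_chrom)

    def encode(col: str) -> np.ndarray:
        vals = df[col].astype(str)
        bad = ~vals.isin(_CODE_OF)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: invalid genotype {vals.iloc[row]!r} "
                f"in column {col!r} at data row {row + 1}"
            )
        return vals.map(_CODE_OF).to_numpy(dtype=np.uint8)

    loci = df[locus_cols].copy()
    return PairedGenotypeTable(
        patient=patient,
        loci=loci,
        germline=encode(germline),
        tissues={t: encode(t) for t in tissues},
    )


def write_genotypes(table: PairedGenotypeTable, path, germline_label: str = "G") -> None:
    df = table.loci.copy()
    df[germline_label] = [_NAME_OF[int(v)] for v in table.germline]
    for label, vec in table.tissues.items():
        df[label] = [_NAME_OF[int(v)] for v in vec]
    df.to_csv(path, sep="\t", index=False)


def read_vcf(
    path, patient: str, germline: str, tissues: list[str]
) -> PairedGenotypeTable:
    """Read biallelic diploid genotypes from a VCF.

    Skips multi-allelic, non-diploid and non-autosomal records, logging the
    skip counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = [germline] + list(tissues)
    for s in wanted:
        if s not in samples:
            raise KeyError(f"sample {s!r} not in VCF (have {samples})")
    idx = [samples.index(s) for s in wanted]
    rows = []
    calls: list[list[int]] = []
    skipped = {"multiallelic": 0, "non_diploid": 0, "non_autosomal": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        try:
            c = _norm_chrom(rec.CHROM)
        except ValueError:
            skipped["non_autosomal"] += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        row_calls = []
        ok = True
        for i in idx:
            g = gts[i]
            if len(g) != 3:
                ok = False
                break
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row_calls.append(_CODE_OF["NC"])
            else:
                row_calls.append({0: 0, 1: 1, 2: 2}[a + b])
        if not ok:
            skipped["non_diploid"] += 1
            continue
        vid = rec.ID or f"{c}:{rec.POS}"
        vtype = "SNP" if rec.is_snp else "INDEL"
        rows.append((c, rec.POS, vid, vtype))
        calls.append(row_calls)
    if any(skipped.values()):
        logger.info("VCF ingest skipped records: %s", skipped)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id", "vtype"])
    mat = np.array(calls, dtype=np.uint8).reshape(len(rows), len(wanted))
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    mat = mat[order]
    return PairedGenotypeTable(
        patient=patient,
        loci=loci,
        germline=mat[:, 0],
        tissues={t: mat[:, 1 + i] for i, t in enumerate(tissues)},
    )


def ingest_qc(
    tables: list[PairedGenotypeTable],
    min_call_rate: float = 0.95,
    max_nocalls: int | None = 2,
) -> tuple[list[PairedGenotypeTable], dict]:
    """Variant-level ingest filters, computed cohort-wide.

    Variants with a call rate below ``min_call_rate`` across all sample
    vectors of all tables are removed, as are variants with more than
    ``max_nocalls`` no-calls across those vectors (set ``max_nocalls=None``
    to disable).  All tables must share a locus panel.  Returns filtered
    tables plus a report of removals by reason.
    """
    if not tables:
        raise ValueError("no tables supplied")
    ref = tables[0].loci[["chrom", "pos"]].to_numpy()
    for t in tables[1:]:
        if t.n_loci != tables[0].n_loci or not np.array_equal(
            t.loci[["chrom", "pos"]].to_numpy(), ref
        ):
            raise ValueError("ingest_qc requires a shared locus panel")
    vecs = []
    for t in tables:
        vecs.append(t.germline)
        vecs.extend(t.tissues[s] for s in t.sample_labels)
    mat = np.stack(vecs)  # samples x loci
    nocalls = (mat == Genotype.NOCALL).sum(axis=0)
    n_samples = mat.shape[0]
    call_rate = 1.0 - nocalls / n_samples
    low_rate = call_rate < min_call_rate
    too_many = (
        nocalls > max_nocalls if max_nocalls is not None else np.zeros_like(low_rate)
    )
    drop = low_rate | too_many
    keep = ~drop
    report = {
        "n_input": int(mat.shape[1]),
        "n_removed": int(drop.sum()),
        "n_low_call_rate": int(low_rate.sum()),
        "n_excess_nocalls": int(too_many.sum()),
        "min_call_rate": min_call_rate,
        "max_nocalls": max_nocalls,
        "n_samples": n_samples,
    }
    out = []
    for t in tables:
        out.append(
            PairedGenotypeTable(
                patient=t.patient,
                loci=t.loci.loc[keep].reset_index(drop=True),
                germline=t.germline[keep],
                tissues={s: t.tissues[s][keep] for s in t.sample_labels},
            )
        )
    return out, report


# --- annotation ---------------------------------------------------------


def read_arm_table(path) -> list[ArmDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        ArmDefinition(
            chrom=_norm_chrom(r.chrom),
            arm=str(r.arm),
            start=int(r.start),
            end=int(r.end),
            centromere_boundary=int(r.centromere_boundary),
        )
        for r in df.itertuples()
    ]


def write_arm_table(arms: list[ArmDefinition], path) -> None:
    pd.DataFrame(
        [
            (a.chrom, a.arm, a.start, a.end, a.centromere_boundary)
            for a in arms
        ],
        columns=["chrom", "arm", "start", "end", "centromere_boundary"],
    ).to_csv(path, sep="\t", index=False)


def read_genes_bed(
    path, fragile_list=None, census_list=None
) -> list[GeneRegion]:
    """BED4 gene regions plus optional membership lists (one symbol/line).

    Duplicate names resolve to the longest entry.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    fragile = set()
    census = set()
    if fragile_list:
        fragile = {l.strip() for l in Path(fragile_list).read_text().splitlines() if l.strip()}
    if census_list:
        census = {l.strip() for l in Path(census_list).read_text().splitlines() if l.strip()}
    genes = [
        GeneRegion(
            name=str(r.name),
            chrom=_norm_chrom(r.chrom),
            start=int(r.start) + 1,  # BED 0-based half-open -> 1-based inclusive
            end=int(r.end),
            is_fragile_site_collocated=str(r.name) in fragile,
            is_cancer_census=str(r.name) in census,
        )
        for r in df.itertuples()
    ]
    return dedupe_genes(genes)


def write_genes_bed(genes: list[GeneRegion], path) -> None:
    pd.DataFrame(
        [(g.chrom, g.start - 1, g.end, g.name) for g in genes]
    ).to_csv(path, sep="\t", index=False, header=False)


def read_cnv_bed(path) -> list[CNVSegment]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "state", "sample"],
    )
    return [
        CNVSegment(
            chrom=_norm_chrom(r.chrom),
            start=int(r.start) + 1,
            end=int(r.end),
            state=str(r.state),
            sample=str(r.sample),
        )
        for r in df.itertuples()
    ]


def write_cnv_bed(segments: list[CNVSegment], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start - 1, s.end, s.state, s.sample) for s in segments]
    ).to_csv(path, sep="\t", index=False, header=False)


# --- tracts -------------------------------------------------------------

_TRACT_COLS = [
    "chrom", "start", "end", "arm", "n_events", "copy_state", "length",
    "qc_monoallelic", "qc_nocall_germline", "qc_nocall_tissue", "patient",
    "sample",
]


def write_tracts(tracts: TractSet, path) -> None:
    """Tract TSV, 1-based inclusive, deterministic column order and float
    format.  Empty sets still produce a headers-only file."""
    df = tracts.to_frame()[_TRACT_COLS] if len(tracts) else pd.DataFrame(
        columns=_TRACT_COLS
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tracts(path, params: CallerParams | None = None) -> TractSet:
    df = pd.read_csv(path, sep="\t")
    tracts = [
        LOHTract(
            chrom=_norm_chrom(r.chrom),
            arm=str(r.arm),
            start=int(r.start),
            end=int(r.end),
            n_events=int(r.n_events),
            copy_state=str(r.copy_state),
            qc_monoallelic=float(r.qc_monoallelic),
            qc_nocall_germline=float(r.qc_nocall_germline),
            qc_nocall_tissue=float(r.qc_nocall_tissue),
            patient=str(r.patient),
            sample=str(r.sample),
        )
        for r in df.itertuples()
    ]
    patient = tracts[0].patient if tracts else ""
    sample = tracts[0].sample if tracts else ""
    return TractSet(patient=patient, sample=sample, tracts=tracts, params=params)


def tracts_to_bed(tracts: TractSet, path) -> None:
    """BED6 export: name = copy state, score = event count."""
    rows = [
        (t.chrom, t.start - 1, t.end, t.copy_state, t.n_events, "+")
        for t in tracts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# --- run configuration and provenance -----------------------------------


@dataclass
class RunConfig:
    """Flat run configuration mirroring caller/permutation/enrichment knobs."""

    min_events: int = 2
    gap_threshold_bp: int = 40_000
    apply_sparsity_split: bool = True
    qc_monoallelic_max: float = 0.20
    qc_nocall_max: float = 0.20
    cnv_min_length_bp: int = 0
    n_perm: int = 5000
    centromere_exclusion_bp: int = 3_000_000
    arm_end_exclusion_bp: int = 10_000
    min_call_rate: float = 0.95
    max_nocalls: int = 2
    top_gene_min_patients: int = 6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_events=self.min_events,
            gap_threshold_bp=self.gap_threshold_bp,
            apply_sparsity_split=self.apply_sparsity_split,
            qc_monoallelic_max=self.qc_monoallelic_max,
            qc_nocall_max=self.qc_nocall_max,
            cnv_min_length_bp=self.cnv_min_length_bp,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_provenance(out_dir, config: dict, seed: int, inputs: list) -> Path:
    """Sidecar recording the effective config, seed, input digests, version."""
    from . import __version__

    out = Path(out_dir) / "provenance.json"
    payload = {
        "tool": "lohtrack",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
    }
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out
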