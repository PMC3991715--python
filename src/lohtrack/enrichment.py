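"""Arm-level LOH burden profiles and gene-level concurrence/enrichment.

Arm profiles express each sample's LOH burden as total tract length per arm
divided by arm length, making arms of different sizes comparable; cohorts can
be stratified (e.g. by tumor T stage) and two mean profiles correlated
(Pearson).  Gene-level analysis counts, per gene, the patients whose low- and
high-stage samples both carry a stringent (>=2-event) tract in the gene
region, with and without requiring the two tracts to overlap inside the gene,
over the denominator of informative patients (>=1 germline HET locus in the
gene).  Category enrichment among top-concurrence genes uses a df=1
chi-square goodness-of-fit test against a baseline membership proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import LOHTract, TractSet
from .genome import GeneRegion, GenomeAnnotation, PairedGenotypeTable

__all__ = [
    "ArmProfile",
    "EnrichmentResult",
    "arm_profile",
    "cohort_arm_summary",
    "profile_correlation",
    "gene_concurrence_table",
    "category_enrichment",
    "goodness_of_fit",
]


@dataclass
class ArmProfile:
    """Per-arm total tract length and arm-length-adjusted burden.

    ``values`` is indexed by arm name with columns ``total_bp`` and
    ``adjusted`` (total / arm length, dimensionless; bounded by 1 for
    non-overlapping tracts).
    """

    patient: str
    sample: str
    values: pd.DataFrame
    criterion: str = ">=2 events"

    @property
    def adjusted(self) -> pd.Series:
        return self.values["adjusted"]

    @property
    def total_bp(self) -> int:
        return int(self.values["total_bp"].sum())


def arm_profile(tracts: TractSet, annotation: GenomeAnnotation) -> ArmProfile:
    """Sum tract lengths per arm and normalise by arm length.

    Every annotated arm appears (zero where the sample has no tracts); a
    tract not contained in its recorded arm is an input error.
    """
    totals = {a.name: 0 for a in annotation.arms}
    lengths = {a.name: a.length for a in annotation.arms}
    for t in tracts:
        name = t.arm_name
        if name not in totals:
            raise ValueError(f"tract on unannotated arm {name}")
        arm = annotation.arm_by_name(name)
        if t.start < arm.start or t.end > arm.end:
            raise ValueError(
                f"tract {t.chrom}:{t.start}-{t.end} outside arm {name} bounds"
            )
        totals[name] += t.length
    criterion = (
        f">={tracts.params.min_events} events" if tracts.params else ">=2 events"
    )
    df = pd.DataFrame(
        {
            "total_bp": pd.Series(totals),
            "adjusted": pd.Series(
                {k: totals[k] / lengths[k] for k in totals}
            ),
        }
    )
    df.index.name = "arm"
    return ArmProfile(
        patient=tracts.patient, sample=tracts.sample, values=df, criterion=criterion
    )


def cohort_arm_summary(
    profiles: list[ArmProfile], groups: dict[str, str]
) -> pd.DataFrame:
    """Median/Q1/Q3 of adjusted arm burden per (stratum, arm) across patients.

    ``groups`` maps patient id to stratum label (e.g. T1/T2/T3&4).  Patients
    missing from the mapping are skipped; empty strata are omitted with a
    warning.
    """
    rows = []
    for p in profiles:
        stratum = groups.get(p.patient)
        if stratum is None:
            continue
        for arm, adj in p.adjusted.items():
            rows.append({"stratum": stratum, "arm": arm, "adjusted": adj})
    if not rows:
        warnings.warn("no profiles matched any stratum")
        return pd.DataFrame(columns=["median", "q1", "q3"])
    df = pd.DataFrame(rows)
    for stratum in set(groups.values()):
        if stratum not in set(df["stratum"]):
            warnings.warn(f"stratum {stratum!r} has no profiles; omitted")
    out = (
        df.groupby(["stratum", "arm"])["adjusted"]
        .agg(
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
            n="count",
        )
    )
    return out


def mean_profile(profiles: list[ArmProfile]) -> pd.Series:
    """Cohort mean of adjusted arm burdens (index: arm name)."""
    if not profiles:
        raise ValueError("no profiles")
    mat = pd.concat([p.adjusted.rename(p.patient) for p in profiles], axis=1)
    return mat.mean(axis=1)


def profile_correlation(profile_a, profile_b) -> tuple[float, float]:
    """Pearson correlation between two per-arm adjusted profiles.

    Accepts :class:`ArmProfile` objects or per-arm Series; arms are aligned
    by name, and arms undefined on either side are dropped pairwise.  The
    two-sided p-value comes from the t transform with df = #arms - 2.
    """
    a = profile_a.adjusted if isinstance(profile_a, ArmProfile) else profile_a
    b = profile_b.adjusted if isinstance(profile_b, ArmProfile) else profile_b
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 shared arms for a correlation")
    if joined["a"].nunique() == 1 or joined["b"].nunique() == 1:
        raise ValueError("correlation undefined: zero variance in a profile")
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p)


def _tracts_in_gene(tracts: TractSet, gene: GeneRegion) -> list[LOHTract]:
    return [
        t
        for t in tracts
        if t.chrom == gene.chrom and t.start <= gene.end and t.end >= gene.start
    ]


def gene_concurrence_table(
    cohort: dict[str, dict[str, TractSet]],
    annotation: GenomeAnnotation,
    germline_tables: dict[str, PairedGenotypeTable],
) -> pd.DataFrame:
    """Per-gene cross-patient concurrence counts.

    ``cohort`` maps patient id to ``{"low": TractSet, "high": TractSet}``
    called under the stringent criterion.  A patient counts toward a gene's
    ``n_concurrent`` column when both samples carry a tract overlapping the
    gene region (>=1 bp of tract inside the gene; no overlap between the
    tracts required), toward ``n_concurrent_overlap`` when additionally some
    low-tract / high-tract pair shares >=1 bp inside the gene, and toward
    ``n_informative`` when the germline has >=1 HET locus inside the gene.
    Sorted by ``n_concurrent_overlap`` descending.
    """
    from .genome import Genotype

    het_index: dict[str, dict[int, np.ndarray]] = {}
    for pid, table in germline_tables.items():
        het = table.germline_het_mask()
        pos = table.loci["pos"].to_numpy()
        chrom = table.loci["chrom"].to_numpy()
        per_chrom: dict[int, np.ndarray] = {}
        for c in np.unique(chrom):
            mask = (chrom == c) & het
            per_chrom[int(c)] = pos[mask]
        het_index[pid] = per_chrom
    rows = []
    for gene in annotation.genes:
        n_loose = n_strict = n_inf = 0
        for pid, pair in cohort.items():
            low_hits = _tracts_in_gene(pair["low"], gene)
            high_hits = _tracts_in_gene(pair["high"], gene)
            if low_hits and high_hits:
                n_loose += 1
                strict = False
                for lt in low_hits:
                    for ht in high_hits:
                        lo = max(lt.start, ht.start, gene.start)
                        hi = min(lt.end, ht.end, gene.end)
                        if hi - lo + 1 >= 1:
                            strict = True
                            break
                    if strict:
                        break
                if strict:
                    n_strict += 1
            het_pos = het_index.get(pid, {}).get(gene.chrom)
            if het_pos is not None and het_pos.size:
                lo = np.searchsorted(het_pos, gene.start, side="left")
                hi = np.searchsorted(het_pos, gene.end, side="right")
                if hi > lo:
                    n_inf += 1
        rows.append(
            {
                "gene": gene.name,
                "chrom": gene.chrom,
                "start": gene.start,
                "end": gene.end,
                "n_concurrent": n_loose,
                "n_concurrent_overlap": n_strict,
                "n_informative": n_inf,
                "fragile_site": gene.is_fragile_site_collocated,
                "cancer_census": gene.is_cancer_census,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        bad = df["n_concurrent_overlap"] > df["n_concurrent"]
        if bad.any():
            raise AssertionError("overlap count exceeded no-overlap count")
        df = df.sort_values(
            ["n_concurrent_overlap", "n_concurrent", "gene"],
            ascending=[False, False, True],
        ).reset_index(drop=True)
    return df


@dataclass
class EnrichmentResult:
    """Chi-square goodness-of-fit of category membership among top genes."""

    n_top: int
    n_member: int
    observed_prop: float
    baseline_prop: float
    chi2: float
    p_value: float
    baseline_mode: str = ""
    warning: str | None = None


def goodness_of_fit(
    n_member: int, n_total: int, baseline_prop: float, baseline_mode: str = ""
) -> EnrichmentResult:
    """One-sample chi-square (df=1) of an observed membership count against a
    baseline proportion."""
    if not (0.0 < baseline_prop < 1.0):
        raise ValueError("baseline proportion must be in (0, 1)")
    expected = np.array(
        [n_total * baseline_prop, n_total * (1.0 - baseline_prop)]
    )
    observed = np.array([n_member, n_total - n_member], dtype=float)
    chi2, p = stats.chisquare(observed, expected)
    warning = None
    if expected.min() < 1.0:
        warning = "expected count < 1; chi-square approximation unreliable"
    return EnrichmentResult(
        n_top=n_total,
        n_member=n_member,
        observed_prop=n_member / n_total,
        baseline_prop=baseline_prop,
        chi2=float(chi2),
        p_value=float(p),
        baseline_mode=baseline_mode,
        warning=warning,
    )


def category_enrichment(
    gene_table: pd.DataFrame,
    category: str,
    min_patients: int = 6,
    baseline_mode: str = "all_genes",
) -> EnrichmentResult:
    """Test whether a gene category is over-represented among top-concurrence
    genes.

    Top genes have ``n_concurrent_overlap >= min_patients``.  The baseline
    proportion is the category frequency among all genes
    (``baseline_mode="all_genes"``) or among genes with >=1 concurrent
    patient (``"concurrent_genes"``).
    """
    if category not in ("fragile_site", "cancer_census"):
        raise ValueError("category must be fragile_site or cancer_census")
    top = gene_table[gene_table["n_concurrent_overlap"] >= min_patients]
    if baseline_mode == "all_genes":
        base = gene_table
    elif baseline_mode == "concurrent_genes":
        base = gene_table[gene_table["n_concurrent_overlap"] >= 1]
    else:
        raise ValueError("baseline_mode must be all_genes or concurrent_genes")
    if len(top) == 0 or len(base) == 0:
        raise ValueError("no genes in top set or baseline")
    baseline_prop = float(base[category].mean())
    return goodness_of_fit(
        int(top[category].sum()), len(top), baseline_prop, baseline_mode
    )
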