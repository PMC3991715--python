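"""Arm profiles, cohort summaries, gene concurrence, category enrichment."""

import numpy as np
import pandas as pd
import pytest

from lohtrack import (
    ArmDefinition,
    GeneRegion,
    GenomeAnnotation,
    Genotype,
    arm_profile,
    category_enrichment,
    cohort_arm_summary,
    gene_concurrence_table,
    goodness_of_fit,
    profile_correlation,
)
from lohtrack.enrichment import ArmProfile, mean_profile

from util import make_table, oracle_chi2_gof, tract_set

G = Genotype


def small_annotation():
    return GenomeAnnotation(
        arms=[ArmDefinition(1, "p", 1, 1_000, centromere_boundary=1_000)],
        genes=[GeneRegion("GENE1", 1, 100, 300)],
    )


class TestArmProfile:
    def test_total_and_adjusted(self):
        ann = small_annotation()
        ts = tract_set([(1, 100), (201, 300)])
        prof = arm_profile(ts, ann)
        assert prof.values.loc["1p", "total_bp"] == 200
        assert prof.values.loc["1p", "adjusted"] == pytest.approx(0.2)

    def test_empty_set_all_zero(self):
        prof = arm_profile(tract_set([]), small_annotation())
        assert (prof.values["total_bp"] == 0).all()

    def test_totals_conserved(self):
        ann = small_annotation()
        ts = tract_set([(1, 50), (100, 400), (500, 999)])
        prof = arm_profile(ts, ann)
        assert prof.total_bp == ts.total_length

    def test_tract_outside_arm_rejected(self):
        ann = small_annotation()
        ts = tract_set([(900, 2_000)])
        with pytest.raises(ValueError, match="outside arm"):
            arm_profile(ts, ann)


def _profile(patient, values):
    df = pd.DataFrame(
        {"total_bp": [0] * len(values), "adjusted": list(values.values())},
        index=list(values),
    )
    df.index.name = "arm"
    return ArmProfile(patient=patient, sample="Tt", values=df)


class TestCohortSummary:
    def test_identical_profiles_collapse_quartiles(self):
        profiles = [_profile(f"P{i}", {"1p": 0.3}) for i in range(3)]
        out = cohort_arm_summary(profiles, {f"P{i}": "T1" for i in range(3)})
        row = out.loc[("T1", "1p")]
        assert row["median"] == row["q1"] == row["q3"] == pytest.approx(0.3)

    def test_median_of_three(self):
        profiles = [_profile(f"P{i}", {"1p": v}) for i, v in enumerate((1.0, 2.0, 3.0))]
        out = cohort_arm_summary(profiles, {f"P{i}": "T1" for i in range(3)})
        assert out.loc[("T1", "1p"), "median"] == pytest.approx(2.0)

    def test_empty_stratum_warns(self):
        profiles = [_profile("P0", {"1p": 0.1})]
        with pytest.warns(UserWarning, match="T2"):
            cohort_arm_summary(profiles, {"P0": "T1", "P1": "T2"})


class TestProfileCorrelation:
    arms = [f"{c}p" for c in range(1, 9)]

    def test_perfect_positive(self):
        a = pd.Series(np.arange(8, dtype=float) / 10, index=self.arms)
        r, p = profile_correlation(a, 2 * a)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        a = pd.Series(np.arange(8, dtype=float) / 10, index=self.arms)
        r, _ = profile_correlation(a, 0.9 - a)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = pd.Series(np.arange(8, dtype=float), index=self.arms)
        b = pd.Series(np.ones(8), index=self.arms)
        with pytest.raises(ValueError, match="zero variance"):
            profile_correlation(a, b)

    def test_mean_profile_is_arm_wise_average(self):
        p1 = _profile("P1", {"1p": 0.2, "1q": 0.4})
        p2 = _profile("P2", {"1p": 0.4, "1q": 0.0})
        m = mean_profile([p1, p2])
        assert m["1p"] == pytest.approx(0.3)
        assert m["1q"] == pytest.approx(0.2)


class TestGeneConcurrence:
    ann = GenomeAnnotation(
        arms=[ArmDefinition(1, "p", 1, 10_000, centromere_boundary=10_000)],
        genes=[GeneRegion("GENE1", 1, 1_000, 2_000)],
    )

    def _germ(self, het_in_gene=True):
        pos = [1_500] if het_in_gene else [5_000]
        return make_table(pos, [G.AB], [G.AA])

    def _cohort(self, low_iv, high_iv):
        return {
            "P1": {
                "low": tract_set(low_iv, sample="Td"),
                "high": tract_set(high_iv, sample="Tt"),
            }
        }

    def test_overlapping_tracts_count_in_both_columns(self):
        table = gene_concurrence_table(
            self._cohort([(1_500, 1_600)], [(1_550, 1_650)]),
            self.ann,
            {"P1": self._germ()},
        )
        row = table.iloc[0]
        assert row["n_concurrent"] == 1 and row["n_concurrent_overlap"] == 1
        assert row["n_informative"] == 1

    def test_disjoint_tracts_in_gene_loose_only(self):
        table = gene_concurrence_table(
            self._cohort([(1_100, 1_200)], [(1_500, 1_600)]),
            self.ann,
            {"P1": self._germ()},
        )
        row = table.iloc[0]
        assert row["n_concurrent"] == 1 and row["n_concurrent_overlap"] == 0

    def test_no_germline_het_not_informative(self):
        table = gene_concurrence_table(
            self._cohort([(1_500, 1_600)], [(1_550, 1_650)]),
            self.ann,
            {"P1": self._germ(het_in_gene=False)},
        )
        assert table.iloc[0]["n_informative"] == 0

    def test_count_ordering_invariant(self):
        table = gene_concurrence_table(
            self._cohort([(1_500, 1_600)], [(1_550, 1_650)]),
            self.ann,
            {"P1": self._germ()},
        )
        assert (table["n_concurrent_overlap"] <= table["n_concurrent"]).all()


class TestGoodnessOfFit:
    @pytest.mark.parametrize(
        "k,n,p0",
        [(49, 429, 0.084), (12, 429, 0.019), (10, 100, 0.10), (3, 50, 0.02)],
    )
    def test_matches_manual_chi_square(self, k, n, p0):
        res = goodness_of_fit(k, n, p0)
        stat, p = oracle_chi2_gof(k, n, p0)
        assert res.chi2 == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_exact_expectation_gives_p_one(self):
        res = goodness_of_fit(10, 100, 0.10)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_expected_count_warned(self):
        res = goodness_of_fit(1, 20, 0.01)
        assert res.warning is not None

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(1, 10, 0.0)

    def test_category_enrichment_from_table(self):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "n_concurrent_overlap": [8] * 5 + [1] * 10 + [0] * 5,
                "fragile_site": [True, True, False, False, False] + [True] * 2 + [False] * 13,
                "cancer_census": [False] * 20,
            }
        )
        res = category_enrichment(table, "fragile_site", min_patients=6)
        assert res.n_top == 5 and res.n_member == 2
        assert res.baseline_prop == pytest.approx(4 / 20)
        stat, p = oracle_chi2_gof(2, 5, 0.2)
        assert res.chi2 == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)
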