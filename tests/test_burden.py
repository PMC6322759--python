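from fractions import Fraction
from math import comb

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from cardioburden.burden import (
    BurdenTable,
    CarrierSummary,
    TableUnit,
    carrier_burden_test,
    cohort_maf,
    compare_demographics,
    expected_reference_carriers,
    fisher_exact_two_sided,
    ga_chi2_test,
    gene_allele_burden,
    sex_fisher_test,
    summarize_carriers,
    variant_maf_test,
)
from cardioburden.io import ReferencePopulation, VariantKey, Zygosity
from cardioburden.panel import Category, default_panel
from cardioburden.triage import triage_all
from conftest import make_obs


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive fixed-margins enumeration in exact rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denominator = comb(n, r1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(c1, k) * comb(n - c1, r1 - k), denominator)

    p_obs = prob(a)
    threshold = p_obs * (1 + Fraction(1, 10**7))
    total = sum(
        prob(k)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if prob(k) <= threshold
    )
    return float(total)


small_cells = st.integers(0, 15)


class TestFisherExact:
    def test_kcnq1_allele_table(self):
        result = fisher_exact_two_sided(BurdenTable(5, 575, 219, 66_521, TableUnit.ALLELES))
        assert result.p_two_sided == pytest.approx(0.046, abs=5e-4)

    def test_gpd1l_allele_table(self):
        result = fisher_exact_two_sided(BurdenTable(4, 576, 160, 66_580, TableUnit.ALLELES))
        assert result.p_two_sided == pytest.approx(0.054, abs=5e-4)

    @pytest.mark.parametrize("k,n", [(2, 10), (5, 12), (0, 7)])
    def test_equal_proportions_give_p_one(self, k, n):
        result = fisher_exact_two_sided(BurdenTable(k, n - k, k, n - k))
        assert result.p_two_sided == pytest.approx(1.0)

    def test_matches_oracle_on_enumerated_small_tables(self):
        for a in range(0, 13):
            for c in range(0, 13):
                table = BurdenTable(a, 12 - a, c, 12 - c)
                assert fisher_exact_two_sided(table).p_two_sided == pytest.approx(
                    fisher_oracle(a, 12 - a, c, 12 - c), abs=1e-12
                )

    @settings(max_examples=300, deadline=None)
    @given(a=small_cells, b=small_cells, c=small_cells, d=small_cells)
    def test_matches_oracle_property(self, a, b, c, d):
        assume(a + b > 0 and c + d > 0 and a + b + c + d <= 60)
        result = fisher_exact_two_sided(BurdenTable(a, b, c, d))
        assert result.p_two_sided == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_odds_ratio(self):
        assert fisher_exact_two_sided(BurdenTable(2, 4, 1, 8)).odds_ratio == pytest.approx(4.0)

    def test_odds_ratio_infinite(self):
        assert fisher_exact_two_sided(BurdenTable(2, 0, 1, 8)).odds_ratio == float("inf")

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            BurdenTable(0, 0, 1, 1)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            BurdenTable(-1, 2, 3, 4)

    def test_upper_tail_monotone_in_a(self):
        # with the other cells fixed, pushing a further above its null
        # expectation shrinks the upper-tail point mass
        b, c, d = 30, 10, 40
        previous = None
        for a in range(8, 20):
            from scipy.stats import hypergeom

            table = BurdenTable(a, b, c, d)
            tail = hypergeom.sf(a - 1, table.total, a + c, a + b)
            if previous is not None:
                assert tail <= previous + 1e-12
            previous = tail


class TestCarrierSummary:
    def test_fixture_counts(self, fixture_observations, fixture_panel):
        results = triage_all(fixture_observations)
        summary = summarize_carriers(results, fixture_panel, 290)
        assert summary.carriers_total == 35
        assert summary.carriers_one == 31
        assert summary.carriers_two_plus == 4
        assert summary.carriers_by_category[Category.CHANNELOPATHY] == 23
        assert summary.carriers_by_category[Category.CARDIOMYOPATHY] == 15

    def test_dual_category_consistency(self, fixture_observations, fixture_panel):
        results = triage_all(fixture_observations)
        summary = summarize_carriers(results, fixture_panel, 290)
        dual = (
            summary.carriers_by_category[Category.CHANNELOPATHY]
            + summary.carriers_by_category[Category.CARDIOMYOPATHY]
            - summary.carriers_total
        )
        assert dual == 3  # cases with one variant in each category

    def test_empty_results(self, fixture_panel):
        summary = summarize_carriers([], fixture_panel, 290)
        assert summary.carriers_total == 0
        assert summary.non_carriers == 290

    def test_two_variants_same_gene_is_one_carrier(self, fixture_panel):
        results = triage_all(
            [
                make_obs(case_id="c1", gene="KCNQ1", pos=100, consequence="nonsense"),
                make_obs(case_id="c1", gene="KCNQ1", pos=200, consequence="nonsense"),
            ]
        )
        summary = summarize_carriers(results, fixture_panel, 10)
        assert summary.carriers_total == 1
        assert summary.carriers_two_plus == 1

    def test_cohort_smaller_than_carriers_rejected(self, fixture_panel):
        results = triage_all(
            [
                make_obs(case_id=f"c{i}", gene="KCNQ1", pos=100 + i, consequence="nonsense")
                for i in range(3)
            ]
        )
        with pytest.raises(ValueError):
            summarize_carriers(results, fixture_panel, 2)

    def test_conservation_carriers_plus_noncarriers(self, fixture_observations, fixture_panel):
        results = triage_all(fixture_observations)
        summary = summarize_carriers(results, fixture_panel, 290)
        assert summary.carriers_total + summary.non_carriers == 290


class TestExpectedReferenceCarriers:
    def test_fixture_exac_expectation(self, fixture_observations, fixture_references):
        keys = {o.key for o in fixture_observations}
        count, proportion = expected_reference_carriers(keys, fixture_references["ExAC_NFE"])
        assert count == 1776
        assert proportion == pytest.approx(0.0532, abs=5e-5)

    def test_hand_arithmetic(self):
        ref = ReferencePopulation(
            "r",
            n_individuals=1000,
            maf_of={
                VariantKey("chr1", 1, "A", "G"): 0.001,
                VariantKey("chr1", 2, "A", "G"): 0.002,
            },
        )
        count, proportion = expected_reference_carriers(ref.maf_of.keys(), ref)
        assert count == 6  # round(0.003 * 2000)
        assert proportion == pytest.approx(0.006)

    def test_empty_set(self, fixture_references):
        assert expected_reference_carriers([], fixture_references["ExAC_NFE"]) == (0, 0.0)

    def test_duplicates_counted_once(self):
        ref = ReferencePopulation(
            "r", n_individuals=1000, maf_of={VariantKey("chr1", 1, "A", "G"): 0.001}
        )
        key = VariantKey("chr1", 1, "A", "G")
        count, _ = expected_reference_carriers([key, key, key], ref)
        assert count == 2  # round(0.001 * 2000), not tripled

    def test_capped_at_population_size(self):
        ref = ReferencePopulation(
            "r", n_individuals=10, maf_of={VariantKey("chr1", 1, "A", "G"): 0.9}
        )
        count, proportion = expected_reference_carriers(ref.maf_of.keys(), ref)
        assert count == 10 and proportion == 1.0


class TestCohortMaf:
    def test_gpd1l_four_heterozygotes(self, fixture_observations):
        key = next(o.key for o in fixture_observations if o.gene == "GPD1L")
        matching = [o for o in fixture_observations if o.key == key]
        assert cohort_maf(matching, 290) == pytest.approx(4 / 580)

    def test_homozygous_counts_two_alleles(self, fixture_observations):
        matching = [o for o in fixture_observations if o.gene == "ABCC9"]
        assert matching[0].zygosity is Zygosity.HOMOZYGOUS
        assert cohort_maf(matching, 290) == pytest.approx(2 / 580)

    def test_no_observations_is_zero(self):
        assert cohort_maf([], 290) == 0.0

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError):
            cohort_maf([make_obs(pos=1), make_obs(pos=2)], 10)

    def test_allele_overflow_rejected(self):
        observations = [
            make_obs(case_id=f"c{i}", zygosity=Zygosity.HOMOZYGOUS) for i in range(3)
        ]
        with pytest.raises(ValueError):
            cohort_maf(observations, 2)


@pytest.fixture(scope="module")
def fixture_summary(fixture_observations, fixture_panel):
    return summarize_carriers(triage_all(fixture_observations), fixture_panel, 290)


class TestBurdenTests:
    def test_all_genes_vs_exac(self, fixture_summary):
        result = carrier_burden_test(fixture_summary, 1776, 33_370)
        assert result.table.a == 35 and result.table.b == 255
        assert result.table.c == 1776 and result.table.d == 31_594
        assert result.p_two_sided < 0.001

    def test_channelopathy_vs_swegen(self, fixture_summary):
        result = carrier_burden_test(fixture_summary, 23, 1_000, Category.CHANNELOPATHY)
        assert (result.table.a, result.table.b) == (23, 267)
        assert result.p_two_sided < 0.001

    def test_cardiomyopathy_vs_swegen(self, fixture_summary):
        result = carrier_burden_test(fixture_summary, 28, 1_000, Category.CARDIOMYOPATHY)
        assert result.p_two_sided == pytest.approx(0.061, abs=5e-4)

    def test_equal_rates_give_p_one(self, fixture_panel):
        summary = CarrierSummary(
            cohort_size=100, carriers_total=10, carriers_one=10, carriers_two_plus=0
        )
        assert carrier_burden_test(summary, 10, 100).p_two_sided == pytest.approx(1.0)

    def test_ref_carriers_exceeding_ref_rejected(self, fixture_summary):
        with pytest.raises(ValueError):
            carrier_burden_test(fixture_summary, 2_000, 1_000)

    def test_kcnq1_gene_allele_burden(self, fixture_observations, fixture_references):
        pathogenic = [r.observation for r in triage_all(fixture_observations) if r.is_pathogenic]
        result = gene_allele_burden(
            "KCNQ1", pathogenic, 290, 219, fixture_references["ExAC_NFE"]
        )
        assert (result.table.a, result.table.b) == (5, 575)
        assert result.table.unit is TableUnit.ALLELES
        assert result.p_two_sided == pytest.approx(0.046, abs=5e-4)
        assert result.table.a / (result.table.a + result.table.b) == pytest.approx(
            0.0086, abs=5e-5
        )

    def test_gene_allele_burden_degenerate_rejected(self, fixture_references):
        with pytest.raises(ValueError):
            gene_allele_burden("KCNQ1", [], 0, 0, fixture_references["ExAC_NFE"])

    def test_gpd1l_variant_maf_test(self, fixture_observations, fixture_references):
        key = next(o.key for o in fixture_observations if o.gene == "GPD1L")
        result = variant_maf_test(key, fixture_observations, 290, fixture_references["ExAC_NFE"])
        assert (result.table.a, result.table.c) == (4, 160)
        assert result.p_two_sided == pytest.approx(0.054, abs=5e-4)

    def test_variant_absent_from_reference_rejected(self, fixture_references):
        with pytest.raises(KeyError):
            variant_maf_test(
                VariantKey("chr1", 1, "A", "G"), [], 290, fixture_references["ExAC_NFE"]
            )

    def test_variant_maf_equal_rates_p_one(self):
        key = VariantKey("chr1", 1, "A", "G")
        ref = ReferencePopulation("r", n_individuals=290, maf_of={key: 2 / 580})
        observations = [
            make_obs(case_id="a", chrom="chr1", pos=1),
            make_obs(case_id="b", chrom="chr1", pos=1),
        ]
        result = variant_maf_test(key, observations, 290, ref)
        assert result.p_two_sided == pytest.approx(1.0)


class TestDemographics:
    def test_hand_computed_three_bin_chi2(self):
        # carriers binned (10,20,30), cohort (20,20,20):
        # chi2 = 25/15 + 25/15 + 0 + 0 + 1 + 1 = 16/3; df = 2; p = exp(-8/3)
        carrier_ga = [5] * 10 + [15] * 20 + [25] * 30
        cohort_ga = [5] * 20 + [15] * 20 + [25] * 20
        statistic, p = ga_chi2_test(carrier_ga, cohort_ga, [0, 10, 20, 30])
        assert statistic == pytest.approx(16 / 3)
        import math

        assert p == pytest.approx(math.exp(-8 / 3))

    def test_identical_distributions_statistic_zero(self):
        values = [5] * 4 + [15] * 6 + [25] * 3
        statistic, p = ga_chi2_test(values, values, [0, 10, 20, 30])
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_expected_cell_advises_merge(self):
        with pytest.raises(ValueError, match="merge"):
            ga_chi2_test([5, 5], [5, 5], [0, 10, 20])

    def test_sex_equal_proportions_p_one(self):
        assert sex_fisher_test((5, 5), (50, 50)).p_two_sided == pytest.approx(1.0)

    def test_compare_demographics_dispatch(self, fixture_observations):
        carriers = fixture_observations[:10]
        p_sex = compare_demographics(carriers, fixture_observations, test="fisher")
        assert 0.0 <= p_sex <= 1.0
        p_ga = compare_demographics(
            carriers, fixture_observations, ga_bins=[150, 200, 250, 300], test="chi2"
        )
        assert 0.0 <= p_ga <= 1.0

    def test_unknown_test_rejected(self, fixture_observations):
        with pytest.raises(ValueError):
            compare_demographics(fixture_observations, fixture_observations, test="anova")
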