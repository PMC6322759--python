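"""Carrier aggregation and 2x2 exact-test comparisons against reference populations.

Carrier counting is by distinct case: a case with two qualifying variants is
one carrier (but increments both disease-category counts when the variants
fall in different categories).  Reference-population carrier expectations
assume no reference individual carries more than one qualifying variant, so
the expected carrier count is the rounded sum of per-variant MAFs times the
allele number, each distinct variant counted once.

The two-sided Fisher p-value follows the point-probability rule: sum the
hypergeometric probabilities of all tables (with margins fixed) no more
likely than the observed one, with a 1e-7 relative tolerance for ties.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ReferencePopulation, VariantKey, VariantObservation, ga_days
from .panel import Category, GenePanel
from .triage import TriageResult

__all__ = [
    "TableUnit",
    "BurdenTable",
    "ExactTestResult",
    "CarrierSummary",
    "summarize_carriers",
    "expected_reference_carriers",
    "cohort_maf",
    "fisher_exact_two_sided",
    "carrier_burden_test",
    "gene_allele_burden",
    "variant_maf_test",
    "compare_demographics",
    "ga_chi2_test",
    "sex_fisher_test",
]

#: relative tolerance for point-probability ties in the two-sided rule
_TIE_GAMMA = 1.0 + 1e-7


class TableUnit(str, enum.Enum):
    INDIVIDUALS = "individuals"
    ALLELES = "alleles"


@dataclass(frozen=True)
class BurdenTable:
    """A 2x2 contingency table: cohort (a, b) versus reference (c, d)."""

    a: int
    b: int
    c: int
    d: int
    unit: TableUnit = TableUnit.INDIVIDUALS

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"table cells must be non-negative integers: {self}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError(f"degenerate table margins: {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ExactTestResult:
    p_two_sided: float
    odds_ratio: float
    table: BurdenTable

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {self.p_two_sided}")


def fisher_exact_two_sided(table: BurdenTable) -> ExactTestResult:
    """Exact two-sided test of independence on a 2x2 table.

    p = sum of P(k) over the hypergeometric support for all k with
    P(k) <= P(a) * (1 + 1e-7); odds ratio is the sample odds ratio
    (a*d)/(b*c), infinite when b*c == 0 and a*d > 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, total = a + b, a + c, table.total
    # support of the (1,1) cell with both margins fixed
    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * _TIE_GAMMA].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds_ratio = float("inf") if a * d > 0 else float("nan")
    else:
        odds_ratio = (a * d) / (b * c)
    return ExactTestResult(p_two_sided=p, odds_ratio=odds_ratio, table=table)


@dataclass
class CarrierSummary:
    """Distinct-case carrier counts for a cohort of declared size."""

    cohort_size: int
    carriers_total: int
    carriers_one: int
    carriers_two_plus: int
    carriers_by_category: dict[Category, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carriers_total != self.carriers_one + self.carriers_two_plus:
            raise ValueError("carriers_total must equal carriers_one + carriers_two_plus")
        if self.carriers_total > self.cohort_size:
            raise ValueError("more carriers than cohort members")

    @property
    def non_carriers(self) -> int:
        return self.cohort_size - self.carriers_total

    def proportion(self, category: Category | None = None) -> float:
        count = (
            self.carriers_total
            if category is None
            else self.carriers_by_category.get(Category(category), 0)
        )
        return count / self.cohort_size


def summarize_carriers(
    results: Iterable[TriageResult], panel: GenePanel, cohort_size: int
) -> CarrierSummary:
    """Aggregate putative-pathogenic triage calls to case-level carrier counts."""
    pathogenic = [r for r in results if r.is_pathogenic]
    per_case: dict[str, int] = defaultdict(int)
    cases_by_category: dict[Category, set[str]] = {c: set() for c in Category}
    for result in pathogenic:
        obs = result.observation
        per_case[obs.case_id] += 1
        cases_by_category[panel.category_of(obs.gene)].add(obs.case_id)
    if len(per_case) > cohort_size:
        raise ValueError(
            f"cohort_size {cohort_size} smaller than {len(per_case)} distinct carrier cases"
        )
    return CarrierSummary(
        cohort_size=cohort_size,
        carriers_total=len(per_case),
        carriers_one=sum(1 for n in per_case.values() if n == 1),
        carriers_two_plus=sum(1 for n in per_case.values() if n >= 2),
        carriers_by_category={c: len(ids) for c, ids in cases_by_category.items()},
    )


def expected_reference_carriers(
    variants: Iterable[VariantKey], ref: ReferencePopulation
) -> tuple[int, float]:
    """Expected carriers of any of ``variants`` in ``ref``, and the proportion.

    Under the one-carrier-per-individual assumption the expectation is
    sum(MAF_i) * allele_number over the distinct variants (0 for variants
    absent from the reference), rounded to the nearest integer and capped at
    the number of individuals.
    """
    distinct = set(variants)
    total_maf = sum(ref.maf_of.get(key, 0.0) for key in distinct)
    count = min(round(total_maf * ref.allele_number), ref.n_individuals)
    return count, count / ref.n_individuals


def cohort_maf(
    observations: Iterable[VariantObservation], cohort_size: int
) -> float:
    """Cohort minor allele frequency of one variant: alt alleles over 2N."""
    observations = list(observations)
    keys = {obs.key for obs in observations}
    if len(keys) > 1:
        raise ValueError(f"observations span multiple variants: {sorted(keys)}")
    alleles = sum(obs.allele_count for obs in observations)
    if alleles > 2 * cohort_size:
        raise ValueError(f"{alleles} alt alleles exceed 2N = {2 * cohort_size}")
    return alleles / (2 * cohort_size)


def carrier_burden_test(
    summary: CarrierSummary,
    ref_carriers: int,
    ref_n: int,
    category: Category | None = None,
) -> ExactTestResult:
    """Compare cohort carrier counts (all genes or one category) to a reference."""
    if ref_carriers > ref_n:
        raise ValueError("reference carriers exceed reference size")
    carriers = (
        summary.carriers_total
        if category is None
        else summary.carriers_by_category.get(Category(category), 0)
    )
    table = BurdenTable(
        a=carriers,
        b=summary.cohort_size - carriers,
        c=ref_carriers,
        d=ref_n - ref_carriers,
        unit=TableUnit.INDIVIDUALS,
    )
    return fisher_exact_two_sided(table)


def gene_allele_burden(
    gene: str,
    observations: Iterable[VariantObservation],
    cohort_size: int,
    ref_alt_alleles: int,
    ref: ReferencePopulation,
) -> ExactTestResult:
    """Gene-wide alt-allele burden versus a reference allele count."""
    gene = gene.upper()
    alt = sum(o.allele_count for o in observations if o.gene == gene)
    table = BurdenTable(
        a=alt,
        b=2 * cohort_size - alt,
        c=ref_alt_alleles,
        d=ref.allele_number - ref_alt_alleles,
        unit=TableUnit.ALLELES,
    )
    return fisher_exact_two_sided(table)


def variant_maf_test(
    key: VariantKey,
    observations: Iterable[VariantObservation],
    cohort_size: int,
    ref: ReferencePopulation,
) -> ExactTestResult:
    """Compare one variant's cohort allele count to its reference frequency."""
    maf = ref.maf(key)
    if maf is None:
        raise KeyError(f"variant {key} absent from reference {ref.name}")
    matching = [o for o in observations if o.key == key]
    alt = sum(o.allele_count for o in matching)
    ref_alt = round(maf * ref.allele_number)
    table = BurdenTable(
        a=alt,
        b=2 * cohort_size - alt,
        c=ref_alt,
        d=ref.allele_number - ref_alt,
        unit=TableUnit.ALLELES,
    )
    return fisher_exact_two_sided(table)


def ga_chi2_test(
    carrier_ga: Sequence[int | float],
    cohort_ga: Sequence[int | float],
    bin_edges: Sequence[float],
) -> tuple[float, float]:
    """Chi-square comparison of gestational-age interval distributions.

    Bins both samples with ``bin_edges``, builds a k x 2 table, computes
    sum((O-E)^2 / E) with expectations from pooled margins and p from the
    chi-square distribution with (k - 1) degrees of freedom.
    """
    obs_a, _ = np.histogram(carrier_ga, bins=bin_edges)
    obs_b, _ = np.histogram(cohort_ga, bins=bin_edges)
    observed = np.column_stack([obs_a, obs_b]).astype(float)
    row_sums = observed.sum(axis=1, keepdims=True)
    col_sums = observed.sum(axis=0, keepdims=True)
    expected = row_sums @ col_sums / observed.sum()
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero; merge gestational-age bins")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    dof = observed.shape[0] - 1
    return statistic, float(stats.chi2.sf(statistic, dof))


def sex_fisher_test(
    carrier_counts: tuple[int, int], cohort_counts: tuple[int, int]
) -> ExactTestResult:
    """Exact 2x2 comparison of sex counts (e.g. (XX, XY) per group)."""
    table = BurdenTable(
        a=carrier_counts[0],
        b=carrier_counts[1],
        c=cohort_counts[0],
        d=cohort_counts[1],
        unit=TableUnit.INDIVIDUALS,
    )
    return fisher_exact_two_sided(table)


def compare_demographics(
    carrier_cases: Iterable[VariantObservation],
    all_cases: Iterable[VariantObservation],
    ga_bins: Sequence[float] | None = None,
    test: str = "chi2",
) -> float:
    """Demographic comparison of carrier cases against the complete cohort.

    ``test="chi2"`` bins gestational ages (days) and runs :func:`ga_chi2_test`;
    ``test="fisher"`` compares XX/XY counts with the exact test.  Observations
    with unknown gestational age (or sex) are dropped from the respective
    comparison.  Duplicate case_ids are collapsed to their first occurrence.
    """
    carriers = _first_per_case(carrier_cases)
    cohort = _first_per_case(all_cases)
    if test == "chi2":
        if ga_bins is None:
            raise ValueError("ga_bins required for the chi2 comparison")
        carrier_ga = [d for o in carriers if (d := ga_days(o.gestational_age)) is not None]
        cohort_ga = [d for o in cohort if (d := ga_days(o.gestational_age)) is not None]
        _, p = ga_chi2_test(carrier_ga, cohort_ga, ga_bins)
        return p
    if test == "fisher":
        def sex_counts(group: Sequence[VariantObservation]) -> tuple[int, int]:
            xx = sum(1 for o in group if o.sex.value == "XX")
            xy = sum(1 for o in group if o.sex.value == "XY")
            return xx, xy

        return sex_fisher_test(sex_counts(carriers), sex_counts(cohort)).p_two_sided
    raise ValueError(f"unknown test {test!r}; expected 'chi2' or 'fisher'")


def _first_per_case(
    observations: Iterable[VariantObservation],
) -> list[VariantObservation]:
    seen: dict[str, VariantObservation] = {}
    for obs in observations:
        seen.setdefault(obs.case_id, obs)
    return list(seen.values())
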