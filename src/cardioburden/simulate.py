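"""Synthetic cohort generation and the packaged study dataset.

The simulator draws carrier cases by independent Bernoulli sampling, assigns
each carrier one or two variants guaranteed to classify putative pathogenic
under the default triage configuration, and sprinkles in decoys (VUS,
synonymous, and common variants) that the filters must dispose of.  Every
generated variant also receives log-uniform reference-population MAFs below
the frequency-exclusion threshold (decoy common variants excepted), so
carrier-burden expectations are well defined.

:func:`study_fixture` returns the packaged 39-row annotated cohort (290
cases) together with reference populations built from its MAF columns and
the default 70-gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .burden import carrier_burden_test, summarize_carriers
from .io import (
    Consequence,
    ReferencePopulation,
    Sex,
    VariantKey,
    VariantObservation,
    Zygosity,
    read_observations,
    reference_from_observations,
)
from .panel import Category, GenePanel, default_panel
from .triage import Fate, Label, TriageConfig, triage_all

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "RecoveryReport",
    "simulate_cohort",
    "study_fixture",
    "end_to_end_recovery",
]

_STUDY_COHORT_SIZE = 290
_REFERENCE_SIZES = {"ExAC_NFE": 33_370, "SweGen": 1_000}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 290
    carrier_prevalence: float = 0.12
    dual_variant_fraction: float = 4 / 35
    category_split: float = 23 / 35  # fraction channelopathy
    vus_per_case_rate: float = 0.5
    synonymous_decoy_rate: float = 0.2
    common_decoy_rate: float = 0.2
    maf_log10_range: tuple[float, float] = (-5.0, -2.4)
    ref_populations: tuple[tuple[str, int], ...] = (
        ("ExAC_NFE", 33_370),
        ("SweGen", 1_000),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("carrier_prevalence", self.carrier_prevalence),
            ("dual_variant_fraction", self.dual_variant_fraction),
            ("category_split", self.category_split),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if self.n_cases == 0 and self.carrier_prevalence > 0:
            raise ValueError("cannot place carriers in an empty cohort")
        lo, hi = self.maf_log10_range
        if hi >= np.log10(0.01):
            raise ValueError(
                "maf_log10_range upper bound must stay below log10(0.01) so "
                "generated pathogenic variants survive the frequency filter"
            )
        if lo > hi:
            raise ValueError("maf_log10_range must be ordered (lo, hi)")


@dataclass
class SyntheticCohort:
    observations: list[VariantObservation]
    carrier_cases: set[str]
    variant_truth: dict[VariantKey, str]  # pathogenic / vus / decoy_*
    references: dict[str, ReferencePopulation]
    config: SimulationConfig

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_cases)


def _random_ga(rng: np.random.Generator) -> str:
    return f"{rng.integers(22, 42)}+{rng.integers(0, 7)}"


class _VariantFactory:
    """Mints unique variant keys with fresh positions per cohort."""

    def __init__(self, rng: np.random.Generator, panel: GenePanel) -> None:
        self.rng = rng
        self._counter = 0
        # stable pseudo-chromosome per gene; positions never collide
        self._gene_chrom = {
            g.symbol: f"chr{1 + i % 22}" for i, g in enumerate(panel)
        }

    def new_key(self, gene: str) -> VariantKey:
        self._counter += 1
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        return VariantKey(
            chrom=self._gene_chrom[gene],
            pos=1_000_000 + self._counter * 37,
            ref=str(ref),
            alt=str(alt),
        )


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort with known carrier truth; deterministic under seed.

    Every truth-pathogenic variant classifies putative pathogenic under the
    default :class:`~cardioburden.triage.TriageConfig` and every decoy is
    removed by the filters or labelled non-pathogenic; this is asserted
    before returning.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()
    factory = _VariantFactory(rng, panel)
    chan_genes = panel.symbols(Category.CHANNELOPATHY)
    cardio_genes = panel.symbols(Category.CARDIOMYOPATHY)

    observations: list[VariantObservation] = []
    carrier_cases: set[str] = set()
    variant_truth: dict[VariantKey, str] = {}
    maf_records: dict[VariantKey, dict[str, float]] = {}

    def draw_mafs(key: VariantKey, common: bool = False) -> dict[str, float]:
        lo, hi = cfg.maf_log10_range
        mafs = {
            name: 0.05 if common else float(10.0 ** rng.uniform(lo, hi))
            for name, _ in cfg.ref_populations
        }
        maf_records[key] = mafs
        return mafs

    for case_index in range(cfg.n_cases):
        case_id = f"S{case_index + 1:04d}"
        sex = Sex.XX if rng.random() < 0.5 else Sex.XY
        ga = _random_ga(rng)
        is_carrier = rng.random() < cfg.carrier_prevalence
        if is_carrier:
            carrier_cases.add(case_id)
            n_variants = 2 if rng.random() < cfg.dual_variant_fraction else 1
            for _ in range(n_variants):
                chan = rng.random() < cfg.category_split
                gene = str(rng.choice(chan_genes if chan else cardio_genes))
                key = factory.new_key(gene)
                lof = rng.random() < 0.5
                consequence = (
                    Consequence(
                        str(rng.choice(["nonsense", "frameshift", "splice_site"]))
                    )
                    if lof
                    else Consequence.MISSENSE
                )
                observations.append(
                    VariantObservation(
                        case_id=case_id,
                        sex=sex,
                        gestational_age=ga,
                        gene=gene,
                        key=key,
                        consequence=consequence,
                        zygosity=Zygosity.HETEROZYGOUS,
                        cadd_scaled=float(rng.uniform(15, 45)),
                        ref_mafs=draw_mafs(key),
                        reported_in_affected=not lof,
                        functional_evidence=(not lof) and rng.random() < 0.5,
                    )
                )
                variant_truth[key] = "pathogenic"
        # decoys: retained-but-uncertain, filtered-synonymous, filtered-common
        for _ in range(rng.poisson(cfg.vus_per_case_rate)):
            gene = str(rng.choice(chan_genes + cardio_genes))
            key = factory.new_key(gene)
            observations.append(
                VariantObservation(
                    case_id=case_id, sex=sex, gestational_age=ga, gene=gene,
                    key=key, consequence=Consequence.MISSENSE,
                    cadd_scaled=float(rng.uniform(12, 30)),
                    ref_mafs=draw_mafs(key),
                )
            )
            variant_truth[key] = "vus"
        if rng.random() < cfg.synonymous_decoy_rate:
            gene = str(rng.choice(chan_genes + cardio_genes))
            key = factory.new_key(gene)
            observations.append(
                VariantObservation(
                    case_id=case_id, sex=sex, gestational_age=ga, gene=gene,
                    key=key, consequence=Consequence.SYNONYMOUS,
                    cadd_scaled=float(rng.uniform(0, 10)),
                    ref_mafs=draw_mafs(key),
                )
            )
            variant_truth[key] = "decoy_synonymous"
        if rng.random() < cfg.common_decoy_rate:
            gene = str(rng.choice(chan_genes + cardio_genes))
            key = factory.new_key(gene)
            observations.append(
                VariantObservation(
                    case_id=case_id, sex=sex, gestational_age=ga, gene=gene,
                    key=key, consequence=Consequence.MISSENSE,
                    cadd_scaled=float(rng.uniform(0, 20)),
                    ref_mafs=draw_mafs(key, common=True),
                )
            )
            variant_truth[key] = "decoy_common"

    references = {
        name: ReferencePopulation(
            name=name,
            n_individuals=n,
            maf_of={key: mafs[name] for key, mafs in maf_records.items()},
        )
        for name, n in cfg.ref_populations
    }
    cohort = SyntheticCohort(
        observations=observations,
        carrier_cases=carrier_cases,
        variant_truth=variant_truth,
        references=references,
        config=cfg,
    )
    _assert_label_guarantee(cohort)
    return cohort


def _assert_label_guarantee(cohort: SyntheticCohort) -> None:
    """Truth-pathogenic variants must triage pathogenic; decoys must not."""
    results = triage_all(cohort.observations, TriageConfig())
    for result in results:
        truth = cohort.variant_truth[result.observation.key]
        if truth == "pathogenic":
            assert result.label is Label.PUTATIVE_PATHOGENIC, result
        elif truth == "decoy_common":
            assert result.fate is Fate.EXCLUDED_FREQUENCY, result
        elif truth == "decoy_synonymous":
            assert result.fate is Fate.EXCLUDED_CONSEQUENCE, result
        else:
            assert result.label is not Label.PUTATIVE_PATHOGENIC, result


def study_fixture(
    panel_overrides=None,
) -> tuple[list[VariantObservation], dict[str, ReferencePopulation], GenePanel]:
    """The packaged 290-case study dataset.

    Returns the 39 annotated case-variant rows, reference populations built
    from the two MAF columns (ExAC_NFE n=33,370, SweGen n=1,000), and the
    default 70-gene panel.
    """
    resource = resources.files("cardioburden").joinpath("data/study_cohort.tsv")
    with resources.as_file(resource) as path:
        observations = read_observations(path)
    references = {
        name: reference_from_observations(observations, name, n)
        for name, n in _REFERENCE_SIZES.items()
    }
    return observations, references, default_panel(panel_overrides)


@dataclass
class RecoveryReport:
    """Per-replicate pipeline recovery of carrier prevalence and test calibration."""

    replicates: int
    alpha: float
    estimated_prevalence: list[float]
    p_values: list[float]
    true_prevalence: float

    @property
    def mean_prevalence(self) -> float:
        return float(np.mean(self.estimated_prevalence))

    @property
    def bias(self) -> float:
        return self.mean_prevalence - self.true_prevalence

    @property
    def rejection_rate(self) -> float:
        return float(np.mean([p < self.alpha for p in self.p_values]))


def end_to_end_recovery(
    cfg: SimulationConfig,
    replicates: int,
    ref_n: int = 1_000,
    ref_prevalence: float | None = None,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Run simulate -> triage -> carrier burden over replicates.

    The reference carrier count is drawn binomially at ``ref_prevalence``
    (defaulting to the cohort's generative prevalence, i.e. the null), so the
    rejection rate estimates type-I error under the null and power otherwise.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ref_p = cfg.carrier_prevalence if ref_prevalence is None else ref_prevalence
    rng = np.random.default_rng(cfg.seed + 7_919)
    panel = default_panel()
    estimated: list[float] = []
    p_values: list[float] = []
    for i in range(replicates):
        cohort = simulate_cohort(replace(cfg, seed=cfg.seed + i))
        results = triage_all(cohort.observations)
        summary = summarize_carriers(results, panel, cfg.n_cases)
        estimated.append(summary.carriers_total / cfg.n_cases)
        ref_carriers = int(rng.binomial(ref_n, ref_p))
        p_values.append(
            carrier_burden_test(summary, ref_carriers, ref_n).p_two_sided
        )
    return RecoveryReport(
        replicates=replicates,
        alpha=alpha,
        estimated_prevalence=estimated,
        p_values=p_values,
        true_prevalence=cfg.carrier_prevalence,
    )
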