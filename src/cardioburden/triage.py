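"""Variant triage: frequency/consequence filtering and pathogenicity labelling.

Rules applied in order to each observation:

1. frequency filter — exclude if any annotated reference-population MAF
   exceeds the threshold (default 1%); missing MAFs never exclude;
2. consequence filter — exclude synonymous variants and intronic variants
   not predicted to affect splicing; a splice-predicted intronic variant is
   reclassified as a splice-site change for the remaining rules;
3. classification — loss-of-function variants, and missense variants with
   prior reports in affected individuals or functional evidence, are
   labelled putative pathogenic; missense variants with no such evidence
   that sit at poorly conserved positions and have a low scaled CADD score
   are likely benign; everything else is a VUS.

Putative-pathogenic calls receive a simplified two-tier class (3 = uncertain
significance, 4 = likely pathogenic): by default class 4 for LoF changes with
no prior disease report, class 3 otherwise; a per-row published class, when
present, overrides the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import Consequence, LOF_CONSEQUENCES, VariantObservation

__all__ = [
    "Fate",
    "Label",
    "FrequencyRule",
    "TriageConfig",
    "TriageResult",
    "frequency_filter",
    "consequence_filter",
    "classify",
    "triage_observation",
    "triage_all",
    "cadd_rank_fraction",
]


class Fate(str, enum.Enum):
    EXCLUDED_FREQUENCY = "excluded_frequency"
    EXCLUDED_CONSEQUENCE = "excluded_consequence"
    RETAINED = "retained"


class Label(str, enum.Enum):
    PUTATIVE_PATHOGENIC = "putative_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    NONE = "none"


class FrequencyRule(str, enum.Enum):
    """How multiple population MAFs combine in the frequency filter."""

    ANY = "any"  # one population above threshold excludes (strict reading)
    ALL = "all"  # every available population must be above threshold


@dataclass(frozen=True)
class TriageConfig:
    maf_exclusion_threshold: float = 0.01
    cadd_low_threshold: float = 10.0
    lof_consequences: frozenset[Consequence] = LOF_CONSEQUENCES
    frequency_rule: FrequencyRule = FrequencyRule.ANY
    use_published_class: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_exclusion_threshold <= 1.0:
            raise ValueError("maf_exclusion_threshold must be in (0, 1]")
        if self.cadd_low_threshold < 0:
            raise ValueError("cadd_low_threshold must be >= 0")


@dataclass
class TriageResult:
    """Fate, label and simplified class for one observation, with the rule trail."""

    observation: VariantObservation
    fate: Fate
    label: Label
    acmg_class: int | None  # 3, 4, or None when unassigned
    trace: list[str] = field(default_factory=list)
    #: consequence after possible intronic -> splice_site reclassification
    effective_consequence: Consequence | None = None

    def __post_init__(self) -> None:
        if self.fate is not Fate.RETAINED:
            assert self.label is Label.NONE and self.acmg_class is None
        if self.label is Label.PUTATIVE_PATHOGENIC:
            assert self.acmg_class in (3, 4)

    @property
    def retained(self) -> bool:
        return self.fate is Fate.RETAINED

    @property
    def is_pathogenic(self) -> bool:
        return self.label is Label.PUTATIVE_PATHOGENIC


def cadd_rank_fraction(score: float) -> float:
    """Fraction of possible genomic variants at least as deleterious.

    A scaled score C places the variant among the top 10**(-C/10) fraction
    (20 -> 1%, 30 -> 0.1%).
    """
    if score < 0:
        raise ValueError(f"scaled CADD score must be >= 0, got {score}")
    return 10.0 ** (-score / 10.0)


def frequency_filter(
    obs: VariantObservation, cfg: TriageConfig | None = None
) -> tuple[bool, str | None]:
    """Return ``(passed, reason)``; missing MAFs never cause failure."""
    cfg = cfg or TriageConfig()
    above = {
        pop: maf
        for pop, maf in obs.ref_mafs.items()
        if maf > cfg.maf_exclusion_threshold
    }
    if not obs.ref_mafs or not above:
        return True, None
    if cfg.frequency_rule is FrequencyRule.ALL and len(above) < len(obs.ref_mafs):
        return True, None
    pops = ",".join(sorted(above))
    return False, f"maf_above_{cfg.maf_exclusion_threshold:g}[{pops}]"


def consequence_filter(
    obs: VariantObservation,
) -> tuple[bool, str | None, Consequence]:
    """Return ``(passed, reason, effective_consequence)``.

    Synonymous variants fail; intronic variants fail unless predicted to
    affect splicing, in which case they pass reclassified as splice-site.
    """
    if obs.consequence is Consequence.SYNONYMOUS:
        return False, "synonymous", obs.consequence
    if obs.consequence is Consequence.INTRONIC:
        if obs.splice_prediction_affected:
            return True, None, Consequence.SPLICE_SITE
        return False, "intronic_no_splice_effect", obs.consequence
    return True, None, obs.consequence


def classify(
    obs: VariantObservation,
    cfg: TriageConfig | None = None,
    effective_consequence: Consequence | None = None,
    trace: Sequence[str] = (),
) -> TriageResult:
    """Label an observation that already passed both filters."""
    cfg = cfg or TriageConfig()
    consequence = effective_consequence or obs.consequence
    trail = list(trace)

    is_lof = consequence in cfg.lof_consequences
    has_evidence = obs.reported_in_affected or obs.functional_evidence
    if is_lof or has_evidence:
        label = Label.PUTATIVE_PATHOGENIC
        trail.append("lof" if is_lof else "evidence_supported")
        acmg_class = _assign_class(obs, is_lof, trail, cfg)
    elif (
        consequence is Consequence.MISSENSE
        and obs.conservation_low
        and obs.cadd_scaled is not None
        and obs.cadd_scaled < cfg.cadd_low_threshold
    ):
        label = Label.LIKELY_BENIGN
        acmg_class = None
        trail.append("benign_low_conservation_low_cadd")
    else:
        label = Label.VUS
        acmg_class = None
        trail.append("vus_fallback")
    return TriageResult(
        observation=obs,
        fate=Fate.RETAINED,
        label=label,
        acmg_class=acmg_class,
        trace=trail,
        effective_consequence=consequence,
    )


def _assign_class(
    obs: VariantObservation, is_lof: bool, trail: list[str], cfg: TriageConfig
) -> int:
    default = 4 if (is_lof and not obs.reported_in_affected) else 3
    trail.append(f"acmg_simplified_default_{default}")
    if cfg.use_published_class and obs.acmg_class_published is not None:
        if obs.acmg_class_published != default:
            trail.append(f"acmg_published_override_{obs.acmg_class_published}")
        return obs.acmg_class_published
    return default


def triage_observation(
    obs: VariantObservation, cfg: TriageConfig | None = None
) -> TriageResult:
    """Run the full rule chain on one observation."""
    cfg = cfg or TriageConfig()
    for pop, maf in obs.ref_mafs.items():
        if maf > 0.5:
            raise ValueError(
                f"{obs.case_id}/{obs.key}: {pop} MAF {maf} > 0.5 is not a minor "
                "allele frequency"
            )
    passed, reason = frequency_filter(obs, cfg)
    if not passed:
        return TriageResult(
            observation=obs, fate=Fate.EXCLUDED_FREQUENCY, label=Label.NONE,
            acmg_class=None, trace=[reason],
        )
    trace = ["frequency_pass"]
    passed, reason, effective = consequence_filter(obs)
    if not passed:
        return TriageResult(
            observation=obs, fate=Fate.EXCLUDED_CONSEQUENCE, label=Label.NONE,
            acmg_class=None, trace=trace + [reason],
        )
    trace.append("consequence_pass")
    if effective is not obs.consequence:
        trace.append("intronic_reclassified_splice_site")
    return classify(obs, cfg, effective_consequence=effective, trace=trace)


def triage_all(
    observations: Iterable[VariantObservation], cfg: TriageConfig | None = None
) -> list[TriageResult]:
    cfg = cfg or TriageConfig()
    return [triage_observation(obs, cfg) for obs in observations]


def write_triage_table(results: Sequence[TriageResult], dest) -> None:
    """Write input columns plus fate, label, acmg_class and the rule trace."""
    from .io import write_observations

    write_observations(
        [r.observation for r in results],
        dest,
        extra_columns={
            "fate": [r.fate.value for r in results],
            "label": [r.label.value for r in results],
            "acmg_class": [
                "-" if r.acmg_class is None else str(r.acmg_class) for r in results
            ],
            "trace": [";".join(r.trace) for r in results],
        },
    )


def read_triage_table(source) -> list[TriageResult]:
    """Reconstruct triage results written by :func:`write_triage_table`."""
    import csv

    from .io import read_observations

    observations = read_observations(source)
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = [row for row in reader if any(v.strip() for v in row.values() if v)]
    if len(rows) != len(observations):
        raise ValueError(f"{source}: row mismatch while reading triage annotations")
    results = []
    for obs, row in zip(observations, rows):
        fate = Fate(row["fate"])
        _, _, effective = consequence_filter(obs)
        results.append(
            TriageResult(
                observation=obs,
                fate=fate,
                label=Label(row["label"]),
                acmg_class=None if row["acmg_class"] == "-" else int(row["acmg_class"]),
                trace=row["trace"].split(";") if row["trace"] else [],
                effective_consequence=effective if fate is Fate.RETAINED else None,
            )
        )
    return results
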