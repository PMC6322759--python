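"""Monte Carlo permutation comparison of pathogenic-variant proportions.

Each iteration draws a fixed-size subset of variants (without replacement by
default) independently from each of two cohorts and counts the flagged
pathogenic variants; the mean proportion over all iterations is reported per
cohort.  As an extension, the fraction of iterations in which cohort A's
count exceeds cohort B's is also reported — this quantity is an addition to
the mean-proportion comparison, not part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import VariantKey
from .triage import TriageConfig, TriageResult

__all__ = [
    "VariantCohort",
    "PermutationResult",
    "permute_proportions",
    "build_cohort_from_triage",
    "read_variant_cohort",
    "write_variant_cohort",
]


@dataclass
class VariantCohort:
    """A named list of variants flagged pathogenic or not."""

    name: str
    variants: list[tuple[VariantKey, bool]]

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def flagged_fraction(self) -> float:
        if not self.variants:
            raise ValueError(f"cohort {self.name!r} is empty")
        return sum(flag for _, flag in self.variants) / len(self.variants)


@dataclass
class PermutationResult:
    iterations: int
    sample_size: int
    seed: int
    mean_proportion_a: float
    mean_proportion_b: float
    #: extension: fraction of iterations with count_a > count_b
    frac_a_exceeds_b: float
    counts_a: np.ndarray | None = field(default=None, repr=False)
    counts_b: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for p in (self.mean_proportion_a, self.mean_proportion_b):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mean proportion outside [0,1]: {p}")


def permute_proportions(
    a: VariantCohort,
    b: VariantCohort,
    iterations: int = 10_000,
    sample_size: int = 50,
    seed: int = 0,
    with_replacement: bool = False,
    keep_counts: bool = True,
) -> PermutationResult:
    """Estimate mean pathogenic proportions over random fixed-size draws.

    Draws are made independently from each cohort in every iteration,
    without replacement unless ``with_replacement`` is set.  Fully
    deterministic for a given seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for cohort in (a, b):
        if not with_replacement and len(cohort) < sample_size:
            raise ValueError(
                f"cohort {cohort.name!r} has {len(cohort)} variants, "
                f"fewer than sample_size {sample_size}"
            )
        if len(cohort) == 0:
            raise ValueError(f"cohort {cohort.name!r} is empty")
    rng = np.random.default_rng(seed)
    flags_a = np.array([flag for _, flag in a.variants], dtype=bool)
    flags_b = np.array([flag for _, flag in b.variants], dtype=bool)
    counts_a = np.empty(iterations, dtype=np.int64)
    counts_b = np.empty(iterations, dtype=np.int64)
    for i in range(iterations):
        idx_a = rng.choice(flags_a.size, size=sample_size, replace=with_replacement)
        idx_b = rng.choice(flags_b.size, size=sample_size, replace=with_replacement)
        counts_a[i] = flags_a[idx_a].sum()
        counts_b[i] = flags_b[idx_b].sum()
    return PermutationResult(
        iterations=iterations,
        sample_size=sample_size,
        seed=seed,
        mean_proportion_a=float(counts_a.mean()) / sample_size,
        mean_proportion_b=float(counts_b.mean()) / sample_size,
        frac_a_exceeds_b=float((counts_a > counts_b).mean()),
        counts_a=counts_a if keep_counts else None,
        counts_b=counts_b if keep_counts else None,
    )


def build_cohort_from_triage(
    results: Iterable[TriageResult],
    cfg: TriageConfig | None = None,
    name: str = "cohort",
) -> VariantCohort:
    """Distinct retained missense/LoF variants with all MAFs below threshold.

    A variant is flagged pathogenic iff any of its observations was labelled
    putative pathogenic.
    """
    cfg = cfg or TriageConfig()
    flags: dict[VariantKey, bool] = {}
    for result in results:
        if not result.retained:
            continue
        consequence = result.effective_consequence or result.observation.consequence
        if consequence not in cfg.lof_consequences and consequence.value != "missense":
            continue
        obs = result.observation
        if any(maf >= cfg.maf_exclusion_threshold for maf in obs.ref_mafs.values()):
            continue
        flags[obs.key] = flags.get(obs.key, False) or result.is_pathogenic
    ordered = sorted(flags.items())
    return VariantCohort(name=name, variants=[(k, v) for k, v in ordered])


def read_variant_cohort(source, name: str | None = None) -> VariantCohort:
    """Read a ``chrom pos ref alt is_pathogenic`` table."""
    import csv
    from pathlib import Path

    variants: list[tuple[VariantKey, bool]] = []
    with open(source, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:5] != ["chrom", "pos", "ref", "alt", "is_pathogenic"]:
            raise ValueError(f"{source}: unexpected cohort header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if row[4] not in {"0", "1"}:
                raise ValueError(f"{source}:{lineno}: is_pathogenic must be 0/1")
            variants.append(
                (VariantKey(row[0], int(row[1]), row[2], row[3]), row[4] == "1")
            )
    return VariantCohort(name=name or Path(str(source)).stem, variants=variants)


def write_variant_cohort(cohort: VariantCohort, dest) -> None:
    import csv

    with open(dest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "is_pathogenic"])
        for key, flag in cohort.variants:
            writer.writerow([key.chrom, key.pos, key.ref, key.alt, int(flag)])
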