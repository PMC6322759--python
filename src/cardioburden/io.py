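"""Readers and writers for annotated case-variant tables and reference MAF tables.

The flat-file dialect is tab-separated with a fixed header (see
``OBSERVATION_COLUMNS``); ``-`` or an empty cell denotes a missing value and
booleans are encoded ``0``/``1``.  A minimal VCF route with the same semantic
content is provided via :func:`read_vcf_observations`.

Coordinates are 1-based GRCh37/hg19 with ``chr``-prefixed chromosome names.
Deletions are stored VCF-style left-anchored (the reference allele includes
the anchoring base).
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Sex",
    "Consequence",
    "Zygosity",
    "VariantKey",
    "VariantObservation",
    "ReferencePopulation",
    "ParseError",
    "OBSERVATION_COLUMNS",
    "parse_genomic_change",
    "ga_days",
    "read_observations",
    "write_observations",
    "read_vcf_observations",
    "load_reference",
    "write_reference",
    "reference_from_observations",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_SNV_RE = re.compile(r"^(chr[\w]+):(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^(chr[\w]+):(\d+)_(\d+)del$")


class ParseError(ValueError):
    """Raised for malformed input rows; message carries the line number."""


class Sex(str, enum.Enum):
    XX = "XX"
    XY = "XY"
    UNKNOWN = "unknown"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


#: Consequences expected to abolish the gene product.
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"allele must be non-empty A/C/G/T, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    def __str__(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def parse_genomic_change(text: str, ref_bases: str | None = None) -> VariantKey:
    """Parse a printed genomic-change string into a :class:`VariantKey`.

    Substitutions look like ``chr12:22063090C>T``.  Deletion ranges like
    ``chr19:49684650_49684657del`` carry no allele sequence, so the deleted
    bases plus the left-anchoring base must be supplied via ``ref_bases``
    (length = deleted span + 1); the anchored position is the range start.
    """
    m = _SNV_RE.match(text)
    if m:
        chrom, pos, ref, alt = m.groups()
        return VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
    m = _DEL_RE.match(text)
    if m:
        chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        if end < start:
            raise ParseError(f"deletion range end < start in {text!r}")
        span = end - start + 1
        if ref_bases is None:
            raise ParseError(
                f"deletion {text!r} needs ref_bases (anchor + {span} deleted bases)"
            )
        if len(ref_bases) != span + 1:
            raise ParseError(
                f"ref_bases for {text!r} must have length {span + 1}, "
                f"got {len(ref_bases)}"
            )
        return VariantKey(chrom=chrom, pos=start, ref=ref_bases, alt=ref_bases[0])
    raise ParseError(f"unrecognized genomic change: {text!r}")


@dataclass(frozen=True)
class VariantObservation:
    """One case-variant row with its annotations.

    ``ref_mafs`` maps a reference-population name to a minor allele
    frequency; a population absent from the map was not observed there.
    Evidence booleans are input annotations computed upstream (literature,
    splice prediction, conservation), not derived here.
    """

    case_id: str
    gene: str
    key: VariantKey
    consequence: Consequence
    zygosity: Zygosity = Zygosity.HETEROZYGOUS
    sex: Sex = Sex.UNKNOWN
    gestational_age: str = "-"
    hgvs_c: str = ""
    hgvs_p: str = ""
    dbsnp_id: str = ""
    cadd_scaled: float | None = None
    ref_mafs: Mapping[str, float] = field(default_factory=dict)
    reported_in_affected: bool = False
    functional_evidence: bool = False
    conservation_low: bool = False
    splice_prediction_affected: bool = False
    acmg_class_published: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "consequence", Consequence(self.consequence))
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError("cadd_scaled must be non-negative")
        for pop, maf in self.ref_mafs.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF for {pop} outside [0,1]: {maf}")
        object.__setattr__(self, "ref_mafs", dict(self.ref_mafs))
        if self.acmg_class_published not in (None, 3, 4):
            raise ValueError("acmg_class_published must be 3, 4 or None")

    @property
    def allele_count(self) -> int:
        """Alt alleles carried: 1 if heterozygous, 2 if homozygous."""
        return 2 if self.zygosity is Zygosity.HOMOZYGOUS else 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantObservation):
            return NotImplemented
        return self.__dict__ == other.__dict__

    def __hash__(self) -> int:
        return hash((self.case_id, self.key))


@dataclass
class ReferencePopulation:
    """A named reference population with per-variant minor allele frequencies."""

    name: str
    n_individuals: int
    maf_of: dict[VariantKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")

    @property
    def allele_number(self) -> int:
        return 2 * self.n_individuals

    def maf(self, key: VariantKey, default: float | None = None) -> float | None:
        return self.maf_of.get(key, default)


_GA_RE = re.compile(r"^(\d+)(?:\+(\d))?$")


def ga_days(text: str) -> int | None:
    """Gestational age in days from a ``weeks+days`` string, else ``None``.

    ``"32+3"`` -> 227; a bare week count ``"30"`` -> 210; anything else
    (``"Full term"``, ``"-"``, ``"N/A"``) is treated as unknown.
    """
    m = _GA_RE.match(text.strip())
    if not m:
        return None
    weeks = int(m.group(1))
    days = int(m.group(2) or 0)
    return weeks * 7 + days


OBSERVATION_COLUMNS = (
    "case_id",
    "sex",
    "ga",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "zygosity",
    "dbsnp",
    "cadd_scaled",
    "maf_exac_nfe",
    "maf_swegen",
    "reported_in_affected",
    "functional_evidence",
    "conservation_low",
    "splice_prediction_affected",
    "acmg_class_published",
)

# the two canonical population columns of the fixed header
_MAF_COLUMN_TO_POP = {"maf_exac_nfe": "ExAC_NFE", "maf_swegen": "SweGen"}
_POP_TO_MAF_COLUMN = {v: k for k, v in _MAF_COLUMN_TO_POP.items()}

_MISSING = {"", "-"}


def _opt(cell: str) -> str | None:
    return None if cell.strip() in _MISSING else cell.strip()


def _parse_bool(cell: str, column: str, lineno: int) -> bool:
    if cell not in {"0", "1"}:
        raise ParseError(f"line {lineno}: column {column} must be 0/1, got {cell!r}")
    return cell == "1"


def read_observations(source: str | Path) -> list[VariantObservation]:
    """Read a tab-separated case-variant table (row order preserved)."""
    with open(source, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{source}: empty file, expected header") from None
        missing_cols = [c for c in OBSERVATION_COLUMNS if c not in header]
        if missing_cols:
            raise ParseError(f"{source}: header lacks columns {missing_cols}")
        idx = {c: header.index(c) for c in header}
        extra_maf_cols = [
            c
            for c in header
            if c.startswith("maf_")
            and c not in _MAF_COLUMN_TO_POP
        ]
        observations: list[VariantObservation] = []
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            try:
                observations.append(
                    _row_to_observation(row, idx, extra_maf_cols, lineno)
                )
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return observations


def _row_to_observation(
    row: Sequence[str],
    idx: Mapping[str, int],
    extra_maf_cols: Sequence[str],
    lineno: int,
) -> VariantObservation:
    def cell(col: str) -> str:
        return row[idx[col]]

    consequence_token = cell("consequence").strip()
    try:
        consequence = Consequence(consequence_token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: unknown consequence {consequence_token!r}"
        ) from None
    ref_mafs: dict[str, float] = {}
    for col in (*_MAF_COLUMN_TO_POP, *extra_maf_cols):
        raw = _opt(cell(col))
        if raw is None:
            continue
        try:
            maf = float(raw)
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric MAF in {col}: {raw!r}") from None
        if not 0.0 <= maf <= 1.0:
            raise ParseError(f"line {lineno}: MAF outside [0,1] in {col}: {maf}")
        pop = _MAF_COLUMN_TO_POP.get(col, col[len("maf_") :])
        ref_mafs[pop] = maf
    cadd_raw = _opt(cell("cadd_scaled"))
    acmg_raw = _opt(cell("acmg_class_published"))
    return VariantObservation(
        case_id=cell("case_id").strip(),
        sex=Sex(cell("sex").strip() or "unknown"),
        gestational_age=cell("ga").strip() or "-",
        gene=cell("gene").strip().upper(),
        key=VariantKey(
            chrom=cell("chrom").strip(),
            pos=int(cell("pos")),
            ref=cell("ref").strip(),
            alt=cell("alt").strip(),
        ),
        hgvs_c=_opt(cell("hgvs_c")) or "",
        hgvs_p=_opt(cell("hgvs_p")) or "",
        consequence=consequence,
        zygosity=Zygosity(cell("zygosity").strip()),
        dbsnp_id=_opt(cell("dbsnp")) or "",
        cadd_scaled=None if cadd_raw is None else float(cadd_raw),
        ref_mafs=ref_mafs,
        reported_in_affected=_parse_bool(cell("reported_in_affected"), "reported_in_affected", lineno),
        functional_evidence=_parse_bool(cell("functional_evidence"), "functional_evidence", lineno),
        conservation_low=_parse_bool(cell("conservation_low"), "conservation_low", lineno),
        splice_prediction_affected=_parse_bool(
            cell("splice_prediction_affected"), "splice_prediction_affected", lineno
        ),
        acmg_class_published=None if acmg_raw is None else int(acmg_raw),
    )


def write_observations(
    observations: Iterable[VariantObservation],
    dest: str | Path,
    extra_columns: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Write observations in the dialect read by :func:`read_observations`.

    Population names other than the two canonical ones get appended
    ``maf_<name>`` columns.  ``extra_columns`` appends additional per-row
    string columns (e.g. triage annotations).
    """
    observations = list(observations)
    extra_pops = sorted(
        {p for o in observations for p in o.ref_mafs} - set(_POP_TO_MAF_COLUMN)
    )
    header = list(OBSERVATION_COLUMNS) + [f"maf_{p}" for p in extra_pops]
    extras = dict(extra_columns or {})
    header += list(extras)
    with open(dest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for i, obs in enumerate(observations):
            row = [
                obs.case_id,
                obs.sex.value,
                obs.gestational_age,
                obs.gene,
                obs.key.chrom,
                str(obs.key.pos),
                obs.key.ref,
                obs.key.alt,
                obs.hgvs_c or "-",
                obs.hgvs_p or "-",
                obs.consequence.value,
                obs.zygosity.value,
                obs.dbsnp_id or "-",
                "-" if obs.cadd_scaled is None else repr(obs.cadd_scaled),
                _fmt_maf(obs.ref_mafs.get("ExAC_NFE")),
                _fmt_maf(obs.ref_mafs.get("SweGen")),
                "1" if obs.reported_in_affected else "0",
                "1" if obs.functional_evidence else "0",
                "1" if obs.conservation_low else "0",
                "1" if obs.splice_prediction_affected else "0",
                "-" if obs.acmg_class_published is None else str(obs.acmg_class_published),
            ]
            row += [_fmt_maf(obs.ref_mafs.get(p)) for p in extra_pops]
            row += [extras[col][i] for col in extras]
            writer.writerow(row)


def _fmt_maf(maf: float | None) -> str:
    return "-" if maf is None else repr(maf)


_VCF_REQUIRED_INFO = ("GENE", "CSQ", "CADD")


def read_vcf_observations(source: str | Path, case_id: str) -> list[VariantObservation]:
    """Read a minimal VCF (v4.2) carrying the annotations in INFO fields.

    Required INFO keys: ``GENE``, ``CSQ``, ``CADD``; optional: ``MAF_EXAC_NFE``,
    ``MAF_SWEGEN``, and flags ``EV_AFF``, ``EV_FUNC``, ``CONS_LOW``,
    ``SPLICE_HIT``.  GT ``1/1`` maps to homozygous, ``0/1``/``1/0`` to
    heterozygous.  Multi-allelic records must be pre-split.
    """
    from cyvcf2 import VCF

    observations: list[VariantObservation] = []
    vcf = VCF(str(source))
    try:
        for record in vcf:
            if len(record.ALT) != 1:
                raise ParseError(
                    f"{source}: multi-allelic record at {record.CHROM}:{record.POS}; "
                    "split before loading"
                )
            info = record.INFO
            for key in _VCF_REQUIRED_INFO:
                if info.get(key) is None:
                    raise ParseError(
                        f"{source}: record {record.CHROM}:{record.POS} lacks INFO/{key}"
                    )
            gt = record.genotypes[0][:2]
            zygosity = (
                Zygosity.HOMOZYGOUS if gt == [1, 1] else Zygosity.HETEROZYGOUS
            )
            ref_mafs: dict[str, float] = {}
            for info_key, pop in (("MAF_EXAC_NFE", "ExAC_NFE"), ("MAF_SWEGEN", "SweGen")):
                value = info.get(info_key)
                if value is not None:
                    ref_mafs[pop] = float(value)
            chrom = record.CHROM if record.CHROM.startswith("chr") else f"chr{record.CHROM}"
            observations.append(
                VariantObservation(
                    case_id=case_id,
                    gene=str(info.get("GENE")).upper(),
                    key=VariantKey(
                        chrom=chrom, pos=record.POS, ref=record.REF, alt=record.ALT[0]
                    ),
                    consequence=Consequence(str(info.get("CSQ"))),
                    zygosity=zygosity,
                    dbsnp_id=record.ID or "",
                    cadd_scaled=float(info.get("CADD")),
                    ref_mafs=ref_mafs,
                    reported_in_affected=bool(info.get("EV_AFF")),
                    functional_evidence=bool(info.get("EV_FUNC")),
                    conservation_low=bool(info.get("CONS_LOW")),
                    splice_prediction_affected=bool(info.get("SPLICE_HIT")),
                )
            )
    finally:
        vcf.close()
    return observations


def load_reference(
    source: str | Path, name: str, n_individuals: int
) -> ReferencePopulation:
    """Read a ``chrom pos ref alt maf`` table into a :class:`ReferencePopulation`."""
    maf_of: dict[VariantKey, float] = {}
    with open(source, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{source}: empty file, expected header") from None
        if header[:5] != ["chrom", "pos", "ref", "alt", "maf"]:
            raise ParseError(f"{source}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            try:
                key = VariantKey(row[0].strip(), int(row[1]), row[2].strip(), row[3].strip())
                maf = float(row[4])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{source}:{lineno}: {exc}") from exc
            if not 0.0 <= maf <= 1.0:
                raise ParseError(f"{source}:{lineno}: MAF outside [0,1]: {maf}")
            maf_of[key] = maf
    return ReferencePopulation(name=name, n_individuals=n_individuals, maf_of=maf_of)


def write_reference(ref: ReferencePopulation, dest: str | Path) -> None:
    with open(dest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "maf"])
        for key in sorted(ref.maf_of):
            writer.writerow([key.chrom, key.pos, key.ref, key.alt, repr(ref.maf_of[key])])


def reference_from_observations(
    observations: Iterable[VariantObservation], name: str, n_individuals: int
) -> ReferencePopulation:
    """Build a reference population from the per-observation MAF annotations.

    Each distinct variant key contributes the MAF annotated for population
    ``name``; keys never annotated for that population are simply absent.
    """
    maf_of: dict[VariantKey, float] = {}
    for obs in observations:
        maf = obs.ref_mafs.get(name)
        if maf is None:
            continue
        previous = maf_of.setdefault(obs.key, maf)
        if previous != maf:
            raise ValueError(
                f"conflicting {name} MAFs for {obs.key}: {previous} vs {maf}"
            )
    return ReferencePopulation(name=name, n_individuals=n_individuals, maf_of=maf_of)
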