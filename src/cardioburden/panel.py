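"""Gene panel model: 70 cardiac genes in two disease categories.

The packaged default panel contains 23 channelopathy-associated and 47
cardiomyopathy-associated genes.  Each gene carries a set of integer disease
association codes (1-15).  Genes whose codes span both disease groups take
the category of the panel section they are listed under; a caller-supplied
override map allows reassignment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Category",
    "PanelGene",
    "GenePanel",
    "PanelError",
    "UnknownGeneError",
    "load_panel",
    "write_panel",
    "default_panel",
]

_VALID_CODES = frozenset(range(1, 16))


class Category(str, enum.Enum):
    """Disease category of a panel gene."""

    CHANNELOPATHY = "channelopathy"
    CARDIOMYOPATHY = "cardiomyopathy"


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


class UnknownGeneError(KeyError):
    """Raised when a gene symbol is not part of the panel."""

    def __init__(self, symbol: str) -> None:
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"gene symbol not in panel: {self.symbol!r}"


@dataclass(frozen=True)
class PanelGene:
    """One gene of the panel with its category and disease codes."""

    symbol: str
    category: Category
    disease_codes: frozenset[int]

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelError("gene symbol must be non-empty")
        object.__setattr__(self, "symbol", self.symbol.upper())
        object.__setattr__(self, "category", Category(self.category))
        codes = frozenset(int(c) for c in self.disease_codes)
        if not codes:
            raise PanelError(f"{self.symbol}: disease_codes must be non-empty")
        if not codes <= _VALID_CODES:
            raise PanelError(
                f"{self.symbol}: disease codes outside 1-15: {sorted(codes - _VALID_CODES)}"
            )
        object.__setattr__(self, "disease_codes", codes)


@dataclass
class GenePanel:
    """An ordered collection of :class:`PanelGene` with unique symbols."""

    genes: list[PanelGene]
    name: str = "panel"
    _by_symbol: dict[str, PanelGene] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_symbol: dict[str, PanelGene] = {}
        for gene in self.genes:
            if gene.symbol in by_symbol:
                raise PanelError(f"duplicate gene symbol in panel: {gene.symbol}")
            by_symbol[gene.symbol] = gene
        self._by_symbol = by_symbol

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._by_symbol

    def __iter__(self):
        return iter(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenePanel):
            return NotImplemented
        return self.genes == other.genes and self.name == other.name

    def gene(self, symbol: str) -> PanelGene:
        try:
            return self._by_symbol[symbol.upper()]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def category_of(self, symbol: str) -> Category:
        """Return the disease category of ``symbol`` (case-insensitive)."""
        return self.gene(symbol).category

    def symbols(self, category: Category | None = None) -> list[str]:
        if category is None:
            return [g.symbol for g in self.genes]
        category = Category(category)
        return [g.symbol for g in self.genes if g.category is category]

    def count(self, category: Category) -> int:
        return len(self.symbols(category))


def load_panel(
    source: str | Path,
    name: str | None = None,
    overrides: Mapping[str, Category | str] | None = None,
) -> GenePanel:
    """Parse a tab-separated panel definition.

    Expected header: ``symbol<TAB>category<TAB>disease_codes`` with codes as
    comma-separated integers.  ``overrides`` maps gene symbols to replacement
    categories, applied after parsing.
    """
    source = Path(source)
    lines = source.read_text().splitlines()
    return _parse_panel(lines, name or source.stem, overrides, str(source))


def _parse_panel(
    lines: Iterable[str],
    name: str,
    overrides: Mapping[str, Category | str] | None,
    origin: str,
) -> GenePanel:
    lines = list(lines)
    if not lines:
        raise PanelError(f"{origin}: empty panel file (missing header)")
    header = lines[0].rstrip("\n").split("\t")
    if header != ["symbol", "category", "disease_codes"]:
        raise PanelError(f"{origin}:1: unexpected header {header!r}")
    override_map = {
        sym.upper(): Category(cat) for sym, cat in (overrides or {}).items()
    }
    genes: list[PanelGene] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise PanelError(f"{origin}:{lineno}: expected 3 fields, got {len(parts)}")
        symbol, category, codes = parts
        try:
            gene = PanelGene(
                symbol=symbol,
                category=override_map.get(symbol.upper(), Category(category)),
                disease_codes=frozenset(int(c) for c in codes.split(",")),
            )
        except (ValueError, PanelError) as exc:
            raise PanelError(f"{origin}:{lineno}: {exc}") from exc
        genes.append(gene)
    return GenePanel(genes=genes, name=name)


def write_panel(panel: GenePanel, dest: str | Path) -> None:
    """Write ``panel`` in the format accepted by :func:`load_panel`."""
    with open(dest, "w") as fh:
        fh.write("symbol\tcategory\tdisease_codes\n")
        for gene in panel:
            codes = ",".join(str(c) for c in sorted(gene.disease_codes))
            fh.write(f"{gene.symbol}\t{gene.category.value}\t{codes}\n")


def default_panel(
    overrides: Mapping[str, Category | str] | None = None,
) -> GenePanel:
    """Load the packaged 70-gene cardiac panel."""
    text = (
        resources.files("cardioburden").joinpath("data/panel_genes.tsv").read_text()
    )
    return _parse_panel(
        text.splitlines(), "cardiac-70", overrides, "packaged panel_genes.tsv"
    )
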