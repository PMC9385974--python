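"""Reading, normalising, merging and writing gene lists.

Gene symbols arrive from heterogeneous origins with inconsistent casing
("BAX", "Bax", "bax"). All comparisons in this package are performed on a
normalised form (mouse-style casing: first letter upper, rest lower), while
the first-seen original spelling is retained for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CategoryMismatchError, EmptyGeneSetError, InvalidSymbolError

#: Allowed gene-set categories.
CATEGORIES = ("apoptosis", "necroptosis", "pyroptosis", "other")


def normalize_symbol(raw: str) -> str:
    """Return the canonical spelling of a gene symbol.

    Casing follows the mouse convention (``"BAX" -> "Bax"``). Identifiers
    containing a ``miR-`` fragment or starting with ``lncRNA`` are
    non-coding-RNA names and are returned with whitespace trimmed only.

    Raises
    ------
    InvalidSymbolError
        If the input is empty or whitespace-only.
    """
    symbol = (raw or "").strip()
    if not symbol:
        raise InvalidSymbolError("empty or whitespace-only gene symbol")
    lowered = symbol.lower()
    if "mir-" in lowered or lowered.startswith("lncrna"):
        return symbol
    return symbol[0].upper() + symbol[1:].lower()


@dataclass
class GeneSet:
    """An ordered, duplicate-free collection of normalised gene symbols.

    Attributes
    ----------
    name : str
        Human-readable set name.
    category : str
        One of :data:`CATEGORIES`.
    provenance : frozenset[str]
        Labels describing where the symbols came from.
    symbols : tuple[str, ...]
        Normalised symbols in first-seen order.
    spellings : dict[str, str]
        Normalised symbol -> first original spelling encountered.
    """

    name: str
    category: str
    provenance: frozenset = field(default_factory=frozenset)
    symbols: tuple = ()
    spellings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise CategoryMismatchError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        self.provenance = frozenset(self.provenance)
        self.symbols = tuple(self.symbols)
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidSymbolError(f"duplicate symbols in gene set {self.name!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    @classmethod
    def from_symbols(
        cls,
        name: str,
        category: str,
        raw_symbols: Iterable[str],
        provenance: Iterable[str] = (),
    ) -> "GeneSet":
        """Build a set from raw symbols, normalising and deduplicating."""
        symbols: list[str] = []
        seen: set[str] = set()
        spellings: dict[str, str] = {}
        for raw in raw_symbols:
            norm = normalize_symbol(raw)
            if norm not in seen:
                seen.add(norm)
                symbols.append(norm)
                spellings[norm] = raw.strip()
        return cls(
            name=name,
            category=category,
            provenance=frozenset(provenance),
            symbols=tuple(symbols),
            spellings=spellings,
        )


def read_gene_list(path, category: str, provenance: str) -> GeneSet:
    """Read a gene list from a one-symbol-per-line file or GMT row(s).

    Lines starting with ``#`` and blank lines are skipped. Lines containing
    tabs are treated as GMT rows (name, description, members...); their
    member fields are pooled.

    Raises
    ------
    EmptyGeneSetError
        If no symbols were parsed.
    """
    path = Path(path)
    raw_symbols: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            fields = line.split("\t")
            raw_symbols.extend(f for f in fields[2:] if f.strip())
        else:
            raw_symbols.append(line)
    if not raw_symbols:
        raise EmptyGeneSetError(f"no gene symbols parsed from {path}")
    return GeneSet.from_symbols(
        name=path.stem, category=category, raw_symbols=raw_symbols,
        provenance=[provenance],
    )


def merge_gene_sets(sets: Sequence[GeneSet], name: str) -> GeneSet:
    """Union a list of same-category gene sets, deduplicating symbols.

    Symbols keep first-seen order across the inputs; provenance labels are
    unioned. Merging is commutative/associative/idempotent up to ordering.

    Raises
    ------
    CategoryMismatchError
        If the inputs do not all share one category.
    EmptyGeneSetError
        If no sets are given.
    """
    if not sets:
        raise EmptyGeneSetError("cannot merge zero gene sets")
    categories = {s.category for s in sets}
    if len(categories) != 1:
        raise CategoryMismatchError(
            f"cannot merge sets of mixed categories: {sorted(categories)}"
        )
    symbols: list[str] = []
    seen: set[str] = set()
    spellings: dict[str, str] = {}
    provenance: set[str] = set()
    for s in sets:
        provenance |= s.provenance
        for sym in s.symbols:
            if sym not in seen:
                seen.add(sym)
                symbols.append(sym)
                spellings[sym] = s.spellings.get(sym, sym)
    return GeneSet(
        name=name,
        category=next(iter(categories)),
        provenance=frozenset(provenance),
        symbols=tuple(symbols),
        spellings=spellings,
    )


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    """Write gene sets as GMT (name, description, members...)."""
    lines = []
    for s in sets:
        desc = f"category={s.category};provenance={','.join(sorted(s.provenance))}"
        lines.append("\t".join([s.name, desc, *s.symbols]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt_rows(path) -> list[tuple[str, str, list[str]]]:
    """Read raw GMT rows as (name, description, member symbols)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise EmptyGeneSetError(f"GMT row with <3 fields in {path}: {line!r}")
        rows.append((fields[0], fields[1], [f for f in fields[2:] if f.strip()]))
    return rows
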