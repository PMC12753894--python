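"""Curated RHO GTPase pathway gene catalog: loading, validation, census.

The catalog is the anchor of every downstream stage. Each entry records a
gene symbol, one or more functional categories (GTPase, GEF, GAP, GDI,
kinase effector, non-kinase signaling element), its coding length in base
pairs, GC fraction, and — for GEFs and GAPs only — the GTPase substrate the
regulator acts on (RHOA, RAC1, CDC42, or UNKNOWN when unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

CATEGORIES = frozenset(
    {"GTPASE", "GEF", "GAP", "GDI", "KINASE_EFFECTOR", "NONKINASE_ELEMENT"}
)
SUBSTRATES = frozenset({"RHOA", "RAC1", "CDC42", "UNKNOWN"})

#: Categories whose members may carry a known GTPase substrate.
REGULATOR_CATEGORIES = frozenset({"GEF", "GAP"})


class CatalogError(ValueError):
    """Raised when a catalog file violates the schema or its invariants."""


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One catalog gene with its functional annotation."""

    symbol: str
    categories: frozenset[str]
    coding_length: int
    gc_fraction: float
    substrate: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogError("empty gene symbol")
        if not self.categories:
            raise CatalogError(f"{self.symbol}: at least one category required")
        unknown = set(self.categories) - CATEGORIES
        if unknown:
            raise CatalogError(
                f"{self.symbol}: unknown category token(s) {sorted(unknown)}"
            )
        if self.coding_length <= 0:
            raise CatalogError(
                f"{self.symbol}: coding_length must be positive, got "
                f"{self.coding_length}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise CatalogError(
                f"{self.symbol}: gc_fraction must lie in [0, 1], got "
                f"{self.gc_fraction}"
            )
        if self.substrate not in SUBSTRATES:
            raise CatalogError(
                f"{self.symbol}: unknown substrate {self.substrate!r}"
            )
        if self.substrate != "UNKNOWN" and not (
            self.categories & REGULATOR_CATEGORIES
        ):
            raise CatalogError(
                f"{self.symbol}: substrate {self.substrate} only allowed for "
                "GEF/GAP entries"
            )


@dataclass(frozen=True)
class CategoryCensus:
    """Per-category gene counts plus multi-membership bookkeeping."""

    per_category: dict[str, int]
    dual_membership_count: int
    unique_total: int


@dataclass
class PathwayCatalog:
    """Ordered collection of :class:`GeneCatalogEntry` with unique symbols."""

    entries: list[GeneCatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.symbol in seen:
                raise CatalogError(f"duplicate gene symbol: {entry.symbol}")
            seen.add(entry.symbol)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneCatalogEntry]:
        return iter(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def lengths(self) -> pd.Series:
        """Coding lengths indexed by symbol, in file order."""
        return pd.Series(
            [e.coding_length for e in self.entries],
            index=self.symbols,
            name="coding_length_bp",
        )

    def gc(self) -> pd.Series:
        return pd.Series(
            [e.gc_fraction for e in self.entries],
            index=self.symbols,
            name="gc_fraction",
        )

    def in_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise CatalogError(f"unknown category token {category!r}")
        return [e.symbol for e in self.entries if category in e.categories]

    def substrate_of(self, symbol: str) -> str:
        for e in self.entries:
            if e.symbol == symbol:
                return e.substrate
        raise KeyError(symbol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "symbol": self.symbols,
                "categories": [";".join(sorted(e.categories)) for e in self.entries],
                "coding_length_bp": [e.coding_length for e in self.entries],
                "gc_fraction": [e.gc_fraction for e in self.entries],
                "substrate": [e.substrate for e in self.entries],
            }
        )


REQUIRED_COLUMNS = (
    "symbol",
    "categories",
    "coding_length_bp",
    "gc_fraction",
)


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load the pathway-gene catalog from a TSV file.

    Expected columns: ``symbol``, ``categories`` (semicolon-joined tokens),
    ``coding_length_bp``, ``gc_fraction``, and optional ``substrate``.
    Lines starting with ``#`` are ignored. Entry order is preserved.

    Raises
    ------
    CatalogError
        On missing columns, duplicate symbols, unknown category or substrate
        tokens, or out-of-range numeric fields.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog file missing column(s): {missing}")
    entries = []
    for row in df.itertuples(index=False):
        categories = frozenset(
            tok.strip().upper() for tok in str(row.categories).split(";") if tok.strip()
        )
        substrate = "UNKNOWN"
        if "substrate" in df.columns:
            raw = getattr(row, "substrate")
            if isinstance(raw, str) and raw.strip():
                substrate = raw.strip().upper()
        entries.append(
            GeneCatalogEntry(
                symbol=str(row.symbol).strip(),
                categories=categories,
                coding_length=int(row.coding_length_bp),
                gc_fraction=float(row.gc_fraction),
                substrate=substrate,
            )
        )
    return PathwayCatalog(entries)


def write_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def category_census(catalog: PathwayCatalog | Iterable[GeneCatalogEntry]) -> CategoryCensus:
    """Tally genes per functional category.

    ``unique_total`` is the number of distinct gene symbols; genes carrying
    several categories are counted once per category, so the per-category
    sum exceeds ``unique_total`` by the number of extra memberships.
    """
    entries = list(catalog)
    per_category = {cat: 0 for cat in sorted(CATEGORIES)}
    dual = 0
    for e in entries:
        for cat in e.categories:
            per_category[cat] += 1
        if len(e.categories) > 1:
            dual += 1
    return CategoryCensus(
        per_category=per_category,
        dual_membership_count=dual,
        unique_total=len({e.symbol for e in entries}),
    )
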