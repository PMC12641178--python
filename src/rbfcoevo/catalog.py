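"""Curated gene catalogue of ribosome biogenesis factors (RBFs) and
ribosomal proteins (RPs).

The catalogue defines the columns of every presence/absence matrix in the
pipeline.  Each entry carries a short gene symbol, its role (``RBF`` or
``RP``), a functional category and an optional set of KEGG orthology (KO)
identifiers used for annotation matching.  The packaged default catalogue
holds 100 RBFs across six functional categories plus 54 RPs; it is a
best-effort reconstruction assembled from published gene lists and standard
E. coli nomenclature, with KO identifiers filled in where unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

ROLES = frozenset({"RBF", "RP"})
CATEGORIES = frozenset(
    {"GTPase", "maturation", "ribonuclease", "helicase", "modification",
     "other", "chaperone"}
)


class CatalogError(ValueError):
    """Raised when a catalogue file fails validation."""


@dataclass(frozen=True)
class GeneEntry:
    """One catalogue gene: symbol, role, functional category, KO ids."""

    gene_id: str
    role: str
    category: str
    ko_ids: frozenset[str] = field(default_factory=frozenset)

    def identifiers(self) -> frozenset[str]:
        """All identifiers that count as a hit for this gene."""
        return self.ko_ids | {self.gene_id}


@dataclass(frozen=True)
class GeneCatalog:
    """Ordered, validated collection of :class:`GeneEntry`.

    Column order of downstream matrices follows entry order.
    """

    entries: tuple[GeneEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise CatalogError("no entries")
        seen: set[str] = set()
        for e in self.entries:
            if e.gene_id in seen:
                raise CatalogError(f"duplicate gene_id: {e.gene_id!r}")
            seen.add(e.gene_id)
            if e.role not in ROLES:
                raise CatalogError(
                    f"unknown role {e.role!r} for gene {e.gene_id!r}")
            if e.category not in CATEGORIES:
                raise CatalogError(
                    f"unknown category {e.category!r} for gene {e.gene_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def subset(self, role: str) -> "GeneCatalog":
        """Catalogue restricted to one role (``RBF`` or ``RP``)."""
        if role not in ROLES:
            raise CatalogError(f"unknown role {role!r}")
        return GeneCatalog(tuple(e for e in self.entries if e.role == role))

    def genes_by_role(self, role: str) -> list[str]:
        return self.subset(role).gene_ids

    def entry(self, gene_id: str) -> GeneEntry:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e
        raise KeyError(gene_id)

    def identifier_map(self) -> dict[str, set[str]]:
        """Map every known identifier (symbol or KO) to the gene ids it hits.

        A KO shared by two genes marks both present.
        """
        m: dict[str, set[str]] = {}
        for e in self.entries:
            for ident in e.identifiers():
                m.setdefault(ident, set()).add(e.gene_id)
        return m


def load_catalog(path: str | Path) -> GeneCatalog:
    """Read a catalogue TSV with columns gene_id, role, category, ko_ids.

    ``ko_ids`` is semicolon-separated and may be blank; matching then falls
    back to the gene symbol alone.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "role", "category", "ko_ids"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise CatalogError("no entries")
    entries = tuple(
        GeneEntry(
            gene_id=row.gene_id.strip(),
            role=row.role.strip(),
            category=row.category.strip(),
            ko_ids=frozenset(k for k in row.ko_ids.split(";") if k.strip()),
        )
        for row in df.itertuples()
    )
    return GeneCatalog(entries)


def default_catalog() -> GeneCatalog:
    """The packaged 100-RBF + 54-RP catalogue."""
    with resources.as_file(
        resources.files("rbfcoevo.data").joinpath("catalog.tsv")
    ) as p:
        return load_catalog(p)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    rows = [
        {
            "gene_id": e.gene_id,
            "role": e.role,
            "category": e.category,
            "ko_ids": ";".join(sorted(e.ko_ids)),
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
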