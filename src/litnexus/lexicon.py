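"""Gene and drug dictionaries with surface-form normalisation.

A lexicon maps every way an entity can be written in prose — primary symbol,
full names, alias symbols, UniGene IDs for genes; preferred name and
synonyms for drugs — onto one canonical identifier, so that an article
mentioning "Her-2", "HER2" or "Hs.446352" is attributed to the same gene.
Matching downstream is exact (dictionary lookup), never fuzzy; the only
forgiveness is case and whitespace, applied here by :func:`normalize_surface`.

The table format is a project TSV dialect: UTF-8, tab-separated columns,
``|`` separating values inside a cell, ``#`` starting comment lines.

Ambiguity handling: surface forms shorter than :data:`MIN_FORM_LENGTH` or in
the stoplist are excluded from the index (short symbols like "ER" and common
words that double as aliases generate far more noise than signal); a form
claimed by several entries is assigned to the lexicographically smallest
canonical id, deterministically and independent of row order, and the
conflict is recorded.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "MIN_FORM_LENGTH",
    "DEFAULT_STOPLIST",
    "GeneEntry",
    "DrugEntry",
    "Lexicon",
    "LexiconError",
    "normalize_surface",
    "load_gene_lexicon",
    "load_drug_lexicon",
    "lookup",
]

#: Normalised forms shorter than this are excluded from the surface index.
MIN_FORM_LENGTH = 3

#: Common English words that collide with real gene alias symbols.
DEFAULT_STOPLIST = frozenset({
    "was", "has", "had", "can", "all", "and", "the", "for", "not", "but",
    "its", "per", "via", "one", "two", "set", "act", "aim", "arm", "cell",
})


class LexiconError(ValueError):
    """Raised on malformed lexicon tables (bad columns, duplicate ids)."""


def normalize_surface(s: str) -> str:
    """Canonical key for a surface form.

    Unicode NFC, case-folded, internal whitespace collapsed to single
    spaces, outer whitespace stripped.  Hyphens and periods are preserved:
    "Her-2" and "Hs.446352" keep their shape.
    """
    if not s or not s.strip():
        raise ValueError("surface form must be non-empty")
    return " ".join(unicodedata.normalize("NFC", s).casefold().split())


@dataclass(frozen=True)
class GeneEntry:
    gene_id: str
    symbol: str
    full_names: tuple[str, ...] = ()
    aliases: tuple[str, ...] = ()
    unigene_ids: tuple[str, ...] = ()

    @property
    def canonical_id(self) -> str:
        return self.gene_id

    def surface_forms(self) -> tuple[str, ...]:
        return (self.symbol, *self.full_names, *self.aliases, *self.unigene_ids)


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()

    @property
    def canonical_id(self) -> str:
        return self.drug_id

    def surface_forms(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


@dataclass
class Lexicon:
    """Entries plus the normalised surface-form index.

    ``excluded`` records (form, entry id, reason) for stoplisted/short forms;
    ``conflicts`` records (form, winning id, losing ids) for forms claimed by
    multiple entries.
    """

    kind: str  # "gene" | "drug"
    entries: list
    surface_index: dict[str, str]
    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    conflicts: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    def lookup(self, surface: str) -> str | None:
        try:
            key = normalize_surface(surface)
        except ValueError:
            return None
        return self.surface_index.get(key)

    def __len__(self) -> int:
        return len(self.entries)


def lookup(lex: Lexicon, surface: str) -> str | None:
    """Canonical id for *surface*, or None.  Exact (never partial) matching."""
    return lex.lookup(surface)


def _read_rows(path: str | Path, n_columns: int) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if all(not cell.strip() for cell in row):
                continue
            if len(row) < n_columns:
                row = row + [""] * (n_columns - len(row))
            rows.append([cell.strip() for cell in row[:n_columns]])
    return rows


def _split_cell(cell: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in cell.split("|") if part.strip())


def _build_index(entries, kind: str, stoplist) -> Lexicon:
    stop = {normalize_surface(w) for w in stoplist} if stoplist else set()
    claims: dict[str, set[str]] = {}
    excluded: list[tuple[str, str, str]] = []
    for entry in entries:
        for form in entry.surface_forms():
            if not form:
                continue
            norm = normalize_surface(form)
            if len(norm) < MIN_FORM_LENGTH:
                excluded.append((form, entry.canonical_id, "below minimum length"))
                continue
            if norm in stop:
                excluded.append((form, entry.canonical_id, "stoplisted"))
                continue
            claims.setdefault(norm, set()).add(entry.canonical_id)
    index: dict[str, str] = {}
    conflicts: list[tuple[str, str, tuple[str, ...]]] = []
    for norm in sorted(claims):
        owners = sorted(claims[norm])
        index[norm] = owners[0]
        if len(owners) > 1:
            conflicts.append((norm, owners[0], tuple(owners[1:])))
    return Lexicon(kind=kind, entries=list(entries), surface_index=index,
                   excluded=excluded, conflicts=conflicts)


def load_gene_lexicon(table: str | Path, stoplist=DEFAULT_STOPLIST) -> Lexicon:
    """Load a gene lexicon TSV: gene_id, symbol, full_names, aliases, unigene_ids.

    The last three columns are ``|``-separated lists.  Symbol, every name,
    every alias and every UniGene ID all enter the surface index — they are
    treated as equal ways of writing the gene.
    """
    entries = []
    seen_ids: set[str] = set()
    for row in _read_rows(table, 5):
        gene_id, symbol, names, aliases, unigenes = row
        if not gene_id or not symbol:
            raise LexiconError(f"gene row missing id or symbol: {row!r}")
        if gene_id in seen_ids:
            raise LexiconError(f"duplicate gene_id {gene_id!r}")
        seen_ids.add(gene_id)
        entries.append(GeneEntry(
            gene_id=gene_id,
            symbol=symbol,
            full_names=_split_cell(names),
            aliases=_split_cell(aliases),
            unigene_ids=_split_cell(unigenes),
        ))
    return _build_index(entries, "gene", stoplist)


def load_drug_lexicon(table: str | Path, stoplist=DEFAULT_STOPLIST) -> Lexicon:
    """Load a drug lexicon TSV: drug_id, preferred_name, synonyms."""
    entries = []
    seen_ids: set[str] = set()
    for row in _read_rows(table, 3):
        drug_id, name, synonyms = row
        if not drug_id or not name:
            raise LexiconError(f"drug row missing id or name: {row!r}")
        if drug_id in seen_ids:
            raise LexiconError(f"duplicate drug_id {drug_id!r}")
        seen_ids.add(drug_id)
        entries.append(DrugEntry(
            drug_id=drug_id,
            preferred_name=name,
            synonyms=_split_cell(synonyms),
        ))
    return _build_index(entries, "drug", stoplist)
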