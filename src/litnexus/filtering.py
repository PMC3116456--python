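"""Dictionary NER over titles and abstracts, and the gene-drug co-mention filter.

A mention is an occurrence of a lexicon surface form bounded on both sides
by a non-alphanumeric character or the string edge, matched
case-insensitively.  Hyphens, periods and slashes inside a form are matched
literally ("Her-2", "Hs.446352", "Her-2/neu"), but act as boundaries at the
edges of a match — so "BRCA1" is found in "BRCA1-deficient" while "BRCA"
never matches inside "BRCA1".  At overlapping candidate positions the
leftmost match wins, and among forms starting at the same position the
longest wins; mentions from one lexicon never overlap each other.

An article survives :func:`filter_corpus` iff its title or abstract contains
at least one gene mention AND at least one drug mention; one
:class:`~litnexus.archive.NexusRecord` is emitted per distinct
(article, gene, drug) combination.  No attempt is made to decide whether the
gene and drug are related — they need not even share a sentence; judging the
relationship is left to the reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .archive import NexusRecord
from .lexicon import Lexicon, normalize_surface
from .medline import ArticleRecord

__all__ = ["Mention", "compile_phrase", "find_mentions", "filter_corpus"]

_BOUNDARY_BEFORE = r"(?<![A-Za-z0-9])"
_BOUNDARY_AFTER = r"(?![A-Za-z0-9])"

_FIELDS = ("title", "abstract")


def _phrase_body(form: str) -> str:
    # tolerate any whitespace run where the form has a single space
    return r"\s+".join(re.escape(part) for part in form.split())


def compile_phrase(form: str) -> re.Pattern:
    """Whole-phrase, word-boundary, case-insensitive matcher for one form."""
    if not form or not form.strip():
        raise ValueError("phrase must be non-empty")
    return re.compile(
        _BOUNDARY_BEFORE + _phrase_body(form) + _BOUNDARY_AFTER, re.IGNORECASE
    )


_matcher_cache: dict[int, tuple[int, re.Pattern]] = {}


def _lexicon_matcher(lex: Lexicon) -> re.Pattern:
    """One alternation over all index forms, longest alternatives first.

    ``finditer`` with a longest-first alternation yields exactly the
    leftmost-longest non-overlapping matches.  The compiled pattern is cached
    per lexicon object (keyed on identity + index size, so a rebuilt index
    invalidates the cache).
    """
    cached = _matcher_cache.get(id(lex))
    if cached is not None and cached[0] == len(lex.surface_index):
        return cached[1]
    forms = sorted(lex.surface_index, key=lambda f: (-len(f), f))
    if forms:
        body = "(?:" + "|".join(_phrase_body(f) for f in forms) + ")"
    else:
        body = r"(?!x)x"  # matches nothing
    pattern = re.compile(_BOUNDARY_BEFORE + body + _BOUNDARY_AFTER, re.IGNORECASE)
    _matcher_cache[id(lex)] = (len(lex.surface_index), pattern)
    return pattern


@dataclass(frozen=True)
class Mention:
    """One located lexicon hit: ``text[start:end] == surface``."""

    surface: str
    canonical_id: str
    field: str  # "title" | "abstract"
    start: int
    end: int


def find_mentions(record: ArticleRecord, lex: Lexicon) -> list[Mention]:
    """All lexicon mentions in the record's title and abstract.

    Sorted by (field, start) with title before abstract.
    """
    matcher = _lexicon_matcher(lex)
    mentions: list[Mention] = []
    for field_name in _FIELDS:
        text = getattr(record, field_name)
        for m in matcher.finditer(text):
            surface = m.group(0)
            canonical = lex.surface_index.get(normalize_surface(surface))
            if canonical is None:  # whitespace variant not in index; cannot happen
                continue
            mentions.append(
                Mention(
                    surface=surface,
                    canonical_id=canonical,
                    field=field_name,
                    start=m.start(),
                    end=m.end(),
                )
            )
    return mentions


def _first_surfaces(mentions: list[Mention]) -> dict[str, str]:
    """canonical id -> surface of its first mention (document order)."""
    surfaces: dict[str, str] = {}
    for m in mentions:
        surfaces.setdefault(m.canonical_id, m.surface)
    return surfaces


def filter_corpus(
    records: list[ArticleRecord], genes: Lexicon, drugs: Lexicon
) -> list[NexusRecord]:
    """Keep articles co-mentioning >=1 gene and >=1 drug; emit per-pair records.

    Output holds one record per distinct (pmid, gene_id, drug_id), sorted by
    that key; the stored surfaces are those of each entity's first mention.
    """
    out: list[NexusRecord] = []
    for record in records:
        gene_surfaces = _first_surfaces(find_mentions(record, genes))
        drug_surfaces = _first_surfaces(find_mentions(record, drugs))
        if not gene_surfaces or not drug_surfaces:
            continue
        authors = record.first_author
        if record.last_author and record.last_author != record.first_author:
            authors = f"{record.first_author}; {record.last_author}"
        for gene_id in sorted(gene_surfaces):
            for drug_id in sorted(drug_surfaces):
                out.append(
                    NexusRecord(
                        pmid=record.pmid,
                        gene_id=gene_id,
                        gene_surface=gene_surfaces[gene_id],
                        drug_id=drug_id,
                        drug_surface=drug_surfaces[drug_id],
                        authors=authors,
                        pub_date=record.pub_date,
                        journal=record.journal,
                        title=record.title,
                    )
                )
    out.sort(key=lambda r: (int(r.pmid), r.gene_id, r.drug_id))
    return out
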