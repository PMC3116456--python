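"""Exact-match retrieval over a loaded archive.

A query is one or more include phrases (disease, gene or drug names) plus
optional exclusion keywords — the "negative control".  Matching is exact
whole-phrase, word-boundary, case-insensitive, over the record's title,
abstract and matched gene/drug surfaces; it is deliberately NOT stemmed or
fuzzy: "BRCA" does not retrieve "BRCA1".  Exclusions apply to the title and
abstract (an abstract containing an excluded keyword removes the record).

Results are ordered newest-first and carry highlight spans for the include
terms plus outbound links (PubMed citation, drug information, Gene
Ontology search); the drug/GO link templates are configurable.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field

from .archive import NexusRecord, pubmed_link
from .filtering import compile_phrase
from .lexicon import normalize_surface

__all__ = [
    "Query",
    "QueryResult",
    "InvalidQueryError",
    "search",
    "pubmed_link",
    "drug_link",
    "go_link",
    "DRUG_LINK_TEMPLATE",
    "GO_LINK_TEMPLATE",
]

DRUG_LINK_TEMPLATE = "https://www.drugs.com/search.php?searchterm={term}"
GO_LINK_TEMPLATE = "https://amigo.geneontology.org/amigo/search/ontology?q={term}"


class InvalidQueryError(ValueError):
    """Raised for queries with no usable include term."""


def drug_link(drug_name: str, template: str = DRUG_LINK_TEMPLATE) -> str:
    """Drug-information URL for a drug name (URL-encoded)."""
    if not drug_name or not drug_name.strip():
        raise ValueError("drug name must be non-empty")
    return template.format(term=urllib.parse.quote(drug_name.strip()))


def go_link(gene_symbol: str, template: str = GO_LINK_TEMPLATE) -> str:
    """Gene Ontology search URL for a gene symbol (URL-encoded)."""
    if not gene_symbol or not gene_symbol.strip():
        raise ValueError("gene symbol must be non-empty")
    return template.format(term=urllib.parse.quote(gene_symbol.strip()))


@dataclass(frozen=True)
class Query:
    """Include phrases plus exclusion keywords.

    ``conjunctive=True`` requires every include term to occur (the behaviour
    of filling several form fields at once); ``False`` accepts any one.
    """

    include_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()
    conjunctive: bool = True


@dataclass
class QueryResult:
    """Matching records with per-record highlight spans and outbound links."""

    records: list[NexusRecord] = field(default_factory=list)
    highlights: list[list[tuple[str, int, int]]] = field(default_factory=list)
    links: list[dict[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _normalized_terms(terms) -> list[str]:
    out = []
    for term in terms:
        try:
            norm = normalize_surface(term)
        except ValueError:
            continue
        out.append(norm)
    return out


def search(
    records: list[NexusRecord],
    abstracts: dict[str, str],
    q: Query,
) -> QueryResult:
    """Run a query against archive records joined with their abstracts.

    A record matches iff every (conjunctive) or any (disjunctive) include
    term occurs in title ∪ abstract ∪ gene surface ∪ drug surface, and no
    exclude term occurs in title ∪ abstract.  Results are ordered by
    publication date descending, then PMID ascending.
    """
    include = _normalized_terms(q.include_terms)
    if not include:
        raise InvalidQueryError("query needs at least one non-empty include term")
    exclude = _normalized_terms(q.exclude_terms)
    inc_patterns = [compile_phrase(t) for t in include]
    exc_patterns = [compile_phrase(t) for t in exclude]

    matched: list[NexusRecord] = []
    for r in records:
        abstract = abstracts.get(r.pmid, "")
        searchable = (r.title, abstract, r.gene_surface, r.drug_surface)
        hits = [any(p.search(t) for t in searchable) for p in inc_patterns]
        ok = all(hits) if q.conjunctive else any(hits)
        if not ok:
            continue
        if any(p.search(r.title) or p.search(abstract) for p in exc_patterns):
            continue
        matched.append(r)

    matched.sort(key=lambda r: (-r.pub_date.toordinal(), int(r.pmid)))

    result = QueryResult()
    for r in matched:
        abstract = abstracts.get(r.pmid, "")
        spans: list[tuple[str, int, int]] = []
        for field_name, text in (("title", r.title), ("abstract", abstract)):
            for p in inc_patterns:
                for m in p.finditer(text):
                    spans.append((field_name, m.start(), m.end()))
        spans = sorted(set(spans), key=lambda s: (s[0] != "title", s[1], s[2]))
        result.records.append(r)
        result.highlights.append(spans)
        result.links.append({
            "pubmed": pubmed_link(r.pmid),
            "drug": drug_link(r.drug_surface),
            "go": go_link(r.gene_surface),
        })
    return result
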