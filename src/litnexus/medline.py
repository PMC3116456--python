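"""Parsing and serialisation of PubMed E-utilities XML payloads.

Two document kinds are handled:

* ESearch results (``<eSearchResult>``): a reported total ``Count`` plus a
  (possibly truncated) ``IdList`` of PMIDs.
* EFetch results (``<PubmedArticleSet>``): full citation records, from which
  only the fields the downstream archive needs are extracted — title,
  abstract, lead author, last (presumptive ranking) author, journal and
  publication date.

All text is normalised to Unicode NFC.  Serialisation back to
``PubmedArticleSet`` XML exists so that synthetic corpora round-trip through
the same parser the live harvester uses.
"""

from __future__ import annotations

import datetime
import re
import unicodedata
from dataclasses import dataclass

from lxml import etree

__all__ = [
    "ArticleRecord",
    "MedlineParseError",
    "parse_esearch_result",
    "parse_efetch_result",
    "article_to_element",
    "articles_to_xml",
    "esearch_result_xml",
]


class MedlineParseError(ValueError):
    """Raised when an E-utilities XML document cannot be interpreted."""


_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


@dataclass(frozen=True)
class ArticleRecord:
    """One parsed publication.

    ``first_author`` and ``last_author`` are rendered "Surname AB"; for a
    single-author article they are equal.  ``abstract`` may be empty —
    citations without abstracts are kept.
    """

    pmid: str
    title: str
    abstract: str
    first_author: str
    last_author: str
    journal: str
    pub_date: datetime.date

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be a non-empty digit string, got {self.pmid!r}")
        if not self.title:
            raise ValueError("title must be non-empty")


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _parse_xml(xml: bytes | str):
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    try:
        return etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise MedlineParseError(
            f"malformed XML at line {exc.position[0]}, column {exc.position[1]}: {exc.args[0]}"
        ) from exc


def parse_esearch_result(xml: bytes | str) -> tuple[int, list[str]]:
    """Extract ``(total Count, ordered PMIDs)`` from an ESearch document.

    ``Count`` is the server-reported total and may exceed the number of IDs
    actually returned when the page was truncated at ``retmax``.
    """
    root = _parse_xml(xml)
    idlist = root.find(".//IdList")
    if idlist is None:
        raise MedlineParseError("ESearch result has no IdList element")
    pmids = [(el.text or "").strip() for el in idlist.findall("Id")]
    pmids = [p for p in pmids if p]
    count_text = root.findtext("Count")
    count = int(count_text) if count_text is not None else len(pmids)
    return count, pmids


def _text_of(el) -> str:
    return _nfc("".join(el.itertext())).strip()


def _author_name(author_el) -> str | None:
    """Render one <Author> as "Surname AB"; corporate authors yield None."""
    surname = author_el.findtext("LastName")
    if not surname:  # CollectiveName or malformed entry: skip
        return None
    initials = author_el.findtext("Initials")
    name = _nfc(surname).strip()
    if initials:
        name += " " + _nfc(initials).strip()
    return name


def _parse_pub_date(article_el) -> datetime.date:
    """Resolve a PubDate (or MedlineDate range) to a calendar date.

    Missing month defaults to January, missing day to 1; a MedlineDate range
    such as "1998 Dec-1999 Jan" resolves to its first parseable year/month.
    """
    pd = article_el.find(".//Journal/JournalIssue/PubDate")
    year = month = day = None
    if pd is not None:
        y = pd.findtext("Year")
        if y and y.strip().isdigit():
            year = int(y)
            m = (pd.findtext("Month") or "").strip()
            if m.isdigit():
                month = int(m)
            elif m[:3].lower() in _MONTHS:
                month = _MONTHS[m[:3].lower()]
            d = (pd.findtext("Day") or "").strip()
            if d.isdigit():
                day = int(d)
        else:
            medline_date = pd.findtext("MedlineDate") or ""
            ym = re.search(r"(\d{4})(?:\s+([A-Za-z]{3}))?", medline_date)
            if ym:
                year = int(ym.group(1))
                if ym.group(2) and ym.group(2).lower() in _MONTHS:
                    month = _MONTHS[ym.group(2).lower()]
    if year is None:
        raise MedlineParseError("article has no parseable publication year")
    return datetime.date(year, month or 1, day or 1)


def parse_efetch_result(
    xml: bytes | str, warnings: list[str] | None = None
) -> list[ArticleRecord]:
    """Parse a ``PubmedArticleSet`` into :class:`ArticleRecord` objects.

    Articles lacking a title or PMID are rejected; each rejection appends one
    entry to *warnings* (when given), so ``len(input) - len(output)`` always
    equals the number of warnings.  Articles without an abstract are accepted
    with an empty abstract.  The abstract is the space-joined concatenation of
    all ``AbstractText`` blocks; structured-abstract labels are dropped.
    """
    root = _parse_xml(xml)
    records: list[ArticleRecord] = []
    for art in root.iter("PubmedArticle"):
        pmid = (art.findtext(".//MedlineCitation/PMID") or "").strip()
        title_el = art.find(".//Article/ArticleTitle")
        title = _text_of(title_el) if title_el is not None else ""
        if not pmid or not pmid.isdigit():
            if warnings is not None:
                warnings.append(f"article with title {title!r} has no valid PMID; skipped")
            continue
        if not title:
            if warnings is not None:
                warnings.append(f"PMID {pmid}: article has no title; skipped")
            continue
        abstract = " ".join(
            t for t in (_text_of(el) for el in art.findall(".//Abstract/AbstractText")) if t
        )
        authors = [
            name
            for name in (_author_name(a) for a in art.findall(".//AuthorList/Author"))
            if name
        ]
        first_author = authors[0] if authors else ""
        last_author = authors[-1] if authors else ""
        journal = _nfc(art.findtext(".//Journal/Title") or "").strip()
        try:
            pub_date = _parse_pub_date(art)
        except MedlineParseError:
            if warnings is not None:
                warnings.append(f"PMID {pmid}: no parseable publication date; skipped")
            continue
        records.append(
            ArticleRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                first_author=first_author,
                last_author=last_author,
                journal=journal,
                pub_date=pub_date,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Serialisation (used by the synthetic-corpus generator and round-trip tests)
# ---------------------------------------------------------------------------

def _split_author(name: str):
    parts = name.rsplit(" ", 1)
    if len(parts) == 2 and parts[1].isupper():
        return parts[0], parts[1]
    return name, None


def article_to_element(record: ArticleRecord):
    """Build a ``<PubmedArticle>`` element carrying the record's fields."""
    art = etree.Element("PubmedArticle")
    cit = etree.SubElement(art, "MedlineCitation")
    etree.SubElement(cit, "PMID").text = record.pmid
    article = etree.SubElement(cit, "Article")
    journal = etree.SubElement(article, "Journal")
    issue = etree.SubElement(journal, "JournalIssue")
    pubdate = etree.SubElement(issue, "PubDate")
    etree.SubElement(pubdate, "Year").text = str(record.pub_date.year)
    etree.SubElement(pubdate, "Month").text = str(record.pub_date.month)
    etree.SubElement(pubdate, "Day").text = str(record.pub_date.day)
    etree.SubElement(journal, "Title").text = record.journal
    etree.SubElement(article, "ArticleTitle").text = record.title
    if record.abstract:
        abstract = etree.SubElement(article, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = record.abstract
    names = [record.first_author]
    if record.last_author != record.first_author:
        names.append(record.last_author)
    names = [n for n in names if n]
    if names:
        alist = etree.SubElement(article, "AuthorList")
        for name in names:
            author = etree.SubElement(alist, "Author")
            surname, initials = _split_author(name)
            etree.SubElement(author, "LastName").text = surname
            if initials:
                etree.SubElement(author, "Initials").text = initials
    return art


def articles_to_xml(records: list[ArticleRecord]) -> bytes:
    """Serialise records as one ``PubmedArticleSet`` document (UTF-8 bytes)."""
    root = etree.Element("PubmedArticleSet")
    for record in records:
        root.append(article_to_element(record))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def esearch_result_xml(count: int, pmids: list[str]) -> bytes:
    """Serialise an ESearch-style result document listing *pmids*."""
    root = etree.Element("eSearchResult")
    etree.SubElement(root, "Count").text = str(count)
    etree.SubElement(root, "RetMax").text = str(len(pmids))
    idlist = etree.SubElement(root, "IdList")
    for pmid in pmids:
        etree.SubElement(idlist, "Id").text = pmid
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")
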