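"""The flat-file archive: one pipe-delimited line per (article, gene, drug) triple.

The archive is deliberately primitive — a single text file is the whole
database.  Field order follows the original record layout::

    | PubMed link | gene | drug | authors | date | journal | title |

extended with two trailing columns carrying the canonical gene and drug ids
(the visible gene/drug columns store the surface form as matched in the
text, which is what a reader wants to see).  A ``#`` header comment states
the dialect version.  Pipes, backslashes and newlines inside fields are
backslash-escaped so serialisation is a true bijection.

Abstracts are not stored in the archive lines; they live in a JSON sidecar
keyed by PMID (:func:`write_abstracts` / :func:`read_abstracts`).
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "ARCHIVE_HEADER",
    "NexusRecord",
    "ArchiveFormatError",
    "pubmed_link",
    "format_line",
    "parse_line",
    "write_archive",
    "read_archive",
    "write_abstracts",
    "read_abstracts",
]

ARCHIVE_HEADER = (
    "# litnexus archive v1 "
    "| pubmed-link | gene | drug | authors | date | journal | title | gene-id | drug-id |"
)

_PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"


class ArchiveFormatError(ValueError):
    """Raised on malformed archive lines or duplicate record keys."""


def pubmed_link(pmid: str) -> str:
    """Canonical PubMed citation URL for a PMID."""
    if not pmid or not pmid.isdigit():
        raise ValueError(f"pmid must be a non-empty digit string, got {pmid!r}")
    return _PUBMED_URL.format(pmid=pmid)


@dataclass(frozen=True)
class NexusRecord:
    """One archived gene-drug co-mention: a candidate disease-gene-drug link."""

    pmid: str
    gene_id: str
    gene_surface: str
    drug_id: str
    drug_surface: str
    authors: str  # "First A; Last B"
    pub_date: datetime.date
    journal: str
    title: str

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise ValueError(f"pmid must be a non-empty digit string, got {self.pmid!r}")

    @property
    def pubmed_link(self) -> str:
        return pubmed_link(self.pmid)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.pmid, self.gene_id, self.drug_id)


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace("|", "\\|")
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"n": "\n", "r": "\r"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _split_unescaped(line: str) -> list[str]:
    """Split on '|' delimiters that are not backslash-escaped."""
    fields = []
    current = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch == "\\" and i + 1 < len(line):
            current.append(ch)
            current.append(line[i + 1])
            i += 2
            continue
        if ch == "|":
            fields.append("".join(current))
            current = []
        else:
            current.append(ch)
        i += 1
    fields.append("".join(current))
    return fields


def format_line(r: NexusRecord) -> str:
    """Serialise one record as a pipe-delimited line (no trailing newline)."""
    fields = (
        r.pubmed_link,
        r.gene_surface,
        r.drug_surface,
        r.authors,
        r.pub_date.isoformat(),
        r.journal,
        r.title,
        r.gene_id,
        r.drug_id,
    )
    return "|" + "|".join(_escape(f) for f in fields) + "|"


def parse_line(line: str) -> NexusRecord:
    """Exact inverse of :func:`format_line`."""
    tokens = _split_unescaped(line.rstrip("\n"))
    # leading and trailing delimiters produce empty sentinel tokens
    if len(tokens) != 11 or tokens[0] != "" or tokens[-1] != "":
        raise ArchiveFormatError(
            f"expected 9 pipe-delimited fields with leading/trailing '|', got {len(tokens) - 2}"
        )
    link, gene_surface, drug_surface, authors, date_s, journal, title, gene_id, drug_id = (
        _unescape(t) for t in tokens[1:-1]
    )
    m = re.search(r"/(\d+)/?$", link)
    if not m:
        raise ArchiveFormatError(f"cannot extract PMID from link {link!r}")
    try:
        pub_date = datetime.date.fromisoformat(date_s)
    except ValueError as exc:
        raise ArchiveFormatError(f"bad date {date_s!r}") from exc
    return NexusRecord(
        pmid=m.group(1),
        gene_id=gene_id,
        gene_surface=gene_surface,
        drug_id=drug_id,
        drug_surface=drug_surface,
        authors=authors,
        pub_date=pub_date,
        journal=journal,
        title=title,
    )


def _sort_key(r: NexusRecord):
    return (int(r.pmid), r.gene_id, r.drug_id)


def write_archive(records: list[NexusRecord], path: str | Path) -> None:
    """Write the archive file: header comment, then one sorted line per record.

    Output order is normalised to (pmid, gene_id, drug_id), so two writes of
    the same record list are byte-identical.  Duplicate keys are an error.
    """
    seen: set[tuple[str, str, str]] = set()
    for r in records:
        if r.key in seen:
            raise ArchiveFormatError(f"duplicate archive key {r.key}")
        seen.add(r.key)
    ordered = sorted(records, key=_sort_key)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(ARCHIVE_HEADER + "\n")
        for r in ordered:
            fh.write(format_line(r) + "\n")


def read_archive(path: str | Path) -> list[NexusRecord]:
    """Read an archive file; ``#`` comment lines are skipped."""
    records: list[NexusRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            try:
                records.append(parse_line(stripped))
            except ArchiveFormatError as exc:
                raise ArchiveFormatError(f"line {lineno}: {exc}") from exc
    return records


def write_abstracts(abstracts: dict[str, str], path: str | Path) -> None:
    """Write the PMID -> abstract sidecar (sorted-key JSON, deterministic)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(abstracts, fh, ensure_ascii=False, indent=0, sort_keys=True)
        fh.write("\n")


def read_abstracts(path: str | Path) -> dict[str, str]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
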