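"""E-utilities client: URL construction and the date-windowed harvest loop.

PubMed's ESearch endpoint caps one page of results at ``retmax`` IDs
(historically 500).  To stay under that cap over decades of literature the
harvest is split into calendar windows whose density tracks publication
volume: semiannual windows through 1985, quarterly through 1995 and monthly
from 1996 on.  Should a window still overflow, the harvester bisects it
recursively; when bisection is impossible the loss is recorded in the
harvest summary rather than silently dropped.

Sources are pluggable: :class:`DirectorySource` serves pre-downloaded (or
synthetic) XML from a local directory so the whole pipeline runs offline;
:class:`LiveSource` talks to NCBI over HTTP with a politeness delay.
"""

from __future__ import annotations

import datetime
import logging
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from .medline import ArticleRecord, MedlineParseError, parse_esearch_result, parse_efetch_result

__all__ = [
    "EUTILS_BASE",
    "SearchWindow",
    "HarvestPlan",
    "HarvestSummary",
    "HarvestResult",
    "SourceError",
    "DirectorySource",
    "LiveSource",
    "build_esearch_url",
    "build_efetch_url",
    "make_harvest_plan",
    "harvest",
]

logger = logging.getLogger(__name__)

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

#: Minimum interval between live requests (NCBI asks for at most 3/s
#: without an API key).
POLITENESS_DELAY_S = 0.34


class SourceError(RuntimeError):
    """An abstract source could not satisfy a request (missing file, HTTP failure)."""


@dataclass(frozen=True)
class SearchWindow:
    """One date-bounded ESearch request: ``[start_date, end_date]`` inclusive."""

    start_date: datetime.date
    end_date: datetime.date
    term: str
    retmax: int = 500

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(f"window start {self.start_date} after end {self.end_date}")
        if self.retmax < 1:
            raise ValueError("retmax must be >= 1")

    @property
    def window_id(self) -> str:
        """Stable identifier, also the fixture file stem: YYYYMMDD-YYYYMMDD."""
        return f"{self.start_date:%Y%m%d}-{self.end_date:%Y%m%d}"

    def bisect(self) -> tuple["SearchWindow", "SearchWindow"]:
        """Split into two contiguous halves; fails on a one-day window."""
        span = (self.end_date - self.start_date).days
        if span < 1:
            raise ValueError("cannot bisect a one-day window")
        mid = self.start_date + datetime.timedelta(days=span // 2)
        left = SearchWindow(self.start_date, mid, self.term, self.retmax)
        right = SearchWindow(mid + datetime.timedelta(days=1), self.end_date, self.term, self.retmax)
        return left, right


@dataclass(frozen=True)
class HarvestPlan:
    """Chronologically ordered, contiguous, non-overlapping search windows."""

    windows: tuple[SearchWindow, ...]
    term: str


def build_esearch_url(term: str, window: SearchWindow) -> str:
    """ESearch URL for *term* restricted to *window*'s date range.

    *term* must already have its spaces joined with ``+`` (the ``+`` acts as
    an AND in the PubMed query language).  The term is embedded quoted, the
    date bounds as ``mindate``/``maxdate`` in YYYY/MM/DD with
    ``datetype=pdat``.
    """
    if not term:
        raise ValueError("search term must be non-empty")
    if any(ch.isspace() for ch in term):
        raise ValueError(f"term must join words with '+', got {term!r}")
    return (
        f'{EUTILS_BASE}/esearch.fcgi?db=pubmed&term="{term}"'
        f"&datetype=pdat&mindate={window.start_date:%Y/%m/%d}"
        f"&maxdate={window.end_date:%Y/%m/%d}&retmax={window.retmax}"
    )


def build_efetch_url(pmid: str) -> str:
    """EFetch URL returning one citation as abstract-flavoured XML."""
    if not pmid or not pmid.isdigit():
        raise ValueError(f"pmid must be a non-empty digit string, got {pmid!r}")
    return f"{EUTILS_BASE}/efetch.fcgi?db=pubmed&id={pmid}&rettype=abstract&retmode=XML"


def _year_windows(year: int, term: str, retmax: int) -> list[SearchWindow]:
    if year <= 1985:
        per_year = 2
    elif year <= 1995:
        per_year = 4
    else:
        per_year = 12
    step = 12 // per_year
    windows = []
    for i in range(per_year):
        start = datetime.date(year, 1 + i * step, 1)
        if i == per_year - 1:
            end = datetime.date(year, 12, 31)
        else:
            nxt = datetime.date(year, 1 + (i + 1) * step, 1)
            end = nxt - datetime.timedelta(days=1)
        windows.append(SearchWindow(start, end, term, retmax))
    return windows


def make_harvest_plan(
    start_year: int,
    end_year: int,
    term: str = "breast+cancer+gene+drug",
    retmax: int = 500,
) -> HarvestPlan:
    """Window schedule tracking literature growth.

    Semiannual windows for years through 1985, quarterly for 1986-1995,
    monthly from 1996 on; windows tile ``[Jan 1 start_year, Dec 31 end_year]``
    exactly once, in chronological order.
    """
    if start_year > end_year:
        raise ValueError(f"start_year {start_year} after end_year {end_year}")
    windows: list[SearchWindow] = []
    for year in range(start_year, end_year + 1):
        windows.extend(_year_windows(year, term, retmax))
    return HarvestPlan(windows=tuple(windows), term=term)


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

class DirectorySource:
    """Offline source reading ``<window_id>.esearch.xml`` / ``<pmid>.efetch.xml``."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def _read(self, name: str) -> bytes:
        path = self.directory / name
        try:
            return path.read_bytes()
        except OSError as exc:
            raise SourceError(f"fixture file not available: {path}") from exc

    def esearch(self, window: SearchWindow) -> bytes:
        return self._read(f"{window.window_id}.esearch.xml")

    def efetch(self, pmid: str) -> bytes:
        return self._read(f"{pmid}.efetch.xml")


class LiveSource:
    """HTTP source for NCBI E-utilities with a politeness delay and fixed retries."""

    def __init__(self, delay: float = POLITENESS_DELAY_S, retries: int = 3, timeout: float = 30.0):
        self.delay = delay
        self.retries = retries
        self.timeout = timeout
        self._last_request = 0.0

    def _get(self, url: str) -> bytes:
        last_error: Exception | None = None
        for _ in range(self.retries):
            wait = self.delay - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except Exception as exc:  # URLError, HTTPError, timeout
                last_error = exc
        raise SourceError(f"request failed after {self.retries} attempts: {url}") from last_error

    def esearch(self, window: SearchWindow) -> bytes:
        return self._get(build_esearch_url(window.term, window))

    def efetch(self, pmid: str) -> bytes:
        return self._get(build_efetch_url(pmid))


# ---------------------------------------------------------------------------
# Harvest loop
# ---------------------------------------------------------------------------

@dataclass
class HarvestSummary:
    """Bookkeeping for one harvest run."""

    windows_searched: int = 0
    windows_failed: list[tuple[str, str]] = field(default_factory=list)
    windows_overflowed: list[str] = field(default_factory=list)
    ids_lost: int = 0
    pmids_fetched: int = 0
    fetch_failures: list[tuple[str, str]] = field(default_factory=list)
    parse_warnings: list[str] = field(default_factory=list)


@dataclass
class HarvestResult:
    records: list[ArticleRecord]
    summary: HarvestSummary


_MAX_BISECT_DEPTH = 16


def _collect_window(source, window: SearchWindow, summary: HarvestSummary, depth: int = 0) -> list[str]:
    """PMIDs for one window, recursively bisecting when the count overflows."""
    xml = source.esearch(window)
    count, pmids = parse_esearch_result(xml)
    summary.windows_searched += 1
    truncated = count > len(pmids) or count > window.retmax
    if truncated and depth < _MAX_BISECT_DEPTH and window.start_date < window.end_date:
        left, right = window.bisect()
        try:
            return _collect_window(source, left, summary, depth + 1) + _collect_window(
                source, right, summary, depth + 1
            )
        except SourceError:
            # Sub-windows unavailable (e.g. a fixture with only the coarse
            # window): keep the truncated page and report the loss.
            logger.warning("window %s overflowed and could not be bisected", window.window_id)
    if truncated:
        summary.windows_overflowed.append(window.window_id)
        summary.ids_lost += max(count - len(pmids), 0)
    return pmids


def harvest(source, plan: HarvestPlan) -> HarvestResult:
    """Run the full harvest: ESearch every window, EFetch every unique PMID.

    Returns one record per unique PMID, ordered by PMID ascending.  A window
    whose search fails is skipped and logged in the summary; the first fetch
    of a PMID wins (duplicates across windows are assumed identical).
    """
    summary = HarvestSummary()
    seen: set[str] = set()
    for window in plan.windows:
        try:
            pmids = _collect_window(source, window, summary)
        except (SourceError, MedlineParseError) as exc:
            logger.warning("window %s skipped: %s", window.window_id, exc)
            summary.windows_failed.append((window.window_id, str(exc)))
            continue
        seen.update(pmids)

    records: list[ArticleRecord] = []
    fetched: set[str] = set()
    for pmid in sorted(seen, key=int):
        if pmid in fetched:
            continue
        try:
            xml = source.efetch(pmid)
            parsed = parse_efetch_result(xml, warnings=summary.parse_warnings)
        except (SourceError, MedlineParseError) as exc:
            logger.warning("PMID %s fetch failed: %s", pmid, exc)
            summary.fetch_failures.append((pmid, str(exc)))
            continue
        for record in parsed:
            if record.pmid not in fetched:
                fetched.add(record.pmid)
                records.append(record)
        summary.pmids_fetched += 1
    records.sort(key=lambda r: int(r.pmid))
    return HarvestResult(records=records, summary=summary)
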