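"""URL construction, harvest-plan scheduling and the offline harvest loop."""

import datetime
import urllib.parse

import pytest

from litnexus import (
    DirectorySource,
    SearchWindow,
    build_efetch_url,
    build_esearch_url,
    harvest,
    make_harvest_plan,
)
from litnexus.eutils import HarvestPlan
from litnexus.medline import articles_to_xml, esearch_result_xml
from litnexus.medline import ArticleRecord

W2000 = SearchWindow(datetime.date(2000, 1, 1), datetime.date(2000, 12, 31), "x")


class TestEsearchUrl:
    def test_contains_quoted_term_and_retmax(self):
        w = SearchWindow(datetime.date(1975, 1, 1), datetime.date(2010, 12, 31),
                         "breast+cancer+genes+drug", retmax=500)
        url = build_esearch_url("breast+cancer+genes+drug", w)
        assert 'esearch.fcgi?db=pubmed&term="breast+cancer+genes+drug"' in url
        assert "retmax=500" in url

    def test_one_day_window_has_equal_date_bounds(self):
        day = datetime.date(2000, 1, 1)
        url = build_esearch_url("x", SearchWindow(day, day, "x", retmax=1))
        parsed = dict(urllib.parse.parse_qsl(urllib.parse.urlsplit(url).query))
        assert parsed["mindate"] == parsed["maxdate"] == "2000/01/01"

    def test_round_trips_through_url_parser(self):
        w = SearchWindow(datetime.date(1999, 4, 1), datetime.date(1999, 6, 30),
                         "colon+cancer", retmax=500)
        url = build_esearch_url("colon+cancer", w)
        parsed = dict(urllib.parse.parse_qsl(urllib.parse.urlsplit(url).query))
        # parse_qsl decodes '+' to space, which inverts the term joining rule
        assert parsed["term"] == '"colon cancer"'
        assert parsed["db"] == "pubmed"
        assert parsed["mindate"] == "1999/04/01"
        assert parsed["maxdate"] == "1999/06/30"
        assert parsed["retmax"] == "500"

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            build_esearch_url("", W2000)

    def test_pure_function(self):
        assert build_esearch_url("x", W2000) == build_esearch_url("x", W2000)


class TestEfetchUrl:
    def test_contains_required_parameters(self):
        url = build_efetch_url("12345")
        assert "efetch.fcgi?db=pubmed&id=12345&rettype=abstract&retmode=XML" in url

    @pytest.mark.parametrize("bad", ["", "12a45", "PMC123"])
    def test_non_numeric_pmid_rejected(self, bad):
        with pytest.raises(ValueError):
            build_efetch_url(bad)

    def test_identifier_preserved_verbatim(self):
        assert "id=000001&" in build_efetch_url("000001")


def _schedule_oracle(start_year: int, end_year: int) -> int:
    """Independent per-year enumeration of the windowing schedule."""
    total = 0
    for year in range(start_year, end_year + 1):
        total += 2 if year <= 1985 else 4 if year <= 1995 else 12
    return total


class TestHarvestPlan:
    @pytest.mark.parametrize(
        "years,expected",
        [((1975, 1975), 2), ((1996, 1996), 12), ((1986, 1986), 4)],
    )
    def test_per_year_window_counts(self, years, expected):
        assert len(make_harvest_plan(*years).windows) == expected

    def test_full_schedule_matches_enumeration_oracle(self):
        plan = make_harvest_plan(1975, 2010)
        assert len(plan.windows) == _schedule_oracle(1975, 2010)
        assert _schedule_oracle(1975, 2010) == 2 * 11 + 4 * 10 + 12 * 15

    def test_windows_tile_range_at_day_level(self):
        plan = make_harvest_plan(1984, 1997)  # spans all three densities
        cursor = datetime.date(1984, 1, 1)
        for w in plan.windows:
            assert w.start_date == cursor
            assert w.end_date >= w.start_date
            cursor = w.end_date + datetime.timedelta(days=1)
        assert cursor == datetime.date(1998, 1, 1)

    def test_reversed_years_rejected(self):
        with pytest.raises(ValueError):
            make_harvest_plan(2001, 2000)


def _fixture_dir(tmp_path, windows_ids: dict[SearchWindow, list[str]], counts=None):
    """Write esearch files per window and a minimal efetch file per PMID."""
    all_pmids = sorted({p for ids in windows_ids.values() for p in ids}, key=int)
    for w, ids in windows_ids.items():
        count = counts[w.window_id] if counts else len(ids)
        (tmp_path / f"{w.window_id}.esearch.xml").write_bytes(
            esearch_result_xml(count, ids)
        )
    for pmid in all_pmids:
        rec = ArticleRecord(
            pmid=pmid, title=f"Article {pmid}", abstract="Text.",
            first_author="Smith A", last_author="Smith A",
            journal="J", pub_date=datetime.date(2000, 1, 1),
        )
        (tmp_path / f"{pmid}.efetch.xml").write_bytes(articles_to_xml([rec]))
    return tmp_path


def _window(start, end, retmax=500):
    return SearchWindow(datetime.date(*start), datetime.date(*end), "t", retmax)


class TestHarvest:
    def test_union_and_dedup_across_windows(self, tmp_path):
        w1 = _window((2000, 1, 1), (2000, 1, 31))
        w2 = _window((2000, 2, 1), (2000, 2, 29))
        w3 = _window((2000, 3, 1), (2000, 3, 31))
        src = DirectorySource(
            _fixture_dir(tmp_path, {w1: ["1", "2"], w2: ["2", "3"], w3: []})
        )
        plan = HarvestPlan(windows=(w1, w2, w3), term="t")
        result = harvest(src, plan)
        assert [r.pmid for r in result.records] == ["1", "2", "3"]

    def test_idempotent(self, tmp_path):
        w = _window((2000, 1, 1), (2000, 1, 31))
        src = DirectorySource(_fixture_dir(tmp_path, {w: ["5", "3", "4"]}))
        plan = HarvestPlan(windows=(w,), term="t")
        assert harvest(src, plan).records == harvest(src, plan).records

    def test_failed_window_skipped_and_reported(self, tmp_path):
        w1 = _window((2000, 1, 1), (2000, 1, 31))
        w_missing = _window((2000, 2, 1), (2000, 2, 29))
        src = DirectorySource(_fixture_dir(tmp_path, {w1: ["1"]}))
        plan = HarvestPlan(windows=(w1, w_missing), term="t")
        result = harvest(src, plan)
        assert [r.pmid for r in result.records] == ["1"]
        assert [wid for wid, _ in result.summary.windows_failed] == [w_missing.window_id]

    def test_overflow_single_window_loses_ids_and_reports(self, tmp_path):
        pmids = [str(i) for i in range(1, 601)]
        w = _window((2000, 1, 1), (2000, 12, 31), retmax=500)
        src = DirectorySource(
            _fixture_dir(tmp_path, {w: pmids[:500]}, counts={w.window_id: 600})
        )
        result = harvest(src, HarvestPlan(windows=(w,), term="t"))
        assert len(result.records) <= 500
        assert result.summary.ids_lost == 100
        assert result.summary.windows_overflowed

    def test_two_subwindows_recover_all_ids(self, tmp_path):
        pmids = [str(i) for i in range(1, 601)]
        w1 = _window((2000, 1, 1), (2000, 6, 30), retmax=500)
        w2 = _window((2000, 7, 1), (2000, 12, 31), retmax=500)
        src = DirectorySource(_fixture_dir(tmp_path, {w1: pmids[:300], w2: pmids[300:]}))
        result = harvest(src, HarvestPlan(windows=(w1, w2), term="t"))
        assert len(result.records) == 600
        assert result.summary.ids_lost == 0

    def test_overflow_bisects_when_subwindow_fixtures_exist(self, tmp_path):
        pmids = [str(i) for i in range(1, 8)]
        coarse = _window((2000, 1, 1), (2000, 1, 4), retmax=4)
        left = _window((2000, 1, 1), (2000, 1, 2), retmax=4)
        right = _window((2000, 1, 3), (2000, 1, 4), retmax=4)
        src = DirectorySource(_fixture_dir(
            tmp_path,
            {coarse: pmids[:4], left: pmids[:4], right: pmids[4:]},
            counts={coarse.window_id: 7, left.window_id: 4, right.window_id: 3},
        ))
        result = harvest(src, HarvestPlan(windows=(coarse,), term="t"))
        assert len(result.records) == 7
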