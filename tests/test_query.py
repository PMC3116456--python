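"""Exact-match retrieval: boolean semantics, exclusions, highlights, links."""

import datetime
import random
import urllib.parse

import pytest

from litnexus import (
    InvalidQueryError,
    NexusRecord,
    Query,
    drug_link,
    go_link,
    pubmed_link,
    search,
)


def _rec(pmid, title, gene="BRCA1", drug="etoposide", date=datetime.date(2001, 1, 1)):
    return NexusRecord(
        pmid=pmid, gene_id=f"G-{gene}", gene_surface=gene,
        drug_id=f"D-{drug}", drug_surface=drug,
        authors="Smith A; Jones B", pub_date=date, journal="J", title=title,
    )


@pytest.fixture()
def small_archive():
    records = [
        _rec("1", "Etoposide response in tumours", drug="etoposide"),
        _rec("2", "A tamoxifen study", drug="tamoxifen"),
        _rec("3", "Combination with etoposide", drug="etoposide"),
        _rec("4", "More on etoposide", drug="etoposide"),
        _rec("5", "Unrelated title", drug="cisplatin"),
    ]
    abstracts = {
        "1": "Cells were treated with etoposide.",
        "2": "Tamoxifen in breast carcinoma.",
        "3": "A mouse model received etoposide.",
        "4": "Etoposide dosing in patients.",
        "5": "Colon cancer incidence was reviewed.",
    }
    return records, abstracts


class TestSearch:
    def test_include_and_exclude_counts(self, small_archive):
        records, abstracts = small_archive
        result = search(records, abstracts,
                        Query(include_terms=("etoposide",), exclude_terms=("mouse",)))
        assert {r.pmid for r in result.records} == {"1", "4"}

    def test_exact_match_rejects_prefix(self, small_archive):
        records, abstracts = small_archive
        result = search(records, abstracts, Query(include_terms=("BRCA",)))
        assert len(result) == 0  # records contain only "BRCA1"

    def test_phrase_match_in_abstract_with_highlight(self, small_archive):
        records, abstracts = small_archive
        result = search(records, abstracts, Query(include_terms=("colon cancer",)))
        assert [r.pmid for r in result.records] == ["5"]
        (spans,) = result.highlights
        field, start, end = spans[0]
        assert field == "abstract"
        assert abstracts["5"][start:end] == "Colon cancer"

    def test_conjunctive_vs_disjunctive(self, small_archive):
        records, abstracts = small_archive
        both = Query(include_terms=("etoposide", "mouse"))
        either = Query(include_terms=("etoposide", "mouse"), conjunctive=False)
        assert {r.pmid for r in search(records, abstracts, both).records} == {"3"}
        assert {r.pmid for r in search(records, abstracts, either).records} == {"1", "3", "4"}

    def test_gene_and_drug_surfaces_searchable(self, small_archive):
        records, abstracts = small_archive
        result = search(records, abstracts, Query(include_terms=("cisplatin",)))
        assert [r.pmid for r in result.records] == ["5"]

    def test_results_ordered_date_desc_then_pmid(self):
        records = [
            _rec("3", "T", date=datetime.date(1999, 1, 1)),
            _rec("1", "T", date=datetime.date(2005, 6, 1)),
            _rec("2", "T", date=datetime.date(2005, 6, 1)),
        ]
        result = search(records, {}, Query(include_terms=("BRCA1",)))
        assert [r.pmid for r in result.records] == ["1", "2", "3"]

    def test_empty_include_rejected(self, small_archive):
        records, abstracts = small_archive
        with pytest.raises(InvalidQueryError):
            search(records, abstracts, Query(include_terms=()))
        with pytest.raises(InvalidQueryError):
            search(records, abstracts, Query(include_terms=("  ",)))

    def test_every_highlight_slices_to_an_include_term(self, small_archive):
        records, abstracts = small_archive
        q = Query(include_terms=("etoposide", "colon cancer"), conjunctive=False)
        result = search(records, abstracts, q)
        for rec, spans in zip(result.records, result.highlights):
            for field, start, end in spans:
                text = rec.title if field == "title" else abstracts[rec.pmid]
                assert text[start:end].lower() in {"etoposide", "colon cancer"}

    def test_exclusions_do_not_apply_to_author_or_journal(self):
        rec = _rec("1", "Plain title")
        result = search([rec], {"1": "Some text about BRCA1."},
                        Query(include_terms=("BRCA1",), exclude_terms=("Smith",)))
        assert len(result) == 1  # "Smith" only occurs in the authors field

    def test_antitone_in_excludes_and_conjuncts(self, small_archive):
        records, abstracts = small_archive
        rng = random.Random(17)
        vocab = ["etoposide", "tamoxifen", "mouse", "patients", "colon cancer",
                 "tumours", "BRCA1", "absentword"]
        for _ in range(50):
            include = tuple(rng.sample(vocab, rng.randint(1, 2)))
            base = Query(include_terms=include)
            with_exclude = Query(include_terms=include,
                                 exclude_terms=(rng.choice(vocab),))
            more_conjuncts = Query(include_terms=include + (rng.choice(vocab),))
            base_set = {r.pmid for r in search(records, abstracts, base).records}
            assert {r.pmid for r in search(records, abstracts, with_exclude).records} <= base_set
            assert {r.pmid for r in search(records, abstracts, more_conjuncts).records} <= base_set


class TestLinks:
    def test_pubmed_link_template(self):
        assert pubmed_link("99").endswith("/99/")

    def test_drug_link_url_encoded(self):
        url = drug_link("nab paclitaxel")
        assert "nab%20paclitaxel" in url

    def test_empty_inputs_rejected(self):
        for fn in (pubmed_link, drug_link, go_link):
            with pytest.raises(ValueError):
                fn("")

    def test_random_names_produce_valid_urls(self):
        rng = random.Random(23)
        alphabet = "abcdefghij -/&%"
        for fn in (drug_link, go_link):
            for _ in range(50):
                name = "".join(rng.choice(alphabet) for _ in range(8)).strip() or "x"
                parts = urllib.parse.urlsplit(fn(name))
                assert parts.scheme == "https" and parts.netloc
                # query must decode back to the original name
                decoded = urllib.parse.unquote(parts.query.split("=", 1)[1])
                assert decoded == name
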