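"""Shared fixtures: demo lexicons and one synthetic corpus per session."""

from __future__ import annotations

import pytest

from litnexus import (
    CorpusSpec,
    DirectorySource,
    filter_corpus,
    generate_corpus,
    generate_demo_lexicons,
    harvest,
    load_drug_lexicon,
    load_gene_lexicon,
    make_harvest_plan,
)

CORPUS_SEED = 20


@pytest.fixture(scope="session")
def lexicon_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("lexicons")
    return generate_demo_lexicons(out)


@pytest.fixture(scope="session")
def gene_lexicon(lexicon_paths):
    return load_gene_lexicon(lexicon_paths[0])


@pytest.fixture(scope="session")
def drug_lexicon(lexicon_paths):
    return load_drug_lexicon(lexicon_paths[1])


@pytest.fixture(scope="session")
def corpus(tmp_path_factory, gene_lexicon, drug_lexicon):
    """(directory, manifest) for the standard 200-document planted corpus."""
    out = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(seed=CORPUS_SEED)  # 200 docs: 60/40/40/60 split
    manifest = generate_corpus(spec, gene_lexicon, drug_lexicon, out)
    return out, manifest


@pytest.fixture(scope="session")
def harvested_records(corpus):
    corpus_dir, _ = corpus
    plan = make_harvest_plan(2000, 2000)
    return harvest(DirectorySource(corpus_dir), plan).records


@pytest.fixture(scope="session")
def nexus_records(harvested_records, gene_lexicon, drug_lexicon):
    return filter_corpus(harvested_records, gene_lexicon, drug_lexicon)
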