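"""Synthetic PubMed corpora and demo lexicons with a ground-truth manifest.

Every other layer of the pipeline is exercised against corpora produced
here: MEDLINE-shaped ``PubmedArticleSet`` XML files with gene and drug
mentions planted at recorded character offsets, windowed ESearch index
files compatible with the offline harvest source, and a
:class:`TruthManifest` stating exactly which articles must survive the
co-mention filter and which (article, gene, drug) records the archive must
contain.

The generator is deliberately simple about prose — template sentences with
a neutral vocabulary — but strict about ground truth: after building each
document it re-runs the production mention finder and refuses to emit a
corpus whose planted offsets do not reproduce exactly.  Decoy strings
(near-miss prefixes/superstrings of real lexicon forms) are screened the
same way, so a decoy can never satisfy whole-phrase boundary matching.

Gene and drug mentions are always planted in separate sentences: a real
abstract rarely puts the gene and the drug in one sentence, and the
co-mention filter must accept such articles regardless.

All randomness flows from the spec's single seed; the same
``(spec, seed)`` yields byte-identical corpora.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .archive import NexusRecord
from .eutils import make_harvest_plan
from .filtering import _lexicon_matcher, find_mentions
from .lexicon import Lexicon, load_gene_lexicon, load_drug_lexicon, normalize_surface
from .medline import ArticleRecord, articles_to_xml, esearch_result_xml

import datetime

__all__ = [
    "CorpusSpec",
    "PlantedMention",
    "DocTruth",
    "TruthManifest",
    "generate_demo_lexicons",
    "generate_corpus",
    "DEMO_GENE_ROWS",
    "DEMO_DRUG_ROWS",
]

# Demo lexicons: breast-cancer genes and drugs with plausible aliases.
# Columns: gene_id, symbol, full names, aliases, UniGene ids ('|'-separated).
# Every surface form ends in a token of >=2 characters so that truncating a
# form by one character never leaves a complete shorter phrase.
DEMO_GENE_ROWS: tuple[tuple[str, str, str, str, str], ...] = (
    ("G-BCL2",  "BCL2",  "B-cell lymphoma protein-2",                "bcl-2|Bcl2",          "Hs.150749"),
    ("G-BRCA1", "BRCA1", "breast cancer type-1 susceptibility protein", "IRIS|PSCP",        "Hs.194143"),
    ("G-ERBB2", "ERBB2", "human epidermal growth factor receptor-2", "Her-2|HER2|neu|Her-2/neu", "Hs.446352"),
    ("G-ERCC1", "ERCC1", "excision repair cross-complementation group-1", "RAD10",          "Hs.435981"),
    ("G-ESR1",  "ESR1",  "estrogen receptor alpha",                  "ER-alpha|NR3A1",      "Hs.208124"),
    ("G-GPX1",  "GPX1",  "glutathione peroxidase",                   "GSHPX1",              "Hs.76686"),
    ("G-MKI67", "MKI67", "marker of proliferation Ki-67",            "Ki-67|KIA",           "Hs.689823"),
    ("G-TFF1",  "TFF1",  "trefoil factor-1",                         "pS2|BCEI",            "Hs.162807"),
    ("G-TP53",  "TP53",  "tumor protein p53",                        "p53|LFS1|TRP53",      "Hs.408312"),
)

# Columns: drug_id, preferred name, synonyms.
DEMO_DRUG_ROWS: tuple[tuple[str, str, str], ...] = (
    ("D-CIS", "cisplatin",   "CDDP|cis-diamminedichloroplatinum"),
    ("D-DHA", "DHA",         "docosahexaenoic acid"),
    ("D-DOC", "docetaxel",   "Taxotere"),
    ("D-DOX", "doxorubicin", "Adriamycin|hydroxydaunorubicin"),
    ("D-EST", "estrogen",    "estradiol|oestrogen"),
    ("D-ETO", "etoposide",   "VP-16|vepesid"),
    ("D-LET", "letrozole",   "Femara"),
    ("D-TAM", "tamoxifen",   "Nolvadex"),
)

_JOURNALS = ("J Clin Oncol", "Breast Cancer Res", "Cancer Res", "Oncol Rep", "Clin Cancer Res")
_SURNAMES = ("Smith", "Jones", "Garcia", "Chen", "Patel", "Kim", "Muller", "Rossi", "Tanaka", "Okafor")
_INITIALS = ("A", "BC", "D", "EF", "JR", "KL", "M")

_FIRST_PMID = 100001
_CORPUS_YEAR = 2000
_TITLE_MENTION_PROB = 0.25


def generate_demo_lexicons(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the bundled demo gene/drug lexicon TSVs; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_path = out / "genes.tsv"
    drug_path = out / "drugs.tsv"
    with open(gene_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gene_id\tsymbol\tfull_names\taliases\tunigene_ids\n")
        for row in DEMO_GENE_ROWS:
            fh.write("\t".join(row) + "\n")
    with open(drug_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# drug_id\tpreferred_name\tsynonyms\n")
        for row in DEMO_DRUG_ROWS:
            fh.write("\t".join(row) + "\n")
    return gene_path, drug_path


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    The category fractions (gene-and-drug, gene-only, drug-only; remainder
    neither) must sum to at most 1.  ``alias_use_prob`` is the chance a
    planted mention uses an alias/name/UniGene form rather than the primary
    symbol; ``decoy_prob`` the chance a document additionally carries a
    near-miss decoy string.
    """

    n_docs: int = 200
    frac_gene_and_drug: float = 0.3
    frac_gene_only: float = 0.2
    frac_drug_only: float = 0.2
    genes_per_doc: tuple[int, int] = (1, 3)
    drugs_per_doc: tuple[int, int] = (1, 2)
    alias_use_prob: float = 0.5
    decoy_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_gene_and_drug, self.frac_gene_only, self.frac_drug_only)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("category fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("category fractions must sum to at most 1")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")


@dataclass(frozen=True)
class PlantedMention:
    pmid: str
    kind: str  # "gene" | "drug"
    canonical_id: str
    surface: str
    field: str  # "title" | "abstract"
    start: int
    end: int


@dataclass
class DocTruth:
    category: str  # "gene_and_drug" | "gene_only" | "drug_only" | "neither"
    gene_ids: list[str]
    drug_ids: list[str]
    mentions: list[PlantedMention]


@dataclass
class TruthManifest:
    """Ground truth for a generated corpus.

    ``expected_nexus`` is the full cross product of planted gene ids and
    drug ids over each surviving (gene-and-drug) document.
    """

    docs: dict[str, DocTruth]
    expected_surviving_pmids: list[str]
    expected_nexus: list[tuple[str, str, str]]

    def to_dict(self) -> dict:
        return {
            "docs": {pmid: asdict(t) for pmid, t in sorted(self.docs.items())},
            "expected_surviving_pmids": self.expected_surviving_pmids,
            "expected_nexus": [list(t) for t in self.expected_nexus],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=1, sort_keys=True)
            fh.write("\n")


class _FieldBuilder:
    """Accumulates one text field, recording mention offsets as it grows."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._length = 0
        self.mentions: list[tuple[int, int, str, str, str]] = []

    def text(self, s: str) -> None:
        self._parts.append(s)
        self._length += len(s)

    def mention(self, surface: str, canonical_id: str, kind: str) -> None:
        start = self._length
        self.text(surface)
        self.mentions.append((start, start + len(surface), surface, canonical_id, kind))

    def build(self) -> str:
        return "".join(self._parts)


def _plantable_forms(lex: Lexicon, other: Lexicon) -> dict[str, list[str]]:
    """Per entry: raw surface forms safe to plant.

    A form is plantable iff the index resolves it to its own entry (not lost
    to length/stoplist exclusion or a conflict) and it contains no
    whole-phrase match of the *other* lexicon (e.g. the gene name
    "estrogen receptor alpha" embeds the drug "estrogen" and would
    contaminate gene-only documents).
    """
    other_matcher = _lexicon_matcher(other)
    plantable: dict[str, list[str]] = {}
    for entry in lex.entries:
        forms = [
            f
            for f in entry.surface_forms()
            if f
            and lex.surface_index.get(normalize_surface(f)) == entry.canonical_id
            and not other_matcher.search(f)
        ]
        if forms:
            plantable[entry.canonical_id] = forms
    return plantable


def _decoy_strings(genes: Lexicon, drugs: Lexicon) -> list[str]:
    """Near-miss strings verified to match nothing in either lexicon."""
    gm = _lexicon_matcher(genes)
    dm = _lexicon_matcher(drugs)
    candidates: list[str] = []
    for lex in (genes, drugs):
        for form in sorted(lex.surface_index):
            if len(form) >= 5:
                candidates.append(form[:-1])  # truncation
            candidates.append(form + "in")  # superstring
    decoys = []
    for cand in candidates:
        padded = f" {cand} "
        if gm.search(padded) or dm.search(padded):
            continue
        decoys.append(cand)
    return sorted(set(decoys))


def _pick_form(forms: list[str], symbol_first: bool, rng: random.Random, alias_prob: float) -> str:
    if len(forms) == 1:
        return forms[0]
    primary, rest = forms[0], forms[1:]
    if symbol_first and rng.random() >= alias_prob:
        return primary
    return rng.choice(rest)


def generate_corpus(
    spec: CorpusSpec,
    genes: Lexicon,
    drugs: Lexicon,
    out_dir: str | Path,
) -> TruthManifest:
    """Emit a synthetic corpus under *out_dir* and return its ground truth.

    Output: one ``<pmid>.efetch.xml`` per document, one
    ``<window_id>.esearch.xml`` per monthly window of the corpus year (the
    layout :class:`~litnexus.eutils.DirectorySource` reads), and
    ``manifest.json``.
    """
    if not genes.entries or not drugs.entries:
        raise ValueError("both lexicons must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    n = spec.n_docs
    n_both = round(n * spec.frac_gene_and_drug)
    n_gene = round(n * spec.frac_gene_only)
    n_drug = round(n * spec.frac_drug_only)
    n_neither = n - n_both - n_gene - n_drug
    if n_neither < 0:
        raise ValueError("category fractions round to more documents than n_docs")
    categories = (
        ["gene_and_drug"] * n_both
        + ["gene_only"] * n_gene
        + ["drug_only"] * n_drug
        + ["neither"] * n_neither
    )
    rng.shuffle(categories)

    gene_forms = _plantable_forms(genes, drugs)
    drug_forms = _plantable_forms(drugs, genes)
    decoys = _decoy_strings(genes, drugs)

    docs: dict[str, DocTruth] = {}
    records: list[ArticleRecord] = []
    for i, category in enumerate(categories):
        pmid = str(_FIRST_PMID + i)
        pub_date = datetime.date(_CORPUS_YEAR, (i % 12) + 1, 1 + (i // 12) % 28)
        journal = rng.choice(_JOURNALS)
        n_authors = rng.randint(1, 3)
        author_names = [
            f"{rng.choice(_SURNAMES)} {rng.choice(_INITIALS)}" for _ in range(n_authors)
        ]

        want_genes = category in ("gene_and_drug", "gene_only")
        want_drugs = category in ("gene_and_drug", "drug_only")
        gene_picks: list[tuple[str, str]] = []
        drug_picks: list[tuple[str, str]] = []
        if want_genes:
            k = min(rng.randint(*spec.genes_per_doc), len(gene_forms))
            for gid in rng.sample(sorted(gene_forms), k):
                gene_picks.append((gid, _pick_form(gene_forms[gid], True, rng, spec.alias_use_prob)))
        if want_drugs:
            k = min(rng.randint(*spec.drugs_per_doc), len(drug_forms))
            for did in rng.sample(sorted(drug_forms), k):
                drug_picks.append((did, _pick_form(drug_forms[did], True, rng, spec.alias_use_prob)))

        title = _FieldBuilder()
        abstract = _FieldBuilder()
        title_gene = gene_picks and rng.random() < _TITLE_MENTION_PROB
        if title_gene:
            title.text("Role of ")
            gid, form = gene_picks[0]
            title.mention(form, gid, "gene")
            title.text(f" in breast carcinoma treatment response: cohort study {i + 1}")
        else:
            title.text(f"Treatment response and outcome in breast carcinoma: cohort study {i + 1}")

        abstract.text("We analysed tumour samples from a prospective clinical cohort. ")
        remaining_genes = gene_picks[1:] if title_gene else gene_picks
        for gid, form in remaining_genes:
            abstract.text("Expression of ")
            abstract.mention(form, gid, "gene")
            abstract.text(" was quantified in the tumour specimens. ")
        for did, form in drug_picks:
            abstract.text("Patients in the intervention arm received ")
            abstract.mention(form, did, "drug")
            abstract.text(" as part of the chemotherapy regimen. ")
        if decoys and rng.random() < spec.decoy_prob:
            abstract.text(f"The assay panel also reported {rng.choice(decoys)} readings. ")
        abstract.text("Survival outcomes were recorded over a five-year follow-up period.")

        record = ArticleRecord(
            pmid=pmid,
            title=title.build(),
            abstract=abstract.build(),
            first_author=author_names[0],
            last_author=author_names[-1],
            journal=journal,
            pub_date=pub_date,
        )

        planted = [
            PlantedMention(pmid, kind, cid, surface, field_name, start, end)
            for field_name, builder in (("title", title), ("abstract", abstract))
            for (start, end, surface, cid, kind) in builder.mentions
        ]
        _verify_document(record, planted, genes, drugs)

        docs[pmid] = DocTruth(
            category=category,
            gene_ids=sorted(gid for gid, _ in gene_picks),
            drug_ids=sorted(did for did, _ in drug_picks),
            mentions=planted,
        )
        records.append(record)
        (out / f"{pmid}.efetch.xml").write_bytes(articles_to_xml([record]))

    # Windowed ESearch index files for the corpus year (monthly schedule).
    plan = make_harvest_plan(_CORPUS_YEAR, _CORPUS_YEAR)
    for window in plan.windows:
        ids = sorted(
            (r.pmid for r in records if window.start_date <= r.pub_date <= window.end_date),
            key=int,
        )
        (out / f"{window.window_id}.esearch.xml").write_bytes(
            esearch_result_xml(len(ids), ids)
        )

    surviving = sorted(
        (p for p, t in docs.items() if t.category == "gene_and_drug"), key=int
    )
    expected_nexus = sorted(
        (
            (pmid, gid, did)
            for pmid in surviving
            for gid in docs[pmid].gene_ids
            for did in docs[pmid].drug_ids
        ),
        key=lambda t: (int(t[0]), t[1], t[2]),
    )
    manifest = TruthManifest(
        docs=docs,
        expected_surviving_pmids=surviving,
        expected_nexus=expected_nexus,
    )
    manifest.save(out / "manifest.json")
    return manifest


def _verify_document(
    record: ArticleRecord,
    planted: list[PlantedMention],
    genes: Lexicon,
    drugs: Lexicon,
) -> None:
    """Refuse to emit a document whose planted offsets do not reproduce.

    Checks (a) each recorded offset slices back to its surface, and (b) the
    production mention finder recovers exactly the planted mention set — so
    decoys and template prose can never add or mask a mention.
    """
    texts = {"title": record.title, "abstract": record.abstract}
    for m in planted:
        if texts[m.field][m.start : m.end] != m.surface:
            raise RuntimeError(f"offset mismatch for {m}")
    for kind, lex in (("gene", genes), ("drug", drugs)):
        found = {
            (m.field, m.start, m.end, m.canonical_id) for m in find_mentions(record, lex)
        }
        expected = {
            (m.field, m.start, m.end, m.canonical_id) for m in planted if m.kind == kind
        }
        if found != expected:
            raise RuntimeError(
                f"{kind} mentions diverge from plant for PMID {record.pmid}: "
                f"found {sorted(found)}, planted {sorted(expected)}"
            )


def expected_nexus_records(manifest: TruthManifest) -> set[tuple[str, str, str]]:
    """The manifest's expected archive keys as a set of (pmid, gene, drug)."""
    return set(manifest.expected_nexus)


def nexus_keys(records: list[NexusRecord]) -> set[tuple[str, str, str]]:
    return {r.key for r in records}
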