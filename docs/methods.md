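# Methods

## The procedure

`litnexus` implements a dictionary-based co-mention pipeline. Nothing in it
is statistical: every decision is an exact string operation against curated
lexicons, which makes the behaviour fully auditable — a property the
intended clinician audience values over recall-maximising NLP.

**Harvesting.** PubMed is queried through E-utilities. ESearch URLs embed
the search phrase (words joined by `+`, which acts as an AND), a
`mindate`/`maxdate` window in `YYYY/MM/DD` with `datetype=pdat`, and
`retmax` (default 500, the classic page cap). Because one search can return
at most `retmax` IDs, the harvest is windowed with a density that tracks
the growth of the literature: 2 windows/year through 1985, 4/year for
1986–1995, 12/year from 1996. The year boundaries are read inclusively so
windows tile the full range with no day-level gap or overlap (verified by
enumeration in the tests). If ESearch still reports more hits than a window
returned, the harvester bisects the window recursively (up to 16 levels);
when bisection is impossible — a one-day window, or a fixture directory
that only contains the coarse window — the loss is counted in the harvest
summary instead of being silent. PMIDs are deduplicated across windows
(first fetch wins; records for the same PMID are assumed identical) and the
output is sorted by PMID.

The source is pluggable. `DirectorySource` reads
`<windowid>.esearch.xml` / `<pmid>.efetch.xml` files, so the entire
pipeline — including all tests and the acceptance script — runs with no
network. `LiveSource` performs the same requests over HTTP with a ≥0.34 s
politeness delay (NCBI's 3-requests-per-second guidance) and a fixed retry
count; it is implemented on stdlib `urllib` since nothing heavier is
needed for two GET endpoints.

**Parsing.** EFetch XML is parsed with lxml. Extracted fields: PMID, title,
abstract, first (lead) author, last (presumptive ranking) author, journal
and publication date. Structured-abstract blocks are joined with single
spaces and their labels dropped. Author names render as "Surname Initials";
corporate authors are skipped when choosing first/last. Dates resolve
missing months to January and missing days to the 1st; `MedlineDate` ranges
("1998 Dec-1999 Jan") resolve to the first parseable year/month. Articles
without a title or PMID are rejected with one warning each, so the parse
deficit always equals the warning count. All text is NFC-normalised.

**Lexicons.** A gene entry carries a canonical id, primary symbol, full
names, alias symbols and UniGene IDs; a drug entry a preferred name and
synonyms. Every surface form is normalised (NFC, casefold, whitespace
collapse; hyphens and periods preserved) and indexed to its canonical id —
the "all forms are equal" rule that lets an abstract citing only a UniGene
ID still count as mentioning the gene. Matching is case-insensitive because
gene symbols appear in arbitrary case in prose, while the rest of the
normalisation is intentionally minimal to preserve exactness.

Two ambiguity guards: normalised forms shorter than 3 characters are
dropped (symbols like "ER" are hopeless in free text), as are forms on a
small English stoplist ("was", "has", … — real alias symbols collide with
common words). Both exclusions are reported, not silent. A form claimed by
several entries is assigned to the lexicographically smallest canonical id
— an arbitrary but deterministic and row-order-independent rule — and the
conflict is logged.

**Mention finding.** A mention is an occurrence of an indexed form bounded
on both sides by a non-alphanumeric character or the string edge. Hyphens,
periods and slashes *inside* a form match literally ("Her-2/neu",
"Hs.446352") but act as boundaries at the edges of a match: "BRCA1" is
found in "BRCA1-deficient", both halves of "Her-2/ErbB2" can match, and
"BRCA" never matches inside "BRCA1". The scanner compiles one alternation
over all index forms ordered longest-first, so matches are
leftmost-longest and non-overlapping within a lexicon; the gene and drug
lexicons are scanned independently, so one span may hold a gene and a drug
mention simultaneously. Internal whitespace in a multi-word form matches
any whitespace run.

**Filtering and archiving.** An article survives iff title ∪ abstract
contains ≥1 gene and ≥1 drug mention — in either field, not necessarily the
same sentence or paragraph. One record per distinct (pmid, gene id,
drug id) is emitted, storing the surface form of each entity's first
mention (what a reader should see) alongside the canonical ids. The archive
is a flat UTF-8 text file, one pipe-delimited line per record with leading
and trailing delimiters, sorted by (pmid, gene, drug) so writes are
byte-deterministic. Pipes, backslashes and newlines inside fields are
backslash-escaped, making `parse_line` an exact inverse of `format_line`
(property-tested). A `#` header comment records the dialect version and
the two appended id columns. Abstracts live in a JSON sidecar keyed by
PMID rather than in the archive lines.

**Querying.** Include terms and exclusion keywords are normalised like
lexicon forms and matched with the same whole-phrase boundary rule. Include
terms search title ∪ abstract ∪ matched gene/drug surfaces; multiple
include terms combine conjunctively by default (a user filling both the
gene and the drug field expects both) with a disjunctive option; exclusions
apply to title and abstract only, since "exclude abstracts that contain a
keyword" should not fire on author or journal names. Results are ordered
newest-first, then by PMID, and carry highlight spans for every include
term plus outbound links (PubMed's current URL scheme; drug-information
and Gene Ontology links are configurable templates, as no stable historic
endpoints exist).

## The synthetic-data generator

`fixtures.generate_corpus` emulates exactly what the downstream consumers
read: MEDLINE-shaped `PubmedArticleSet` files, windowed ESearch indexes,
and realistic-but-neutral template prose with mentions planted at recorded
offsets. Default conditions: 200 documents split 30 % gene+drug, 20 %
gene-only, 20 % drug-only, 30 % neither; 1–3 genes and 1–2 drugs per
planting document; aliases used for half the plantings
(`alias_use_prob=0.5`); near-miss decoy strings (truncations/extensions of
real forms) in 30 % of documents. These rates make every code path —
co-mention acceptance, single-entity rejection, alias resolution, decoy
rejection — exercised in a single corpus of desk-scale size. All randomness
derives from a single seed; identical (spec, seed) produce byte-identical
corpora. Gene and drug mentions are always planted in separate sentences,
because real abstracts rarely put them in one sentence and the filter must
accept such articles regardless.

Two self-checks run at generation time and abort on failure: every recorded
offset must slice back to its surface form, and the production mention
finder must recover exactly the planted mention set (so a decoy or an
unlucky template word can never add or mask a mention). Forms that embed a
form of the *other* lexicon — "estrogen receptor alpha" contains the drug
"estrogen" — are excluded from the planting pool so category labels stay
exact, though they remain fully indexed and matchable.

What the generator does **not** model: realistic MEDLINE field statistics,
MeSH terms, non-ASCII prose, misspelled or novel entity names, and
gene/drug mentions expressed by description rather than by a lexicon form.
Passing tests therefore demonstrate correctness of the machinery (exact
matching, alias equality, archive fidelity, retrieval semantics), not the
real-world recall of any particular gene or drug list — on live data,
recall is bounded by lexicon coverage by construction.

**Demo lexicons.** The bundled tables cover nine breast-cancer genes
(estrogen receptor, ERBB2/Her-2, ERCC1, BRCA1, p53, bcl-2, Ki-67,
glutathione peroxidase, pS2/TFF1) with plausible alias sets and UniGene
IDs, and eight drugs (estrogen, tamoxifen, cisplatin, docetaxel,
doxorubicin, DHA, letrozole, etoposide) with synonyms. One deliberate
design rule: every surface form ends in a token of at least two
characters (e.g. "estrogen receptor alpha" rather than
"estrogen receptor 1"), so truncating any form by one character never
leaves a complete shorter phrase — keeping the exact-match contract
("a one-character truncation retrieves nothing") testable across the whole
lexicon without exceptions.

## Numerical and degenerate-input choices

- Date parameters are emitted as `YYYY/MM/DD`; one-day windows are legal
  (min and max date equal) and are the bisection floor.
- `parse_esearch_result` trusts the reported `Count` over the ID list
  length; a truncated page is the overflow signal.
- Empty abstracts are legal everywhere; empty titles are not.
- Tie-breaks: lexicon conflicts → smallest id; equal-date query results →
  smallest PMID; overlapping mention candidates → leftmost, then longest.
- The query engine treats an archive record whose PMID lacks a sidecar
  abstract as having an empty abstract.

## Known limitations

- Exact dictionary matching cannot find entities absent from the lexicons,
  and inherits any lexicon ambiguity not caught by the length/stoplist
  guards.
- Co-mention is not a relationship: no polarity (sensitivity vs.
  resistance), no sentence-level association, no ranking beyond recency.
- The live source implements only fixed retries and a fixed delay — no
  exponential backoff or API-key handling.
- Window bisection assumes the source can answer arbitrary sub-windows;
  offline fixture directories that cannot are handled by reporting loss.
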