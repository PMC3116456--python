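# litnexus

Dictionary-based mining of the biomedical literature for the
disease–gene–drug nexus.

Clinicians choosing a chemotherapy regimen increasingly want to know which
gene-expression findings have been linked to sensitivity or resistance to a
given drug. Those links are reported in free text across thousands of
abstracts. `litnexus` automates the bookkeeping end of that problem for a
disease domain (the bundled demo targets breast cancer):

1. **Harvest** — query PubMed through NCBI's E-utilities with a disease
   search phrase, looping over date windows so no single search exceeds the
   `retmax` cap on returned IDs (semiannual windows through 1985, quarterly
   through 1995, monthly thereafter; an overflowing window is bisected
   recursively). Every stage also runs fully offline against local XML
   fixtures.
2. **Filter** — scan each title and abstract for *exact* occurrences of
   known gene surface forms (symbol, full names, aliases, UniGene IDs — all
   treated as equal) and drug surface forms (name + synonyms). An article is
   kept only if it co-mentions at least one gene and one drug; each
   distinct (article, gene, drug) triple becomes one archive record.
3. **Archive** — a single pipe-delimited flat text file:
   `| PubMed link | gene | drug | authors | date | journal | title |`
   (plus two appended canonical-id columns), with abstracts in a JSON
   sidecar. No database required.
4. **Query** — exact whole-phrase, word-boundary, case-insensitive
   retrieval with include terms (disease, gene or drug names) and
   "negative control" exclusion keywords, returning highlighted spans and
   outbound PubMed / drug-information / Gene Ontology links.

Matching is deliberately dictionary-exact, never fuzzy or statistical:
gene and drug names are precise tokens, and a query for `BRCA` must not
retrieve `BRCA1`. The system only co-locates entities — deciding whether a
co-mentioned gene–drug pair reflects sensitivity, resistance or coincidence
is left to the reader.

## Worked example

Generate a 50-document synthetic corpus with planted mentions, build the
archive, and query it:

```
$ litnexus make-fixtures --n 50 --seed 7 --out fix
wrote 50 documents, lexicons and manifest under fix (15 documents co-mention gene+drug)

$ litnexus build-archive --in fix/corpus --genes fix/genes.tsv --drugs fix/drugs.tsv --out archive.txt
50 articles in, 15 with gene+drug co-mentions, 47 archive records -> archive.txt

$ litnexus query --archive archive.txt --include etoposide --exclude mouse
...
100014  2000-02-02  ESR1 / etoposide  Breast Cancer Res
    Treatment response and outcome in breast carcinoma: cohort study 14
    https://pubmed.ncbi.nlm.nih.gov/100014/
9 result(s)
```

Of 50 generated abstracts, 15 contain both a gene and a drug mention and
survive the filter; they expand to 47 archive records because an article
mentioning *m* genes and *n* drugs yields *m×n* records (each result row is
a different gene paired with the same drug, or vice versa). The query then
finds the 9 records whose text or matched surfaces contain the exact phrase
`etoposide` and do not contain `mouse`. The first lines of `archive.txt`:

```
# litnexus archive v1 | pubmed-link | gene | drug | authors | date | journal | title | gene-id | drug-id |
|https://pubmed.ncbi.nlm.nih.gov/100003/|GSHPX1|Nolvadex|Okafor D|2000-03-01|Breast Cancer Res|Treatment response and outcome in breast carcinoma: cohort study 3|G-GPX1|D-TAM|
```

A live harvest works the same way with `litnexus fetch --term
breast+cancer+gene+drug --from 1975 --to 2010 --source live --out dir`
(0.34 s politeness delay between requests), after which `build-archive`
consumes the fetched XML directory.

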