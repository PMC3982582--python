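# phenotissue

Mine, score, evaluate and apply tissue–phenotype associations from gene
expression calls and phenotype annotations.

The pipeline builds a joint annotation corpus (per-gene sets of panel
tissues with a `present` expression call and phenotype concepts), then
scores every (tissue, phenotype) pair two ways:

- **Hypergeometric enrichment** — upper-tail p-value of the pair's
  co-annotation overlap (equivalent to the one-sided Fisher exact test),
  with a minimum phenotype occurrence filter (≥ 10 genes) and an inclusive
  significance cutoff (p ≤ 0.005).
- **Association-rule mining** — pairwise apriori over genes-as-transactions
  with absolute support ≥ 6 and confidence ≥ 0.9; each rule carries the
  same Fisher-style p-value of its 2×2 table.

Predictions are evaluated against entity–quality (EQ) anatomy gold
standards through transitive `is_a`/`part_of` reasoning over a term DAG
(`exact` / `psp` / `ldsp` / `no_match` / `no_eq` categories with
with-EQ percentage denominators), and can be applied to re-rank a
candidate-gene list by expression in phenotype-associated tissues.
A synthetic-data module generates complete, seed-reproducible input
bundles with planted enrichments so every stage is testable offline.

## CLI

All stages are exposed through one entry point:

```sh
# generate a synthetic input bundle
phenotissue simulate --config sim.json --out-dir bundle/

# merge expression sources + phenotype annotations into a corpus
phenotissue build-corpus \
    --expression bundle/expression_lacz.tsv,bundle/expression_barcode.tsv \
    --phenotypes bundle/phenotypes.tsv --gene-map bundle/gene_map.tsv \
    --panel bundle/panel.txt --out corpus.tsv --log build.json

# score pairs with either or both methods
phenotissue associate --corpus corpus.tsv --method hypergeom --out hyper.tsv
phenotissue associate --corpus corpus.tsv --method rules --out rules.tsv

# evaluate against EQ gold anatomy
phenotissue evaluate --associations hyper.tsv --eq bundle/eq.tsv \
    --xref bundle/xref.tsv --ontology bundle/anatomy.tsv \
    --panel bundle/panel.txt --out eval.tsv --summary summary.txt

# combined table + per-phenotype browse reports
phenotissue combine --hypergeom hyper.tsv --rules rules.tsv \
    --out combined.tsv --browse-dir browse/

# expression-constrained candidate re-ranking
phenotissue rerank --candidates bundle/candidates.tsv \
    --phenotypes PHEN:0003 --associations hyper.tsv \
    --corpus corpus.tsv --top-n 200 --out reranked.tsv
```

File formats are plain TSV/text throughout (headers documented in the
module docstrings); ontologies load from a 3-column edge TSV or an OBO 1.2
subset.

## Package layout

| module | responsibility |
|---|---|
| `phenotissue.ontology` | term DAGs, transitive `is_a`/`part_of` queries |
| `phenotissue.corpus_io` | reading, id-mapping and merging annotation inputs |
| `phenotissue.enrichment` | contingency counting and hypergeometric scoring |
| `phenotissue.rule_mining` | pairwise apriori rule mining |
| `phenotissue.eq_evaluation` | EQ gold classification and summaries |
| `phenotissue.prioritization` | candidate-list filtering/re-ranking |
| `phenotissue.synthetic_data` | seeded synthetic bundles with planted signal |
| `phenotissue.reporting` | combined tables and browse exports |
| `phenotissue.cli` | click command-line interface |
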