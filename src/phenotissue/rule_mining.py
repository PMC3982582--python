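"""Pairwise apriori mining of tissue<->phenotype association rules.

Genes are the transactions; each transaction holds the gene's panel tissues
and phenotypes as tagged items.  Rule shape is restricted to a single-item
antecedent and single-item consequent with mixed tags (one tissue, one
phenotype).  Classical apriori pruning still applies on this restriction:
only items whose individual support reaches the absolute minimum are
candidate pair members.  Kept rules need support >= 6 genes (absolute) and
confidence >= 0.9 by default; each rule carries the one-sided
Fisher/hypergeometric upper-tail p of its pair's 2x2 table, identical for
both directions over the same pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from phenotissue.corpus_io import AnnotationCorpus
from phenotissue.enrichment import (
    Association,
    ContingencyCounts,
    hypergeom_upper_tail,
)

DEFAULT_MIN_SUPPORT = 6
DEFAULT_MIN_CONFIDENCE = 0.9

TISSUE_TAG = "tissue"
PHENOTYPE_TAG = "phenotype"


class Item(NamedTuple):
    """A tagged transaction item: (tag, term id)."""

    tag: str
    term: str


@dataclass(frozen=True)
class Transaction:
    gene: str
    items: frozenset[Item]


@dataclass(frozen=True)
class Rule:
    antecedent: Item
    consequent: Item
    support_abs: int
    confidence: float
    p_value: float

    def __post_init__(self) -> None:
        if self.antecedent.tag == self.consequent.tag:
            raise ValueError("rule must mix one tissue item and one phenotype item")


def corpus_to_transactions(corpus: AnnotationCorpus) -> list[Transaction]:
    """One transaction per gene: its panel tissues plus its phenotypes, tagged.

    Genes with no annotations yield empty transactions (retained; they
    contribute to no support count).
    """
    out = []
    for gene in sorted(corpus.genes):
        items = frozenset(
            itertools.chain(
                (Item(TISSUE_TAG, t) for t in corpus.tissues(gene)),
                (Item(PHENOTYPE_TAG, p) for p in corpus.phenotypes(gene)),
            )
        )
        out.append(Transaction(gene=gene, items=items))
    return out


def item_supports(transactions: Sequence[Transaction]) -> dict[Item, int]:
    """Absolute support (transaction count) of every item."""
    counts: dict[Item, int] = {}
    for txn in transactions:
        for item in txn.items:
            counts[item] = counts.get(item, 0) + 1
    return counts


def frequent_pairs(
    transactions: Sequence[Transaction],
    min_support_abs: int = DEFAULT_MIN_SUPPORT,
) -> list[tuple[Item, Item, int]]:
    """Mixed-tag item pairs co-occurring in >= min_support_abs transactions.

    Apriori pruning: only items individually reaching the support threshold
    can be pair members (pair support never exceeds member support).
    Returned as (tissue_item, phenotype_item, support_abs), sorted.
    """
    if min_support_abs < 1:
        raise ValueError("min_support_abs must be >= 1")
    supports = item_supports(transactions)
    frequent_tissues = {
        i for i, n in supports.items()
        if i.tag == TISSUE_TAG and n >= min_support_abs
    }
    frequent_phenos = {
        i for i, n in supports.items()
        if i.tag == PHENOTYPE_TAG and n >= min_support_abs
    }

    pair_counts: dict[tuple[Item, Item], int] = {}
    for txn in transactions:
        tissues = [i for i in txn.items if i in frequent_tissues]
        phenos = [i for i in txn.items if i in frequent_phenos]
        for ti in tissues:
            for pi in phenos:
                pair_counts[(ti, pi)] = pair_counts.get((ti, pi), 0) + 1

    return sorted(
        (ti, pi, n)
        for (ti, pi), n in pair_counts.items()
        if n >= min_support_abs
    )


def rule_pvalue(
    support_abs: int, n_antecedent: int, n_consequent: int, pt: int
) -> float:
    """One-sided Fisher upper-tail p of the pair's 2x2 table.

    Delegates to the hypergeometric tail used by the enrichment method so
    the two scoring routes stay commensurable; symmetric in the two item
    counts, hence identical for both rule directions.
    """
    counts = ContingencyCounts(
        o_tp=support_abs, t=n_antecedent, p=n_consequent, pt=pt
    )
    return hypergeom_upper_tail(counts)


def extract_rules(
    pairs: Iterable[tuple[Item, Item, int]],
    transactions: Sequence[Transaction],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[Rule]:
    """Form both directed rules per frequent pair; keep confidence >= minimum.

    Confidence of a -> b is pair support / support(a); an antecedent count
    of 0 cannot occur for a frequent pair.  Output ordered by (antecedent,
    consequent).
    """
    if not (0 < min_confidence <= 1):
        raise ValueError("min_confidence must be in (0, 1]")
    supports = item_supports(transactions)
    pt = len(transactions)
    rules: list[Rule] = []
    for tissue_item, pheno_item, support in pairs:
        p_value = rule_pvalue(
            support, supports[tissue_item], supports[pheno_item], pt
        )
        for antecedent, consequent in (
            (tissue_item, pheno_item),
            (pheno_item, tissue_item),
        ):
            confidence = support / supports[antecedent]
            if confidence >= min_confidence:
                rules.append(
                    Rule(
                        antecedent=antecedent,
                        consequent=consequent,
                        support_abs=support,
                        confidence=confidence,
                        p_value=p_value,
                    )
                )
    rules.sort(key=lambda r: (r.antecedent, r.consequent))
    return rules


def mine_rules(
    corpus: AnnotationCorpus,
    min_support_abs: int = DEFAULT_MIN_SUPPORT,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[Rule]:
    """Full mining pass: transactions -> frequent pairs -> confident rules."""
    transactions = corpus_to_transactions(corpus)
    pairs = frequent_pairs(transactions, min_support_abs=min_support_abs)
    return extract_rules(pairs, transactions, min_confidence=min_confidence)


def rules_to_associations(
    rules: Sequence[Rule],
    corpus: AnnotationCorpus,
    both_directions: bool = False,
) -> list[Association]:
    """Convert rules to Association records (method="rules").

    By default one row per (phenotype, tissue) pair is kept, choosing the
    max-confidence direction; ``both_directions`` keeps every rule.
    Supporting genes are recomputed as the genes co-annotated with both
    terms.
    """
    if not both_directions:
        best: dict[tuple[str, str], Rule] = {}
        for rule in rules:
            key = _pair_key(rule)
            kept = best.get(key)
            if kept is None or rule.confidence > kept.confidence:
                best[key] = rule
        rules = [best[k] for k in sorted(best)]

    genes = sorted(corpus.genes)
    pt = len(genes)
    out: list[Association] = []
    for rule in rules:
        tissue_item = (
            rule.antecedent if rule.antecedent.tag == TISSUE_TAG else rule.consequent
        )
        pheno_item = (
            rule.antecedent if rule.antecedent.tag == PHENOTYPE_TAG else rule.consequent
        )
        supporting = tuple(
            g
            for g in genes
            if tissue_item.term in corpus.tissues(g)
            and pheno_item.term in corpus.phenotypes(g)
        )
        n_tissue = sum(1 for g in genes if tissue_item.term in corpus.tissues(g))
        n_pheno = sum(1 for g in genes if pheno_item.term in corpus.phenotypes(g))
        out.append(
            Association(
                phenotype=pheno_item.term,
                tissue=tissue_item.term,
                method="rules",
                p_value=rule.p_value,
                counts=ContingencyCounts(
                    o_tp=rule.support_abs, t=n_tissue, p=n_pheno, pt=pt
                ),
                supporting_genes=supporting,
                antecedent=rule.antecedent.term,
                confidence=rule.confidence,
            )
        )
    out.sort(key=lambda a: (a.phenotype, a.p_value, a.tissue))
    return out


def _pair_key(rule: Rule) -> tuple[str, str]:
    if rule.antecedent.tag == PHENOTYPE_TAG:
        return (rule.antecedent.term, rule.consequent.term)
    return (rule.consequent.term, rule.antecedent.term)
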