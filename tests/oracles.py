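"""Independent oracles used by the test suite.

Everything here is deliberately separate from the package implementation:
exhaustive draw enumeration and exact-fraction tail sums for the
hypergeometric test, naive fixpoint/path-search reasoning for ontologies,
and brute-force rule enumeration for the miner.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def enumeration_tail_tables(pt: int) -> np.ndarray:
    """counts[t, k] = number of size-t subsets of range(pt) overlapping the
    first-p prefix in exactly k elements, for every p.

    Returns an array of shape (pt+1, pt+1, pt+1) indexed [p, t, k], computed
    by enumerating all 2**pt subsets as bitmasks (true exhaustive draw
    enumeration, vectorized).
    """
    subsets = np.arange(1 << pt, dtype=np.uint64)
    sizes = np.bitwise_count(subsets).astype(np.int64)
    out = np.zeros((pt + 1, pt + 1, pt + 1), dtype=np.int64)
    for p in range(pt + 1):
        mask = np.uint64((1 << p) - 1)
        overlap = np.bitwise_count(subsets & mask).astype(np.int64)
        flat = np.bincount(
            sizes * (pt + 1) + overlap, minlength=(pt + 1) * (pt + 1)
        )
        out[p] = flat.reshape(pt + 1, pt + 1)
    return out


def enumeration_upper_tail(counts: np.ndarray, pt: int, t: int, p: int, o: int) -> float:
    """Upper-tail probability from enumeration counts (exact integer sum)."""
    tail = int(counts[p, t, o:].sum())
    return tail / comb(pt, t)


def exact_fraction_upper_tail(o: int, t: int, p: int, pt: int) -> float:
    """Closed-form tail sum in exact rational arithmetic via math.comb."""
    total = Fraction(0)
    for k in range(o, min(t, p) + 1):
        total += Fraction(comb(p, k) * comb(pt - p, t - k), comb(pt, t))
    return float(total)


def naive_ancestor_fixpoint(term: str, edges) -> set[str]:
    """Iterated single-step parent expansion until fixpoint, excluding term."""
    parents_of: dict[str, set[str]] = {}
    for child, _, parent in edges:
        parents_of.setdefault(child, set()).add(parent)
    frontier = {term}
    closed: set[str] = set()
    while frontier:
        nxt = set()
        for node in frontier:
            for parent in parents_of.get(node, ()):
                if parent not in closed:
                    nxt.add(parent)
        closed |= nxt
        frontier = nxt
    return closed - {term}


def path_exists(a: str, b: str, edges) -> bool:
    """Exhaustive acyclic path search a -> b over (child, rel, parent) edges."""
    parents_of: dict[str, set[str]] = {}
    for child, _, parent in edges:
        parents_of.setdefault(child, set()).add(parent)

    def dfs(node: str, seen: frozenset[str]) -> bool:
        if node == b:
            return True
        for parent in parents_of.get(node, ()):
            if parent not in seen and dfs(parent, seen | {parent}):
                return True
        return False

    return a != b and dfs(a, frozenset([a]))


def brute_force_frequent_pairs(transactions, min_support):
    """All mixed-tag item pairs with co-occurrence >= min_support, no pruning."""
    items = set()
    for txn in transactions:
        items |= set(txn.items)
    tissues = sorted(i for i in items if i.tag == "tissue")
    phenos = sorted(i for i in items if i.tag == "phenotype")
    out = []
    for ti, pi in itertools.product(tissues, phenos):
        support = sum(1 for txn in transactions if ti in txn.items and pi in txn.items)
        if support >= min_support:
            out.append((ti, pi, support))
    return sorted(out)


def brute_force_rules(transactions, min_support, min_confidence):
    """Exhaustive directed mixed-tag rule search; returns comparable tuples."""
    rules = []
    for ti, pi, support in brute_force_frequent_pairs(transactions, min_support):
        for antecedent, consequent in ((ti, pi), (pi, ti)):
            n_ante = sum(1 for txn in transactions if antecedent in txn.items)
            confidence = support / n_ante
            if confidence >= min_confidence:
                rules.append((antecedent, consequent, support, confidence))
    return sorted(rules)


def random_dag_edges(rng, n_terms: int, edge_prob: float = 0.15):
    """Random DAG over term-0..term-(n-1): edges only child -> higher parent."""
    terms = [f"term-{i}" for i in range(n_terms)]
    edges = []
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < edge_prob:
                relation = "is_a" if rng.random() < 0.5 else "part_of"
                edges.append((terms[i], relation, terms[j]))
    return terms, edges
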