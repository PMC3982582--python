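"""Hypergeometric upper-tail scoring of tissue-phenotype pairs.

Every (tissue, phenotype) pair of a corpus is described by the contingency
quadruple (o_tp, t, p, pt): genes annotated with both terms, genes annotated
with the tissue, genes annotated with the phenotype, and the corpus gene
count.  The pair's score is the upper tail P(X >= o_tp) of a hypergeometric
distribution -- the probability of drawing at least the observed overlap
when t genes are sampled without replacement from a universe of pt genes of
which p carry the phenotype.  This is the one-sided ("greater") Fisher exact
p-value of the corresponding 2x2 table.

Tail sums are computed in log space via log-gamma so the test stays exact at
realistic corpus sizes (~10^4 genes); the final exponentiation is clamped to
(0, 1].  Significance filters: phenotypes must annotate at least
``min_phenotype_count`` genes (default 10) to be scored at all, and only
pairs with p <= ``p_cutoff`` (default 0.005, inclusive) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from phenotissue.corpus_io import AnnotationCorpus

DEFAULT_MIN_PHENOTYPE_COUNT = 10
DEFAULT_P_CUTOFF = 0.005

ASSOCIATION_COLUMNS = (
    "phenotype_id",
    "tissue_id",
    "method",
    "p_value",
    "o_tp",
    "t",
    "p",
    "pt",
    "supporting_genes",
)


class CountsError(ValueError):
    """Raised when a contingency quadruple violates its feasibility bounds."""


@dataclass(frozen=True)
class ContingencyCounts:
    """The (o_tp, t, p, pt) quadruple behind every p-value.

    o_tp: genes annotated with both the tissue and the phenotype;
    t: genes annotated with the tissue; p: genes annotated with the
    phenotype; pt: total genes in the corpus.
    """

    o_tp: int
    t: int
    p: int
    pt: int

    def __post_init__(self) -> None:
        if self.pt < 1:
            raise CountsError("pt must be >= 1 (empty universe)")
        if not (0 <= self.t <= self.pt and 0 <= self.p <= self.pt):
            raise CountsError(f"margins out of range: {self}")
        lo = max(0, self.t + self.p - self.pt)
        hi = min(self.t, self.p)
        if not (lo <= self.o_tp <= hi):
            raise CountsError(
                f"o_tp={self.o_tp} infeasible for margins t={self.t}, "
                f"p={self.p}, pt={self.pt} (bounds [{lo}, {hi}])"
            )


@dataclass(frozen=True)
class Association:
    """A scored tissue-phenotype link with its supporting evidence."""

    phenotype: str
    tissue: str
    method: str  # "hypergeom" or "rules"
    p_value: float
    counts: ContingencyCounts
    supporting_genes: tuple[str, ...] = ()
    # rule-mining extras; unset for the hypergeometric method
    antecedent: str | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.supporting_genes and len(self.supporting_genes) != self.counts.o_tp:
            raise CountsError(
                f"{len(self.supporting_genes)} supporting genes but o_tp="
                f"{self.counts.o_tp}"
            )


def contingency(
    corpus: AnnotationCorpus, tissue: str, phenotype: str
) -> ContingencyCounts:
    """Count the (o_tp, t, p, pt) quadruple for one pair over the corpus genes."""
    if tissue not in corpus.tissue_panel:
        raise CountsError(f"tissue {tissue!r} is not in the corpus panel")
    genes = corpus.genes
    if not genes:
        raise CountsError("corpus has no genes (pt must be >= 1)")
    o_tp = t = p = 0
    for gene in genes:
        has_t = tissue in corpus.tissues(gene)
        has_p = phenotype in corpus.phenotypes(gene)
        t += has_t
        p += has_p
        o_tp += has_t and has_p
    return ContingencyCounts(o_tp=o_tp, t=t, p=p, pt=len(genes))


def hypergeom_upper_tail(c: ContingencyCounts) -> float:
    """P(X >= o_tp) for X ~ Hypergeom(pt, p, t).

    Computed as sum_{k=o_tp}^{min(t,p)} C(p,k) C(pt-p, t-k) / C(pt,t) with
    each term evaluated through log-gamma and summed with logsumexp.
    Returns exactly 1.0 when o_tp is at its lower feasibility bound.
    """
    lo = max(0, c.t + c.p - c.pt)
    if c.o_tp <= lo:
        return 1.0
    t, p = sorted((c.t, c.p))  # canonical margin order: exact t<->p symmetry
    k = np.arange(c.o_tp, t + 1)
    log_terms = (
        _log_comb(p, k) + _log_comb(c.pt - p, t - k) - _log_comb(c.pt, t)
    )
    value = float(np.exp(logsumexp(log_terms)))
    return min(max(value, np.nextafter(0.0, 1.0)), 1.0)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def score_corpus(
    corpus: AnnotationCorpus,
    min_phenotype_count: int = DEFAULT_MIN_PHENOTYPE_COUNT,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[Association]:
    """Score all (tissue, phenotype) pairs and apply the occurrence/p filters.

    Phenotypes annotating fewer than ``min_phenotype_count`` genes are
    skipped entirely (tissues are not occurrence-filtered).  Pairs with
    p <= ``p_cutoff`` are emitted sorted by (phenotype, p_value, tissue).
    """
    genes = sorted(corpus.genes)
    if not genes:
        raise CountsError("corpus has no genes")
    pt = len(genes)

    tissue_genes: dict[str, set[str]] = {t: set() for t in corpus.tissue_panel}
    pheno_genes: dict[str, set[str]] = {}
    for gene in genes:
        for tissue in corpus.tissues(gene):
            tissue_genes[tissue].add(gene)
        for phenotype in corpus.phenotypes(gene):
            pheno_genes.setdefault(phenotype, set()).add(gene)

    out: list[Association] = []
    for phenotype in sorted(pheno_genes):
        pg = pheno_genes[phenotype]
        if len(pg) < min_phenotype_count:
            continue
        for tissue in corpus.tissue_panel:
            tg = tissue_genes[tissue]
            both = pg & tg
            counts = ContingencyCounts(
                o_tp=len(both), t=len(tg), p=len(pg), pt=pt
            )
            p_value = hypergeom_upper_tail(counts)
            if p_value <= p_cutoff:
                out.append(
                    Association(
                        phenotype=phenotype,
                        tissue=tissue,
                        method="hypergeom",
                        p_value=p_value,
                        counts=counts,
                        supporting_genes=tuple(sorted(both)),
                    )
                )
    out.sort(key=lambda a: (a.phenotype, a.p_value, a.tissue))
    return out


def format_pvalue(p: float) -> str:
    """Render a p-value with 6 significant digits in scientific notation."""
    return f"{p:.5e}"


def write_associations(
    associations: Sequence[Association], path: str | Path
) -> None:
    """Write associations as TSV; rule rows carry antecedent/confidence columns."""
    has_rules = any(a.method == "rules" for a in associations)
    columns = list(ASSOCIATION_COLUMNS)
    if has_rules:
        columns += ["antecedent", "confidence"]
    lines = ["\t".join(columns)]
    for a in associations:
        row = [
            a.phenotype,
            a.tissue,
            a.method,
            format_pvalue(a.p_value),
            str(a.counts.o_tp),
            str(a.counts.t),
            str(a.counts.p),
            str(a.counts.pt),
            ",".join(a.supporting_genes),
        ]
        if has_rules:
            row.append(a.antecedent or "-")
            row.append("-" if a.confidence is None else f"{a.confidence:.6f}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_associations(path: str | Path) -> list[Association]:
    """Read a TSV written by :func:`write_associations`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        return []
    header = rows[0].split("\t")
    out: list[Association] = []
    for line in rows[1:]:
        row = dict(zip(header, line.split("\t")))
        genes = tuple(g for g in row["supporting_genes"].split(",") if g)
        confidence = row.get("confidence")
        antecedent = row.get("antecedent")
        out.append(
            Association(
                phenotype=row["phenotype_id"],
                tissue=row["tissue_id"],
                method=row["method"],
                p_value=float(row["p_value"]),
                counts=ContingencyCounts(
                    o_tp=int(row["o_tp"]),
                    t=int(row["t"]),
                    p=int(row["p"]),
                    pt=int(row["pt"]),
                ),
                supporting_genes=genes,
                antecedent=None if antecedent in (None, "-") else antecedent,
                confidence=(
                    None
                    if confidence in (None, "-")
                    else float(confidence)
                ),
            )
        )
    return out
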