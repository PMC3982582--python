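"""Expression-constrained re-ranking of disease-gene candidate lists.

Given a pre-ranked candidate list and a set of query phenotypes, the tissues
associated with those phenotypes are collected from a scored association
table, and the top-N candidates are filtered to genes with at least one
'present' call in any of those tissues.  Survivors keep their relative
order and original scores; ranks are renumbered 1..k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from phenotissue.corpus_io import AnnotationCorpus
from phenotissue.enrichment import Association

DEFAULT_TOP_N = 200


class CandidateError(ValueError):
    """Raised for malformed candidate lists."""


@dataclass(frozen=True)
class Candidate:
    rank: int
    gene: str
    score: float
    original_rank: int | None = None


def validate_candidates(candidates: Sequence[Candidate]) -> None:
    """Check ranks are consecutive from 1 and scores non-increasing."""
    for i, c in enumerate(candidates, start=1):
        if c.rank != i:
            raise CandidateError(f"ranks not consecutive from 1 (position {i}: {c.rank})")
    scores = [c.score for c in candidates]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise CandidateError("scores must be non-increasing with rank")


def tissues_for_phenotypes(
    phenotypes: Iterable[str], associations: Sequence[Association]
) -> set[str]:
    """Union of tissues over all associations whose phenotype is in the query set."""
    query = set(phenotypes)
    return {a.tissue for a in associations if a.phenotype in query}


def rerank(
    candidates: Sequence[Candidate],
    tissues: set[str],
    corpus: AnnotationCorpus,
    top_n: int = DEFAULT_TOP_N,
    require_all: bool = False,
) -> list[Candidate]:
    """Filter the top-N candidates to genes expressed in the query tissues.

    A gene survives with >= 1 'present' call in ANY query tissue (or in ALL
    of them with ``require_all``).  Genes absent from the corpus are treated
    as not expressed and dropped.  Survivors are renumbered 1..k, stable.
    """
    if top_n < 1:
        raise CandidateError("top_n must be >= 1")
    validate_candidates(candidates)
    survivors: list[Candidate] = []
    for c in candidates[:top_n]:
        expressed_in = corpus.tissues(c.gene) & tissues
        keep = expressed_in == tissues if require_all else bool(expressed_in)
        if keep:
            survivors.append(
                replace(c, rank=len(survivors) + 1, original_rank=c.rank)
            )
    return survivors


def read_candidates(path: str | Path) -> list[Candidate]:
    """Read a ``rank\\tgene_id\\tscore`` TSV."""
    out: list[Candidate] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "rank":
            continue
        if len(parts) < 3:
            raise CandidateError(f"malformed candidate row: {line!r}")
        out.append(Candidate(rank=int(parts[0]), gene=parts[1], score=float(parts[2])))
    validate_candidates(out)
    return out


def write_candidates(candidates: Sequence[Candidate], path: str | Path) -> None:
    """Write candidates with an ``original_rank`` column when present."""
    lines = ["rank\tgene_id\tscore\toriginal_rank"]
    for c in candidates:
        original = "-" if c.original_rank is None else str(c.original_rank)
        lines.append(f"{c.rank}\t{c.gene}\t{c.score:g}\t{original}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
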