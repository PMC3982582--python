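"""Read, map, merge and validate annotation inputs into one corpus.

Expression calls arrive as four-valued tokens (present/absent/ambiguous/
no_data) from multiple sources; only 'present' calls ever reach the corpus.
Sources are merged by union, gene identifiers are canonicalized through a
cross-reference map (unmappable records are dropped and counted), and
phenotype annotations are accumulated per gene as plain sets with no
ontology propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CALL_TOKENS = ("present", "absent", "ambiguous", "no_data")
# collapse priority for duplicate (gene, tissue) rows within one source
_CALL_RANK = {"present": 0, "ambiguous": 1, "absent": 2, "no_data": 3}


class CorpusError(ValueError):
    """Raised for malformed annotation inputs."""


@dataclass(frozen=True)
class ExpressionCall:
    gene: str
    tissue: str
    source: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALL_TOKENS:
            raise CorpusError(f"invalid call token {self.call!r}")


@dataclass(frozen=True)
class GeneIdMap:
    """Map from foreign gene ids to canonical gene ids."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for foreign, canonical in self.entries.items():
            if not canonical:
                raise CorpusError(f"empty canonical id for foreign id {foreign!r}")

    def get(self, foreign: str) -> str | None:
        return self.entries.get(foreign)


@dataclass
class MapReport:
    """Bookkeeping from a gene-id mapping pass."""

    mapped: int = 0
    dropped: int = 0
    merged: int = 0


@dataclass
class AnnotationCorpus:
    """Per-gene tissue and phenotype annotation sets over a fixed tissue panel.

    This is the universe for all downstream counting: ``genes`` is exactly
    the union of the domains of ``tissues_of`` and ``phenotypes_of``, and
    every tissue appearing in any ``tissues_of`` value is a panel member.
    """

    tissue_panel: list[str]
    tissues_of: dict[str, set[str]] = field(default_factory=dict)
    phenotypes_of: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tissue_panel:
            raise CorpusError("tissue panel must be non-empty")
        if len(set(self.tissue_panel)) != len(self.tissue_panel):
            raise CorpusError("tissue panel contains duplicates")
        panel = set(self.tissue_panel)
        for gene, tissues in self.tissues_of.items():
            extra = tissues - panel
            if extra:
                raise CorpusError(
                    f"gene {gene}: tissues outside the panel: {sorted(extra)}"
                )

    @property
    def genes(self) -> set[str]:
        return set(self.tissues_of) | set(self.phenotypes_of)

    def tissues(self, gene: str) -> set[str]:
        return self.tissues_of.get(gene, set())

    def phenotypes(self, gene: str) -> set[str]:
        return self.phenotypes_of.get(gene, set())


def read_expression_calls(
    path_or_rows: str | Path | Iterable[Sequence[str]],
    source: str = "default",
) -> list[ExpressionCall]:
    """Parse an expression-call table for one source.

    Accepts a TSV path (columns ``gene_id``, ``tissue_id``, ``call``,
    optional ``source``) or an iterable of pre-split rows.  Duplicate
    (gene, tissue) rows within the source collapse with 'present' winning
    over any other call for the same pair.
    """
    if isinstance(path_or_rows, (str, Path)):
        rows = _read_tsv_rows(
            Path(path_or_rows),
            required=("gene_id", "tissue_id", "call"),
            optional=("source",),
        )
    else:
        rows = [
            {"gene_id": r[0], "tissue_id": r[1], "call": r[2]}
            for r in path_or_rows
        ]

    best: dict[tuple[str, str, str], str] = {}
    for lineno, row in enumerate(rows, start=1):
        call = row["call"]
        if call not in CALL_TOKENS:
            raise CorpusError(f"row {lineno}: invalid call token {call!r}")
        src = row.get("source") or source
        key = (row["gene_id"], row["tissue_id"], src)
        prev = best.get(key)
        if prev is None or _CALL_RANK[call] < _CALL_RANK[prev]:
            best[key] = call
    return [
        ExpressionCall(gene=g, tissue=t, source=s, call=c)
        for (g, t, s), c in best.items()
    ]


def read_phenotype_annotations(
    path_or_rows: str | Path | Iterable[Sequence[str]],
) -> list[tuple[str, str]]:
    """Parse gene->phenotype annotation pairs from TSV or pre-split rows."""
    if isinstance(path_or_rows, (str, Path)):
        rows = _read_tsv_rows(
            Path(path_or_rows), required=("gene_id", "phenotype_id")
        )
        return [(r["gene_id"], r["phenotype_id"]) for r in rows]
    return [(r[0], r[1]) for r in path_or_rows]


def read_gene_map(path: str | Path) -> GeneIdMap:
    """Parse a ``foreign_id\\tcanonical_id`` TSV into a :class:`GeneIdMap`."""
    rows = _read_tsv_rows(Path(path), required=("foreign_id", "canonical_id"))
    entries: dict[str, str] = {}
    for row in rows:
        foreign, canonical = row["foreign_id"], row["canonical_id"]
        if foreign in entries and entries[foreign] != canonical:
            raise CorpusError(f"foreign id {foreign!r} maps to multiple canonical ids")
        entries[foreign] = canonical
    return GeneIdMap(entries=entries)


def read_panel(path: str | Path) -> list[str]:
    """Read a newline-separated tissue panel file."""
    panel = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            panel.append(line)
    return panel


def apply_gene_map(records, gene_map: GeneIdMap):
    """Canonicalize gene ids; drop (and count) records with no map entry.

    ``records`` may be a list of :class:`ExpressionCall` or of
    ``(gene, annotation)`` tuples.  Records that share a canonical id after
    mapping are merged (for calls, duplicate (gene, tissue, source) triples
    collapse with 'present' winning).  Returns ``(mapped_records, report)``.
    """
    report = MapReport()
    if records and isinstance(records[0], ExpressionCall):
        best: dict[tuple[str, str, str], str] = {}
        for call in records:
            canonical = gene_map.get(call.gene)
            if canonical is None:
                report.dropped += 1
                continue
            report.mapped += 1
            key = (canonical, call.tissue, call.source)
            prev = best.get(key)
            if prev is not None:
                report.merged += 1
            if prev is None or _CALL_RANK[call.call] < _CALL_RANK[prev]:
                best[key] = call.call
        mapped = [
            ExpressionCall(gene=g, tissue=t, source=s, call=c)
            for (g, t, s), c in best.items()
        ]
        return mapped, report

    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for gene, annotation in records:
        canonical = gene_map.get(gene)
        if canonical is None:
            report.dropped += 1
            continue
        report.mapped += 1
        key = (canonical, annotation)
        if key in seen:
            report.merged += 1
            continue
        seen.add(key)
        out.append(key)
    return out, report


def build_corpus(
    sources: Sequence[Sequence[ExpressionCall]],
    phenotype_annotations: Iterable[tuple[str, str]],
    panel: Sequence[str],
    stats: dict | None = None,
) -> AnnotationCorpus:
    """Merge call sources and phenotype pairs into an :class:`AnnotationCorpus`.

    ``tissues_of[g]`` is the union over sources of panel tissues where ``g``
    has a 'present' call; calls on tissues outside the panel are discarded
    and counted in ``stats['off_panel_calls']`` when a stats dict is given.
    Genes with neither expression nor phenotype annotations do not appear.
    """
    if not panel:
        raise CorpusError("tissue panel must be non-empty")
    panel_set = set(panel)
    tissues_of: dict[str, set[str]] = {}
    off_panel = 0
    non_present = 0
    for calls in sources:
        for call in calls:
            if call.call != "present":
                non_present += 1
                continue
            if call.tissue not in panel_set:
                off_panel += 1
                continue
            tissues_of.setdefault(call.gene, set()).add(call.tissue)

    phenotypes_of: dict[str, set[str]] = {}
    for gene, phenotype in phenotype_annotations:
        phenotypes_of.setdefault(gene, set()).add(phenotype)

    if stats is not None:
        stats["off_panel_calls"] = off_panel
        stats["non_present_calls"] = non_present
        stats["n_genes"] = len(set(tissues_of) | set(phenotypes_of))
    if off_panel:
        logger.info("discarded %d 'present' calls on off-panel tissues", off_panel)

    return AnnotationCorpus(
        tissue_panel=list(panel),
        tissues_of=tissues_of,
        phenotypes_of=phenotypes_of,
    )


def write_corpus(corpus: AnnotationCorpus, path: str | Path) -> None:
    """Serialize a corpus to TSV (panel in a header comment, one gene per row)."""
    lines = ["# phenotissue corpus v1"]
    lines.append("# panel: " + ",".join(corpus.tissue_panel))
    lines.append("gene_id\ttissues\tphenotypes")
    for gene in sorted(corpus.genes):
        tissues = ",".join(sorted(corpus.tissues(gene)))
        phenotypes = ",".join(sorted(corpus.phenotypes(gene)))
        lines.append(f"{gene}\t{tissues}\t{phenotypes}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus(path: str | Path) -> AnnotationCorpus:
    """Read a corpus written by :func:`write_corpus`."""
    panel: list[str] | None = None
    tissues_of: dict[str, set[str]] = {}
    phenotypes_of: dict[str, set[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if line.startswith("# panel:"):
            panel = [t for t in line[len("# panel:"):].strip().split(",") if t]
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "gene_id":
            continue
        if len(parts) != 3:
            raise CorpusError(f"malformed corpus row: {line!r}")
        gene, tissues, phenotypes = parts
        if tissues:
            tissues_of[gene] = set(tissues.split(","))
        if phenotypes:
            phenotypes_of[gene] = set(phenotypes.split(","))
    if panel is None:
        raise CorpusError("corpus file lacks a '# panel:' header")
    return AnnotationCorpus(
        tissue_panel=panel, tissues_of=tissues_of, phenotypes_of=phenotypes_of
    )


def _read_tsv_rows(
    path: Path,
    required: tuple[str, ...],
    optional: tuple[str, ...] = (),
) -> list[dict[str, str]]:
    """Read a headered TSV, returning dict rows; '#' lines are comments."""
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            missing = [c for c in required if c not in header]
            if missing:
                raise CorpusError(f"{path}: missing required columns {missing}")
            continue
        if len(parts) != len(header):
            raise CorpusError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        row = dict(zip(header, (p.strip() for p in parts)))
        rows.append({k: row[k] for k in (*required, *optional) if k in row})
    if header is None:
        raise CorpusError(f"{path}: empty file (no header)")
    return rows
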