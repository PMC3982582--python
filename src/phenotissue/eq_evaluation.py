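"""Evaluate predicted associations against EQ-statement gold anatomy.

Each phenotype's EQ statement names the anatomical entities it affects
(qualities are ignored).  A predicted (phenotype, tissue) association is
classified against the phenotype's gold entities as:

    exact     predicted tissue identical to a gold entity
    psp       predicted tissue is below (subclass/part_of) a gold entity
    ldsp      a gold entity is below the predicted tissue
    no_match  no gold entity relates to the predicted tissue
    no_eq     the phenotype has no EQ statement representable with the panel

Multi-entity statements match on ANY entity with priority
exact > psp > ldsp.  Percentage denominators exclude no_eq rows: summaries
report match rates only over phenotypes/associations that have a
representable EQ statement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from phenotissue.enrichment import Association
from phenotissue.ontology import OntologyGraph, RelationCategory

CATEGORIES = ("exact", "psp", "ldsp", "no_match", "no_eq")
_PRIORITY = {"exact": 0, "psp": 1, "ldsp": 2}


class EvaluationError(ValueError):
    """Raised for malformed EQ inputs or terms unknown to the ontology."""


@dataclass(frozen=True)
class EQStatement:
    """A phenotype's gold anatomical entities, in the working vocabulary."""

    phenotype: str
    entities: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entities:
            raise EvaluationError(
                f"EQ statement for {self.phenotype} has no entities"
            )


@dataclass(frozen=True)
class EvaluationRecord:
    phenotype: str
    tissue: str
    method: str
    category: str
    matched_entity: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise EvaluationError(f"unknown category {self.category!r}")
        has_match = self.category in ("exact", "psp", "ldsp")
        if has_match != (self.matched_entity is not None):
            raise EvaluationError(
                "matched_entity must be present exactly for exact/psp/ldsp"
            )


@dataclass
class EvaluationSummary:
    """Association-level and phenotype-level tallies for one record set."""

    associations: dict[str, int] = field(default_factory=dict)
    phenotypes_expected: int = 0
    phenotypes_not_expected: int = 0
    phenotypes_no_eq: int = 0

    @property
    def total_associations(self) -> int:
        return sum(self.associations.values())

    @property
    def total_phenotypes(self) -> int:
        return (
            self.phenotypes_expected
            + self.phenotypes_not_expected
            + self.phenotypes_no_eq
        )

    @property
    def associations_with_eq(self) -> int:
        return self.total_associations - self.associations.get("no_eq", 0)

    @property
    def phenotypes_with_eq(self) -> int:
        return self.phenotypes_expected + self.phenotypes_not_expected

    def phenotype_expected_pct(self) -> float | None:
        """Share of with-EQ phenotypes recovering an expected tissue."""
        if self.phenotypes_with_eq == 0:
            return None
        return 100.0 * self.phenotypes_expected / self.phenotypes_with_eq

    def association_category_pct(self, category: str) -> float | None:
        if self.associations_with_eq == 0:
            return None
        return 100.0 * self.associations.get(category, 0) / self.associations_with_eq


def load_eq(
    eq_path: str | Path,
    xref_path: str | Path | None,
    anatomy: OntologyGraph,
    stats: dict | None = None,
) -> dict[str, EQStatement]:
    """Load EQ rows and cross-reference entities into the working anatomy.

    EQ TSV: ``phenotype_id\\tanatomy_id`` (one entity per row); xref TSV:
    ``foreign_id\\tworking_id``.  An entity id is first translated through
    the xref table; ids with no xref that are already in the ontology pass
    through unchanged; anything else is dropped and counted.  Phenotypes
    whose every row drops are absent from the result.
    """
    xref: dict[str, str] = {}
    if xref_path is not None:
        for lineno, parts in _tsv_rows(Path(xref_path)):
            if len(parts) != 2:
                raise EvaluationError(
                    f"{xref_path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            xref[parts[0]] = parts[1]

    entities_of: dict[str, set[str]] = {}
    dropped = 0
    for lineno, parts in _tsv_rows(Path(eq_path)):
        if len(parts) != 2:
            raise EvaluationError(
                f"{eq_path}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        phenotype, raw_entity = parts
        entity = xref.get(raw_entity, raw_entity)
        if entity not in anatomy:
            dropped += 1
            continue
        entities_of.setdefault(phenotype, set()).add(entity)

    if stats is not None:
        stats["dropped_entities"] = dropped
    return {
        p: EQStatement(phenotype=p, entities=frozenset(ents))
        for p, ents in entities_of.items()
    }


def representable(
    eq: EQStatement, panel: Sequence[str], anatomy: OntologyGraph
) -> bool:
    """True iff some entity relates (either direction, transitively) to a panel tissue."""
    for entity in eq.entities:
        for tissue in panel:
            if tissue not in anatomy:
                continue
            if anatomy.relate(entity, tissue) is not RelationCategory.UNRELATED:
                return True
    return False


def classify(
    assoc: Association,
    gold: Mapping[str, EQStatement],
    anatomy: OntologyGraph,
    panel: Sequence[str],
) -> EvaluationRecord:
    """Classify one association against the gold EQ map.

    ``no_eq`` when the phenotype has no representable EQ statement; else the
    best category over all gold entities with priority exact > psp > ldsp,
    falling back to ``no_match``.
    """
    if assoc.tissue not in anatomy:
        raise EvaluationError(f"predicted tissue {assoc.tissue!r} unknown to ontology")
    eq = gold.get(assoc.phenotype)
    if eq is None or not representable(eq, panel, anatomy):
        return EvaluationRecord(
            phenotype=assoc.phenotype,
            tissue=assoc.tissue,
            method=assoc.method,
            category="no_eq",
        )

    best: tuple[int, str, str] | None = None  # (priority, entity, category)
    for entity in sorted(eq.entities):
        relation = anatomy.relate(assoc.tissue, entity)
        if relation is RelationCategory.IDENTICAL:
            category = "exact"
        elif relation is RelationCategory.FIRST_BELOW_SECOND:
            category = "psp"
        elif relation is RelationCategory.SECOND_BELOW_FIRST:
            category = "ldsp"
        else:
            continue
        candidate = (_PRIORITY[category], entity, category)
        if best is None or candidate < best:
            best = candidate

    if best is None:
        return EvaluationRecord(
            phenotype=assoc.phenotype,
            tissue=assoc.tissue,
            method=assoc.method,
            category="no_match",
        )
    return EvaluationRecord(
        phenotype=assoc.phenotype,
        tissue=assoc.tissue,
        method=assoc.method,
        category=best[2],
        matched_entity=best[1],
    )


def evaluate(
    associations: Sequence[Association],
    gold: Mapping[str, EQStatement],
    anatomy: OntologyGraph,
    panel: Sequence[str],
) -> list[EvaluationRecord]:
    """Classify every association."""
    return [classify(a, gold, anatomy, panel) for a in associations]


def summarize(records: Iterable[EvaluationRecord]) -> EvaluationSummary:
    """Tally records at the association and phenotype level.

    A phenotype with a representable EQ is 'expected' iff any of its
    associations is exact/psp/ldsp; phenotypes whose records are all no_eq
    count in the no_eq row.  Percentages use with-EQ denominators only.
    """
    records = list(records)
    assoc_counts = Counter(r.category for r in records)

    by_phenotype: dict[str, set[str]] = {}
    for r in records:
        by_phenotype.setdefault(r.phenotype, set()).add(r.category)

    expected = not_expected = no_eq = 0
    for categories in by_phenotype.values():
        if categories <= {"no_eq"}:
            no_eq += 1
        elif categories & {"exact", "psp", "ldsp"}:
            expected += 1
        else:
            not_expected += 1

    return EvaluationSummary(
        associations={c: assoc_counts.get(c, 0) for c in CATEGORIES},
        phenotypes_expected=expected,
        phenotypes_not_expected=not_expected,
        phenotypes_no_eq=no_eq,
    )


def summarize_by_method(
    records: Iterable[EvaluationRecord],
) -> dict[str, EvaluationSummary]:
    """Per-method summaries keyed by method tag."""
    grouped: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        grouped.setdefault(r.method, []).append(r)
    return {m: summarize(rs) for m, rs in sorted(grouped.items())}


def write_records(records: Sequence[EvaluationRecord], path: str | Path) -> None:
    lines = ["phenotype_id\ttissue_id\tmethod\tcategory\tmatched_entity"]
    for r in records:
        lines.append(
            "\t".join(
                (r.phenotype, r.tissue, r.method, r.category, r.matched_entity or "-")
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def format_summary(summaries: Mapping[str, EvaluationSummary]) -> str:
    """Pretty text table of per-method tallies and with-EQ percentages."""
    lines: list[str] = []
    for method, s in summaries.items():
        lines.append(f"method: {method}")
        lines.append("  association level:")
        for category in CATEGORIES:
            n = s.associations.get(category, 0)
            pct = (
                s.association_category_pct(category)
                if category != "no_eq"
                else None
            )
            suffix = f" ({pct:.0f}%)" if pct is not None else ""
            lines.append(f"    {category:<9} {n}{suffix}")
        lines.append(f"    total     {s.total_associations}")
        lines.append("  phenotype level:")
        pct = s.phenotype_expected_pct()
        suffix = f" ({pct:.0f}%)" if pct is not None else ""
        lines.append(f"    expected      {s.phenotypes_expected}{suffix}")
        lines.append(f"    not_expected  {s.phenotypes_not_expected}")
        lines.append(f"    no_eq         {s.phenotypes_no_eq}")
        lines.append(f"    total         {s.total_phenotypes}")
    return "\n".join(lines) + "\n"


def _tsv_rows(path: Path):
    first = True
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if first:
            first = False
            if parts[0] in ("phenotype_id", "foreign_id"):
                continue  # header row
        yield lineno, parts
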