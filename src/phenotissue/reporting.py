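"""Combine method outputs and render flat-file browse views.

The combined table outer-joins the two method outputs on
(phenotype, tissue); a hyphen in a method's p-value column means that
method found no significant association for the pair.  The browse export
writes one markdown block per phenotype listing its significant tissues,
per-method p-values, the EQ statement when known, and supporting genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from phenotissue.corpus_io import AnnotationCorpus
from phenotissue.enrichment import Association, format_pvalue
from phenotissue.eq_evaluation import EQStatement

COMBINED_HEADER = (
    "phenotype_id\ttissue_id\tp_hypergeom\tp_rules\tn_support\tsupporting_genes"
)


class CombineError(ValueError):
    """Raised when the two method outputs disagree on shared evidence."""


@dataclass(frozen=True)
class CombinedRow:
    phenotype: str
    tissue: str
    p_hypergeom: float | None
    p_rules: float | None
    supporting_genes: tuple[str, ...]

    @property
    def n_support(self) -> int:
        return len(self.supporting_genes)


@dataclass
class CombinedResults:
    rows: list[CombinedRow]

    @property
    def n_associations(self) -> int:
        return len(self.rows)

    @property
    def n_phenotypes(self) -> int:
        return len({r.phenotype for r in self.rows})


def combine(
    hyper: Sequence[Association], rules: Sequence[Association]
) -> CombinedResults:
    """Outer-join the two association lists on (phenotype, tissue).

    Supporting-gene lists for a shared key must agree (both methods count
    over the same corpus); a mismatch indicates a corpus mismatch and is an
    error.
    """
    merged: dict[tuple[str, str], dict] = {}
    for assoc_list, column in ((hyper, "p_hypergeom"), (rules, "p_rules")):
        for a in assoc_list:
            key = (a.phenotype, a.tissue)
            entry = merged.setdefault(
                key, {"p_hypergeom": None, "p_rules": None, "genes": None}
            )
            entry[column] = a.p_value
            genes = tuple(a.supporting_genes)
            if entry["genes"] is not None and entry["genes"] != genes:
                raise CombineError(
                    f"conflicting supporting genes for {key}: corpus mismatch?"
                )
            entry["genes"] = genes

    rows = [
        CombinedRow(
            phenotype=phenotype,
            tissue=tissue,
            p_hypergeom=entry["p_hypergeom"],
            p_rules=entry["p_rules"],
            supporting_genes=entry["genes"] or (),
        )
        for (phenotype, tissue), entry in sorted(merged.items())
    ]
    return CombinedResults(rows=rows)


def write_combined(combined: CombinedResults, path: str | Path) -> None:
    lines = [COMBINED_HEADER]
    for r in combined.rows:
        lines.append(
            "\t".join(
                (
                    r.phenotype,
                    r.tissue,
                    "-" if r.p_hypergeom is None else format_pvalue(r.p_hypergeom),
                    "-" if r.p_rules is None else format_pvalue(r.p_rules),
                    str(r.n_support),
                    ",".join(r.supporting_genes),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_combined(path: str | Path) -> CombinedResults:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows: list[CombinedRow] = []
    for line in lines:
        if not line.strip() or line.startswith("#") or line == COMBINED_HEADER:
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise CombineError(f"malformed combined row: {line!r}")
        phenotype, tissue, p_h, p_r, _, genes = parts
        rows.append(
            CombinedRow(
                phenotype=phenotype,
                tissue=tissue,
                p_hypergeom=None if p_h == "-" else float(p_h),
                p_rules=None if p_r == "-" else float(p_r),
                supporting_genes=tuple(g for g in genes.split(",") if g),
            )
        )
    return CombinedResults(rows=rows)


def browse_export(
    combined: CombinedResults,
    corpus: AnnotationCorpus,
    out_dir: str | Path,
    eq: Mapping[str, EQStatement] | None = None,
) -> list[Path]:
    """Write one markdown report per phenotype with associations.

    Phenotypes with no associations get no file.  Term ids containing
    ``:`` are made filesystem-safe by replacing it with ``_``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_phenotype: dict[str, list[CombinedRow]] = {}
    for row in combined.rows:
        by_phenotype.setdefault(row.phenotype, []).append(row)

    written: list[Path] = []
    for phenotype in sorted(by_phenotype):
        rows = by_phenotype[phenotype]
        lines = [f"# {phenotype}", ""]
        if eq and phenotype in eq:
            entities = ", ".join(sorted(eq[phenotype].entities))
            lines += [f"EQ entities: {entities}", ""]
        lines.append("| tissue | p (hypergeom) | p (rules) | supporting genes |")
        lines.append("|---|---|---|---|")
        for r in rows:
            lines.append(
                "| {} | {} | {} | {} |".format(
                    r.tissue,
                    "-" if r.p_hypergeom is None else format_pvalue(r.p_hypergeom),
                    "-" if r.p_rules is None else format_pvalue(r.p_rules),
                    ", ".join(r.supporting_genes),
                )
            )
        path = out / f"{phenotype.replace(':', '_')}.md"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written
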