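"""Seed-reproducible synthetic input bundles with planted associations.

Emulates the shape of the real inputs: a ~21-tissue panel, thousands of
genes with sparse 'present' calls split across two overlapping expression
sources, dense per-gene phenotype annotation lists, a small anatomy DAG
whose terms sit above and below the panel tissues, EQ statements for a
subset of phenotypes (routed through a foreign-id cross-reference table),
and a ranked candidate-gene list.

Planting model: for a non-planted (tissue, phenotype) pair, membership in
the tissue's and the phenotype's gene sets is independent at the configured
base rates.  For a planted pair, P(phenotype | tissue-expressed) is
inflated on the odds scale by ``enrichment_odds``.

All randomness flows from a single master seed through named SeedSequence
substreams, so identical configs produce byte-identical bundles and
changing one component's draws does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from phenotissue.corpus_io import (
    AnnotationCorpus,
    ExpressionCall,
    GeneIdMap,
    apply_gene_map,
    build_corpus,
)
from phenotissue.enrichment import Association
from phenotissue.ontology import OntologyGraph, build_graph
from phenotissue.prioritization import Candidate

_STREAMS = ("expression", "phenotypes", "source_split", "noise", "eq", "candidates")

ROOT_TERM = "ANAT:ROOT"


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    n_phenotypes: int
    tissue_panel_size: int = 21
    mean_phenotypes_per_gene: float = 13.4
    tissue_call_rate: float = 0.3
    planted: tuple[tuple[int, int, float], ...] = ()
    eq_coverage: float = 0.8
    eq_correct_fraction: float = 0.8
    n_candidates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_phenotypes < 1 or self.tissue_panel_size < 1:
            raise ConfigError("n_genes, n_phenotypes, tissue_panel_size must be >= 1")
        if self.mean_phenotypes_per_gene > self.n_phenotypes:
            raise ConfigError(
                "expected phenotype count per gene exceeds n_phenotypes"
            )
        for name in ("tissue_call_rate", "eq_coverage", "eq_correct_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        for t_idx, p_idx, odds in self.planted:
            if not (0 <= t_idx < self.tissue_panel_size):
                raise ConfigError(f"planted tissue index {t_idx} out of range")
            if not (0 <= p_idx < self.n_phenotypes):
                raise ConfigError(f"planted phenotype index {p_idx} out of range")
            if odds < 1.0:
                raise ConfigError("enrichment_odds must be >= 1")
        if len({(t, p) for t, p, _ in self.planted}) != len(self.planted):
            raise ConfigError("duplicate planted pairs")

    @property
    def base_phenotype_rate(self) -> float:
        return self.mean_phenotypes_per_gene / self.n_phenotypes


@dataclass
class Bundle:
    """All in-memory artifacts of one simulation run."""

    config: SimulationConfig
    panel: list[str]
    genes: list[str]
    phenotype_ids: list[str]
    anatomy_edges: list[tuple[str, str, str]]
    anatomy: OntologyGraph
    sources: dict[str, list[ExpressionCall]]
    gene_map: GeneIdMap
    phenotype_annotations: list[tuple[str, str]]
    eq_rows: list[tuple[str, str]]
    xref_rows: list[tuple[str, str]]
    truth: list[tuple[str, str]]  # (tissue_id, phenotype_id) planted pairs
    candidates: list[Candidate]
    corpus: AnnotationCorpus = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    false_positives: int
    n_planted: int
    n_recovered: int


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {
        name: np.random.Generator(np.random.PCG64(ss))
        for name, ss in zip(_STREAMS, children)
    }


def tissue_id(i: int) -> str:
    return f"TIS:{i:03d}"


def phenotype_id(i: int) -> str:
    return f"PHEN:{i:04d}"


def gene_id(i: int) -> str:
    return f"GENE:{i:05d}"


def foreign_gene_id(i: int) -> str:
    return f"ENSX:{i:07d}"


def _anatomy_edges(panel: Sequence[str]) -> list[tuple[str, str, str]]:
    """A small DAG: sub part_of tissue, tissue is_a region, region is_a root."""
    edges: list[tuple[str, str, str]] = []
    for i, tissue in enumerate(panel):
        region = f"REG:{i:03d}"
        sub = f"SUB:{i:03d}"
        edges.append((sub, "part_of", tissue))
        edges.append((tissue, "is_a", region))
        edges.append((region, "is_a", ROOT_TERM))
    return edges


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate a complete input bundle; identical seed => identical bundle."""
    rngs = _substreams(config.seed)
    n_genes = config.n_genes
    n_tissues = config.tissue_panel_size
    n_phenos = config.n_phenotypes

    panel = [tissue_id(i) for i in range(n_tissues)]
    genes = [gene_id(i) for i in range(n_genes)]
    phenotype_ids = [phenotype_id(i) for i in range(n_phenos)]

    # --- expression presence and phenotype membership matrices -------------
    present = rngs["expression"].random((n_genes, n_tissues)) < config.tissue_call_rate

    q = config.base_phenotype_rate
    prob = np.full((n_genes, n_phenos), q)
    for t_idx, p_idx, odds in config.planted:
        inflated = odds * q / (1.0 - q + odds * q)
        prob[present[:, t_idx], p_idx] = inflated
    has_pheno = rngs["phenotypes"].random((n_genes, n_phenos)) < prob

    # --- split present calls across two overlapping sources ----------------
    gi, ti = np.nonzero(present)
    split = rngs["source_split"].random(len(gi))
    calls_a: list[ExpressionCall] = []
    calls_b: list[ExpressionCall] = []
    for g, t, u in zip(gi, ti, split):
        call_args = dict(
            gene=foreign_gene_id(g), tissue=panel[t], call="present"
        )
        if u < 0.35:
            calls_a.append(ExpressionCall(source="lacz", **call_args))
        elif u < 0.70:
            calls_b.append(ExpressionCall(source="barcode", **call_args))
        else:
            calls_a.append(ExpressionCall(source="lacz", **call_args))
            calls_b.append(ExpressionCall(source="barcode", **call_args))

    # sprinkle non-present calls so the 'present'-only filter is exercised
    gj, tj = np.nonzero(~present)
    v = rngs["noise"].random(len(gj))
    for g, t, u in zip(gj, tj, v):
        if u >= 0.16:
            continue
        if u < 0.06:
            token, sink, src = "absent", calls_a, "lacz"
        elif u < 0.12:
            token, sink, src = "absent", calls_b, "barcode"
        elif u < 0.14:
            token, sink, src = "ambiguous", calls_a, "lacz"
        else:
            token, sink, src = "no_data", calls_b, "barcode"
        sink.append(
            ExpressionCall(
                gene=foreign_gene_id(g), tissue=panel[t], call=token, source=src
            )
        )

    gene_map = GeneIdMap(
        entries={foreign_gene_id(i): gene_id(i) for i in range(n_genes)}
    )

    phenotype_annotations = [
        (genes[g], phenotype_ids[p]) for g, p in zip(*np.nonzero(has_pheno))
    ]

    # --- anatomy, EQ statements and cross-references ------------------------
    anatomy_edges = _anatomy_edges(panel)
    anatomy = build_graph(anatomy_edges)
    working_terms = sorted(anatomy.terms - {ROOT_TERM})
    xref_rows = [(f"XR:{term}", term) for term in working_terms]

    planted_tissue_of = {p_idx: t_idx for t_idx, p_idx, _ in config.planted}
    rng_eq = rngs["eq"]
    covered = rng_eq.random(n_phenos) < config.eq_coverage
    correct = rng_eq.random(n_phenos) < config.eq_correct_fraction
    neighbour_pick = rng_eq.integers(0, 3, size=n_phenos)  # exact / psp / ldsp
    decoy_tissue = rng_eq.integers(0, n_tissues, size=n_phenos)

    eq_rows: list[tuple[str, str]] = []
    for p_idx in range(n_phenos):
        if not covered[p_idx]:
            continue
        t_idx = planted_tissue_of.get(p_idx)
        if t_idx is not None and correct[p_idx]:
            entity = [
                panel[t_idx],            # exact match
                f"REG:{t_idx:03d}",      # predicted tissue below gold -> psp
                f"SUB:{t_idx:03d}",      # gold below predicted tissue -> ldsp
            ][neighbour_pick[p_idx]]
        else:
            d = int(decoy_tissue[p_idx])
            if t_idx is not None and d == t_idx:
                d = (d + 1) % n_tissues
            entity = panel[d]
        eq_rows.append((phenotype_ids[p_idx], f"XR:{entity}"))

    truth = [(panel[t], phenotype_ids[p]) for t, p, _ in config.planted]

    # --- ranked candidate list ----------------------------------------------
    n_cand = min(config.n_candidates, n_genes)
    chosen = rngs["candidates"].choice(n_genes, size=n_cand, replace=False)
    scores = np.sort(rngs["candidates"].random(n_cand))[::-1]
    candidates = [
        Candidate(rank=i + 1, gene=genes[g], score=round(float(s), 6))
        for i, (g, s) in enumerate(zip(chosen, scores))
    ]

    # --- run the real ingestion path to obtain the merged corpus ------------
    mapped_a, _ = apply_gene_map(calls_a, gene_map)
    mapped_b, _ = apply_gene_map(calls_b, gene_map)
    corpus = build_corpus([mapped_a, mapped_b], phenotype_annotations, panel)

    return Bundle(
        config=config,
        panel=panel,
        genes=genes,
        phenotype_ids=phenotype_ids,
        anatomy_edges=anatomy_edges,
        anatomy=anatomy,
        sources={"lacz": calls_a, "barcode": calls_b},
        gene_map=gene_map,
        phenotype_annotations=phenotype_annotations,
        eq_rows=eq_rows,
        xref_rows=xref_rows,
        truth=truth,
        candidates=candidates,
        corpus=corpus,
    )


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle artifact as deterministic TSV/text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, calls in sorted(bundle.sources.items()):
        path = out / f"expression_{name}.tsv"
        lines = ["gene_id\ttissue_id\tcall\tsource"]
        for c in sorted(calls, key=lambda c: (c.gene, c.tissue, c.call)):
            lines.append(f"{c.gene}\t{c.tissue}\t{c.call}\t{c.source}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[f"expression_{name}"] = path

    paths["phenotypes"] = _write_rows(
        out / "phenotypes.tsv",
        "gene_id\tphenotype_id",
        sorted(bundle.phenotype_annotations),
    )
    paths["gene_map"] = _write_rows(
        out / "gene_map.tsv",
        "foreign_id\tcanonical_id",
        sorted(bundle.gene_map.entries.items()),
    )
    paths["panel"] = out / "panel.txt"
    paths["panel"].write_text("\n".join(bundle.panel) + "\n", encoding="utf-8")
    paths["anatomy"] = _write_rows(
        out / "anatomy.tsv",
        "child_id\trelation\tparent_id",
        sorted(bundle.anatomy_edges),
    )
    paths["eq"] = _write_rows(
        out / "eq.tsv", "phenotype_id\tanatomy_id", sorted(bundle.eq_rows)
    )
    paths["xref"] = _write_rows(
        out / "xref.tsv", "foreign_id\tworking_id", sorted(bundle.xref_rows)
    )
    paths["truth"] = _write_rows(
        out / "truth.tsv", "tissue_id\tphenotype_id", sorted(bundle.truth)
    )
    paths["candidates"] = out / "candidates.tsv"
    lines = ["rank\tgene_id\tscore"]
    for c in bundle.candidates:
        lines.append(f"{c.rank}\t{c.gene}\t{c.score:g}")
    paths["candidates"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def truth_recovery_report(
    truth: Sequence[tuple[str, str]], associations: Sequence[Association]
) -> RecoveryReport:
    """Recall over planted pairs and false-positive count among the rest."""
    truth_set = {(t, p) for t, p in truth}
    predicted = {(a.tissue, a.phenotype) for a in associations}
    recovered = truth_set & predicted
    false_positives = len(predicted - truth_set)
    recall = len(recovered) / len(truth_set) if truth_set else 0.0
    return RecoveryReport(
        recall=recall,
        false_positives=false_positives,
        n_planted=len(truth_set),
        n_recovered=len(recovered),
    )


def _write_rows(path: Path, header: str, rows) -> Path:
    lines = [header]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
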