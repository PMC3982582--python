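import pytest

from phenotissue.enrichment import Association, ContingencyCounts
from phenotissue.eq_evaluation import (
    EQStatement,
    EvaluationError,
    EvaluationRecord,
    classify,
    evaluate,
    format_summary,
    load_eq,
    representable,
    summarize,
    summarize_by_method,
    write_records,
)
from phenotissue.ontology import build_graph

COUNTS = ContingencyCounts(o_tp=0, t=5, p=5, pt=50)


def assoc(phenotype, tissue, method="hypergeom"):
    return Association(
        phenotype=phenotype,
        tissue=tissue,
        method=method,
        p_value=0.001,
        counts=COUNTS,
    )


@pytest.fixture
def anatomy():
    # eye with retina below it, organ above; liver/brain unrelated branches
    return build_graph(
        [
            ("retina", "part_of", "eye"),
            ("eye", "is_a", "organ"),
            ("liver", "is_a", "organ"),
            ("brain", "is_a", "organ"),
            ("cortex", "part_of", "brain"),
        ]
    )


PANEL = ["eye", "liver", "brain"]


class TestLoadEq:
    def test_xref_translation(self, tmp_path, anatomy):
        eq = tmp_path / "eq.tsv"
        eq.write_text("phenotype_id\tanatomy_id\np1\tuberon_x\n")
        xref = tmp_path / "xref.tsv"
        xref.write_text("foreign_id\tworking_id\nuberon_x\teye\n")
        gold = load_eq(eq, xref, anatomy)
        assert gold == {"p1": EQStatement("p1", frozenset({"eye"}))}

    def test_unmappable_entity_dropped_and_counted(self, tmp_path, anatomy):
        eq = tmp_path / "eq.tsv"
        eq.write_text("p1\tnowhere\np2\teye\n")
        stats = {}
        gold = load_eq(eq, None, anatomy, stats=stats)
        assert "p1" not in gold
        assert stats["dropped_entities"] == 1
        assert gold["p2"].entities == frozenset({"eye"})

    def test_rows_aggregate_per_phenotype(self, tmp_path, anatomy):
        eq = tmp_path / "eq.tsv"
        eq.write_text("p1\teye\np1\tliver\n")
        gold = load_eq(eq, None, anatomy)
        assert gold["p1"].entities == frozenset({"eye", "liver"})

    def test_malformed_row_rejected_with_line_number(self, tmp_path, anatomy):
        eq = tmp_path / "eq.tsv"
        eq.write_text("p1\teye\nonly-one-column\n")
        with pytest.raises(EvaluationError, match=":2"):
            load_eq(eq, None, anatomy)

    def test_planted_unmappable_fraction(self, tmp_path, anatomy):
        rows = [f"p{i}\teye" for i in range(20)]
        rows += [f"q{i}\tunknown-{i}" for i in range(7)]
        eq = tmp_path / "eq.tsv"
        eq.write_text("\n".join(rows) + "\n")
        stats = {}
        gold = load_eq(eq, None, anatomy, stats=stats)
        assert stats["dropped_entities"] == 7
        assert len(gold) == 20

    def test_empty_entities_invalid(self):
        with pytest.raises(EvaluationError):
            EQStatement("p1", frozenset())


class TestRepresentable:
    def test_entity_is_panel_tissue(self, anatomy):
        assert representable(EQStatement("p", frozenset({"eye"})), PANEL, anatomy)

    def test_entity_below_panel_tissue(self, anatomy):
        assert representable(EQStatement("p", frozenset({"retina"})), PANEL, anatomy)

    def test_entity_above_panel_tissue(self, anatomy):
        assert representable(EQStatement("p", frozenset({"organ"})), PANEL, anatomy)

    def test_disconnected_entity_false(self):
        graph = build_graph(
            [("eye", "is_a", "organ"), ("island", "is_a", "isolate")]
        )
        eq = EQStatement("p", frozenset({"island"}))
        assert not representable(eq, ["eye"], graph)
        # exhaustive relate oracle over the panel
        assert all(not graph.related("island", t) for t in ["eye"])


class TestClassify:
    def test_exact(self, anatomy):
        gold = {"p1": EQStatement("p1", frozenset({"eye"}))}
        record = classify(assoc("p1", "eye"), gold, anatomy, PANEL)
        assert record.category == "exact"
        assert record.matched_entity == "eye"

    def test_psp_predicted_below_gold(self, anatomy):
        # predicted retina, gold eye, retina part_of eye
        gold = {"p1": EQStatement("p1", frozenset({"eye"}))}
        panel = PANEL + ["retina"]
        record = classify(assoc("p1", "retina"), gold, anatomy, panel)
        assert record.category == "psp"
        assert record.matched_entity == "eye"

    def test_ldsp_gold_below_predicted(self, anatomy):
        gold = {"p1": EQStatement("p1", frozenset({"retina"}))}
        record = classify(assoc("p1", "eye"), gold, anatomy, PANEL)
        assert record.category == "ldsp"

    def test_no_match_unrelated(self, anatomy):
        gold = {"p1": EQStatement("p1", frozenset({"eye"}))}
        record = classify(assoc("p1", "liver"), gold, anatomy, PANEL)
        assert record.category == "no_match"
        assert record.matched_entity is None

    def test_no_eq_when_gold_missing(self, anatomy):
        record = classify(assoc("p1", "eye"), {}, anatomy, PANEL)
        assert record.category == "no_eq"

    def test_no_eq_when_gold_not_representable(self):
        graph = build_graph(
            [("eye", "is_a", "organ"), ("island", "is_a", "isolate")]
        )
        gold = {"p1": EQStatement("p1", frozenset({"island"}))}
        record = classify(assoc("p1", "eye"), gold, graph, ["eye"])
        assert record.category == "no_eq"

    def test_priority_exact_over_psp_over_ldsp(self, anatomy):
        # gold has both the exact tissue and its ancestor: exact wins
        gold = {"p1": EQStatement("p1", frozenset({"eye", "organ", "retina"}))}
        record = classify(assoc("p1", "eye"), gold, anatomy, PANEL)
        assert record.category == "exact"
        # without the exact entity, psp (eye below organ) beats ldsp (retina)
        gold = {"p1": EQStatement("p1", frozenset({"organ", "retina"}))}
        record = classify(assoc("p1", "eye"), gold, anatomy, PANEL)
        assert record.category == "psp"
        assert record.matched_entity == "organ"

    def test_order_independence_of_gold_entities(self, anatomy):
        entities = ["organ", "retina", "eye"]
        records = set()
        for i in range(3):
            rotated = frozenset(entities[i:] + entities[:i])
            gold = {"p1": EQStatement("p1", rotated)}
            records.add(classify(assoc("p1", "eye"), gold, anatomy, PANEL))
        assert len(records) == 1

    def test_unknown_tissue_errors(self, anatomy):
        gold = {"p1": EQStatement("p1", frozenset({"eye"}))}
        with pytest.raises(EvaluationError, match="mystery"):
            classify(assoc("p1", "mystery"), gold, anatomy, PANEL)


class TestSummarize:
    def test_all_no_eq_has_undefined_percentages(self):
        records = [
            EvaluationRecord("p1", "eye", "hypergeom", "no_eq"),
            EvaluationRecord("p2", "liver", "hypergeom", "no_eq"),
        ]
        s = summarize(records)
        assert s.phenotypes_no_eq == 2
        assert s.phenotypes_with_eq == 0
        assert s.phenotype_expected_pct() is None
        assert s.association_category_pct("exact") is None

    def test_hand_tally_ten_records(self):
        records = [
            EvaluationRecord("p1", "eye", "hypergeom", "exact", "eye"),
            EvaluationRecord("p1", "liver", "hypergeom", "no_match"),
            EvaluationRecord("p2", "eye", "hypergeom", "psp", "organ"),
            EvaluationRecord("p2", "brain", "hypergeom", "ldsp", "cortex"),
            EvaluationRecord("p3", "liver", "hypergeom", "no_match"),
            EvaluationRecord("p3", "brain", "hypergeom", "no_match"),
            EvaluationRecord("p4", "eye", "hypergeom", "no_eq"),
            EvaluationRecord("p4", "brain", "hypergeom", "no_eq"),
            EvaluationRecord("p5", "eye", "hypergeom", "ldsp", "retina"),
            EvaluationRecord("p6", "liver", "hypergeom", "no_eq"),
        ]
        s = summarize(records)
        assert s.associations == {
            "exact": 1, "psp": 1, "ldsp": 2, "no_match": 3, "no_eq": 3
        }
        assert s.total_associations == 10
        assert s.phenotypes_expected == 3      # p1, p2, p5
        assert s.phenotypes_not_expected == 1  # p3
        assert s.phenotypes_no_eq == 2         # p4, p6
        assert s.total_phenotypes == 6
        assert s.phenotype_expected_pct() == pytest.approx(75.0)
        assert s.association_category_pct("no_match") == pytest.approx(
            100.0 * 3 / 7
        )

    def test_any_match_rule_at_phenotype_level(self):
        records = [
            EvaluationRecord("p1", "liver", "hypergeom", "no_match"),
            EvaluationRecord("p1", "eye", "hypergeom", "psp", "organ"),
        ]
        s = summarize(records)
        assert s.phenotypes_expected == 1
        assert s.phenotypes_not_expected == 0

    def test_counts_sum_to_totals(self, anatomy):
        gold = {
            "p1": EQStatement("p1", frozenset({"eye"})),
            "p2": EQStatement("p2", frozenset({"retina"})),
        }
        associations = [
            assoc(p, t) for p in ("p1", "p2", "p3") for t in PANEL
        ]
        records = evaluate(associations, gold, anatomy, PANEL)
        s = summarize(records)
        assert s.total_associations == len(associations)
        assert sum(s.associations.values()) == len(associations)

    def test_edge_free_ontology_yields_no_psp_ldsp(self):
        from phenotissue.ontology import OntologyGraph

        graph = OntologyGraph(terms={"eye", "liver"}, edges=set())
        gold = {"p1": EQStatement("p1", frozenset({"eye"}))}
        records = evaluate(
            [assoc("p1", "eye"), assoc("p1", "liver")], gold, graph, ["eye", "liver"]
        )
        categories = {r.category for r in records}
        assert categories == {"exact", "no_match"}

    def test_summarize_by_method_groups(self):
        records = [
            EvaluationRecord("p1", "eye", "hypergeom", "exact", "eye"),
            EvaluationRecord("p1", "eye", "rules", "no_match"),
        ]
        by_method = summarize_by_method(records)
        assert set(by_method) == {"hypergeom", "rules"}
        assert by_method["hypergeom"].associations["exact"] == 1

    def test_format_summary_smoke(self):
        records = [EvaluationRecord("p1", "eye", "hypergeom", "exact", "eye")]
        text = format_summary(summarize_by_method(records))
        assert "hypergeom" in text and "exact" in text

    def test_write_records(self, tmp_path):
        records = [EvaluationRecord("p1", "eye", "hypergeom", "no_match")]
        path = tmp_path / "eval.tsv"
        write_records(records, path)
        assert "p1\teye\thypergeom\tno_match\t-" in path.read_text()


class TestRecordInvariants:
    def test_matched_entity_requires_match_category(self):
        with pytest.raises(EvaluationError):
            EvaluationRecord("p1", "eye", "hypergeom", "no_match", "eye")
        with pytest.raises(EvaluationError):
            EvaluationRecord("p1", "eye", "hypergeom", "exact", None)

    def test_unknown_category_rejected(self):
        with pytest.raises(EvaluationError):
            EvaluationRecord("p1", "eye", "hypergeom", "bogus")
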