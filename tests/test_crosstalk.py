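import numpy as np
import pytest

from secretalk.core import ADIPOSE, MUSCLE, CriteriaConfig
from secretalk.crosstalk import (
    REASON_NON_EXPERIMENTAL,
    REASON_NON_MEMBER,
    REASON_NOT_EXPRESSED,
    REASON_SELF_LOOP,
    REASON_WRONG_COMPARTMENT,
    build_crosstalk,
    network_summary,
)
from secretalk.io_formats import ExpressionTable, MitabRecord


def _rec(a, b, evidence="experimental"):
    return MitabRecord(
        interactor_a=min(a, b),
        interactor_b=max(a, b),
        detection_methods=frozenset({"two hybrid"}),
        evidence_class=evidence,
        source_dbs=frozenset({"IntAct"}),
    )


def _expr(secretome, surfaceome, tissue_a, tissue_b):
    table = ExpressionTable()
    for s in secretome:
        table.set(s, tissue_a, True)
    for s in surfaceome:
        table.set(s, tissue_b, True)
    return table


class TestFilters:
    def test_retained_edge_oriented_secreted_to_surface(self):
        net = build_crosstalk(
            {"PLG"}, {"ENO1"}, {_rec("ENO1", "PLG")},
            _expr({"PLG"}, {"ENO1"}, ADIPOSE, MUSCLE), ADIPOSE, MUSCLE,
        )
        assert net.edges == {("PLG", "ENO1")}

    def test_predicted_evidence_rejected(self):
        net = build_crosstalk(
            {"A"}, {"B"}, {_rec("A", "B", evidence="predicted")},
            _expr({"A"}, {"B"}, ADIPOSE, MUSCLE), ADIPOSE, MUSCLE,
        )
        assert not net.edges
        assert net.rejections[REASON_NON_EXPERIMENTAL] == 1

    def test_experimental_filter_can_be_disabled(self):
        config = CriteriaConfig(require_experimental_ppi=False)
        net = build_crosstalk(
            {"A"}, {"B"}, {_rec("A", "B", evidence="predicted")},
            _expr({"A"}, {"B"}, ADIPOSE, MUSCLE), ADIPOSE, MUSCLE, config,
        )
        assert net.edges == {("A", "B")}

    def test_wrong_compartment_vs_non_member(self):
        records = {_rec("A1", "A2"), _rec("A1", "X")}
        net = build_crosstalk(
            {"A1", "A2"}, {"B1"}, records,
            _expr({"A1", "A2"}, {"B1"}, ADIPOSE, MUSCLE), ADIPOSE, MUSCLE,
        )
        assert net.rejections[REASON_WRONG_COMPARTMENT] == 1
        assert net.rejections[REASON_NON_MEMBER] == 1

    def test_self_loop_rejected(self):
        net = build_crosstalk(
            {"A"}, {"A"}, {_rec("A", "A")}, None, ADIPOSE, MUSCLE,
            CriteriaConfig(require_expression_check=False),
        )
        assert net.rejections[REASON_SELF_LOOP] == 1

    def test_not_expressed_endpoint_rejected(self):
        expr = ExpressionTable()
        expr.set("A", ADIPOSE, True)
        expr.set("B", MUSCLE, False)
        net = build_crosstalk({"A"}, {"B"}, {_rec("A", "B")}, expr, ADIPOSE, MUSCLE)
        assert not net.edges
        assert net.rejections[REASON_NOT_EXPRESSED] == 1

    def test_unknown_expression_passes_with_warning_by_default(self):
        net = build_crosstalk({"A"}, {"B"}, {_rec("A", "B")}, ExpressionTable(), ADIPOSE, MUSCLE)
        assert net.edges == {("A", "B")}
        assert net.warnings

    def test_unknown_expression_rejects_when_configured(self):
        config = CriteriaConfig(unknown_expression_action="reject")
        net = build_crosstalk(
            {"A"}, {"B"}, {_rec("A", "B")}, ExpressionTable(), ADIPOSE, MUSCLE, config
        )
        assert not net.edges

    def test_empty_secretome_empty_network(self):
        net = build_crosstalk(set(), {"B"}, {_rec("A", "B")}, None, ADIPOSE, MUSCLE)
        assert not net.edges and not net.nodes


class TestProperties:
    def _random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"G{i}" for i in range(40)]
        sec = {universe[i] for i in rng.choice(40, size=10, replace=False)}
        surf = {universe[i] for i in rng.choice(40, size=10, replace=False)} - sec
        records = {
            _rec(universe[int(i)], universe[int(j)])
            for i, j in rng.integers(0, 40, size=(30, 2))
            if i != j
        }
        return sec, surf, records

    @pytest.mark.parametrize("seed", range(5))
    def test_edges_subset_of_role_product(self, seed):
        sec, surf, records = self._random_inputs(seed)
        config = CriteriaConfig(require_expression_check=False)
        net = build_crosstalk(sec, surf, records, None, ADIPOSE, MUSCLE, config)
        for u, v in net.edges:
            assert u in sec and v in surf

    @pytest.mark.parametrize("seed", range(5))
    def test_tallies_reconcile_with_input_count(self, seed):
        sec, surf, records = self._random_inputs(seed)
        config = CriteriaConfig(require_expression_check=False)
        net = build_crosstalk(sec, surf, records, None, ADIPOSE, MUSCLE, config)
        assert net.retained_records + sum(net.rejections.values()) == len(records)

    def test_role_swap_transposes_network(self):
        sec, surf = {"A1", "A2"}, {"B1", "B2"}
        records = {_rec("A1", "B1"), _rec("A2", "B2")}
        config = CriteriaConfig(require_expression_check=False)
        forward = build_crosstalk(sec, surf, records, None, ADIPOSE, MUSCLE, config)
        backward = build_crosstalk(surf, sec, records, None, MUSCLE, ADIPOSE, config)
        assert {(v, u) for u, v in forward.edges} == backward.edges


class TestPublishedFixtures:
    def _run(self, fixture):
        (sec_key,) = [k for k in fixture.role_sets if k.startswith("secretome")]
        (surf_key,) = [k for k in fixture.role_sets if k.startswith("surfaceome")]
        tissue_a = sec_key.split("_", 1)[1]
        tissue_b = surf_key.split("_", 1)[1]
        return build_crosstalk(
            fixture.role_sets[sec_key],
            fixture.role_sets[surf_key],
            fixture.mitab_records,
            fixture.expression,
            tissue_a,
            tissue_b,
        )

    def test_adipose_to_muscle_two_links_four_proteins(self, paper_fixtures):
        net = self._run(paper_fixtures["crosstalk_at_to_muscle"])
        summary = network_summary(net)
        assert summary["edges"] == 2
        assert summary["nodes"] == 4
        assert net.edges == {("PLG", "ENO1"), ("APOA1", "KRT1")}

    def test_muscle_to_adipose_sixteen_proteins(self, paper_fixtures):
        net = self._run(paper_fixtures["crosstalk_muscle_to_at"])
        summary = network_summary(net)
        assert summary["edges"] == 11
        assert summary["nodes"] == 16
        assert ("HPX", "CDC42") in net.edges
        assert summary["sources"] == 9 and summary["targets"] == 7

    @pytest.mark.parametrize("name", ["crosstalk_at_to_muscle", "crosstalk_muscle_to_at"])
    def test_every_decoy_rejected_for_its_planted_reason(self, paper_fixtures, name):
        fixture = paper_fixtures[name]
        net = self._run(fixture)
        assert dict(net.rejections) == fixture.expected["decoy_reasons"]


def test_graphml_export(tmp_path):
    net = build_crosstalk(
        {"PLG"}, {"ENO1"}, {_rec("PLG", "ENO1")}, None, ADIPOSE, MUSCLE,
        CriteriaConfig(require_expression_check=False),
    )
    out = tmp_path / "net.graphml"
    net.to_graphml(out)
    import networkx as nx

    back = nx.read_graphml(out)
    assert set(back.edges()) == {("PLG", "ENO1")}
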