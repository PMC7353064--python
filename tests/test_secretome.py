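import pytest

from secretalk.core import ADIPOSE, MUSCLE, CriteriaConfig, InsufficientEvidenceError, PredictorFeatures, TissueProteome
from secretalk.secretome import (
    CLASSICAL,
    NON_CLASSICAL,
    SecretomeResult,
    UnsupportedLabelingError,
    classify_classical,
    classify_non_classical,
    label_kines,
    predict_secretome,
)


def _feat(**kw):
    defaults = dict(
        signalp_d_score=0.2,
        signalp_call=False,
        tm_helix_count=0,
        tm_barrel_count=0,
        gpi_anchor=False,
        targetp_class="other",
        targetp_rc=3,
        go_terms=frozenset(),
    )
    defaults.update(kw)
    return PredictorFeatures(**defaults)


class TestClassicalRoute:
    def test_all_criteria_satisfied(self, config):
        assert classify_classical(_feat(signalp_d_score=0.82, targetp_rc=1), config)

    def test_threshold_is_strict(self, config):
        # a D-score exactly at the threshold must NOT qualify
        assert not classify_classical(_feat(signalp_d_score=0.5, targetp_rc=1), config)

    def test_transmembrane_segment_disqualifies(self, config):
        assert not classify_classical(
            _feat(signalp_d_score=0.82, tm_helix_count=1, targetp_rc=1), config
        )
        assert not classify_classical(
            _feat(signalp_d_score=0.82, tm_barrel_count=1, targetp_rc=1), config
        )

    def test_reliability_class_bound(self, config):
        assert classify_classical(_feat(signalp_d_score=0.82, targetp_rc=2), config)
        assert not classify_classical(_feat(signalp_d_score=0.82, targetp_rc=3), config)

    def test_missing_features(self, config):
        feat = _feat(signalp_d_score=None)
        assert classify_classical(feat, config) is None
        with pytest.raises(InsufficientEvidenceError):
            classify_classical(feat, config, strict=True)

    def test_epsilon_crossing_flips_only_classical(self, config, dag):
        # perturbing the D-score across the threshold flips the classical
        # verdict; the non-classical verdict is untouched
        eps = 1e-9
        below = _feat(signalp_d_score=0.5 - eps, targetp_rc=1)
        above = _feat(signalp_d_score=0.5 + eps, targetp_rc=1)
        assert not classify_classical(below, config)
        assert classify_classical(above, config)
        assert classify_non_classical(below, dag, config) == classify_non_classical(
            above, dag, config
        )


class TestNonClassicalRoute:
    def test_other_class_reliable_extracellular(self, config, dag):
        feat = _feat(targetp_class="other", targetp_rc=2, go_terms={"GO:0070062"})
        assert classify_non_classical(feat, dag, config)

    def test_reliability_bound_enforced(self, config, dag):
        feat = _feat(targetp_class="other", targetp_rc=3, go_terms={"GO:0005576"})
        assert not classify_non_classical(feat, dag, config)

    def test_class_mismatch(self, config, dag):
        feat = _feat(targetp_class="mitochondrial", targetp_rc=1, go_terms={"GO:0005576"})
        assert not classify_non_classical(feat, dag, config)

    def test_requires_extracellular_annotation(self, config, dag):
        feat = _feat(targetp_class="other", targetp_rc=1, go_terms={"GO:0005829"})
        assert not classify_non_classical(feat, dag, config)


class TestPredictSecretome:
    def test_tables_fixture_counts(self, tables_fixture, dag, config):
        t = tables_fixture
        for tissue, total, classical, non_classical in (
            (MUSCLE, 48, 38, 10),
            (ADIPOSE, 88, 68, 20),
        ):
            result = predict_secretome(t.proteomes[tissue], t.features, dag, config)
            assert len(result.calls) == total
            assert len(result.route_symbols(CLASSICAL)) == classical
            assert len(result.route_symbols(NON_CLASSICAL)) == non_classical

    def test_routes_disjoint(self, tables_fixture, dag, config):
        t = tables_fixture
        result = predict_secretome(t.proteomes[ADIPOSE], t.features, dag, config)
        assert not result.route_symbols(CLASSICAL) & result.route_symbols(NON_CLASSICAL)

    def test_empty_proteome(self, dag, config):
        result = predict_secretome(TissueProteome(tissue=ADIPOSE), {}, dag, config)
        assert result.calls == {}

    def test_uncovered_and_unevaluated_tracked(self, dag, config):
        proteome = TissueProteome.from_symbols(ADIPOSE, ["COVERED", "MISSING", "PARTIAL"])
        features = {
            "COVERED": _feat(signalp_d_score=0.9, targetp_class="secretory_pathway", targetp_rc=1),
            "PARTIAL": PredictorFeatures(),  # nothing usable by either route
        }
        result = predict_secretome(proteome, features, dag, config)
        assert result.uncovered == ["MISSING"]
        assert result.unevaluated == ["PARTIAL"]
        assert set(result.calls) == {"COVERED"}

    def test_determinism(self, tables_fixture, dag, config):
        t = tables_fixture
        first = predict_secretome(t.proteomes[MUSCLE], t.features, dag, config)
        second = predict_secretome(t.proteomes[MUSCLE], t.features, dag, config)
        assert first.calls == second.calls

    def test_threshold_comes_from_config(self, tables_fixture, dag):
        # raising the D-score threshold above the fixture's 0.9 kills the
        # classical route entirely; criteria must flow from the config
        strict_config = CriteriaConfig(signalp_threshold=0.95)
        t = tables_fixture
        result = predict_secretome(t.proteomes[MUSCLE], t.features, dag, strict_config)
        assert not result.route_symbols(CLASSICAL)


class TestKineLabeling:
    def test_planted_partition(self):
        adipose = {f"A{i}" for i in range(5)} | {f"S{i}" for i in range(2)}
        muscle = {f"M{i}" for i in range(3)} | {f"S{i}" for i in range(2)}
        labels = label_kines({ADIPOSE: adipose, MUSCLE: muscle})
        counts = {lab: sum(1 for v in labels.values() if v == lab) for lab in set(labels.values())}
        assert counts == {"adipokine": 5, "adipomyokine": 2, "myokine": 3}

    def test_named_examples(self, tables_fixture, dag, config):
        t = tables_fixture
        secretomes = {
            tissue: predict_secretome(t.proteomes[tissue], t.features, dag, config)
            for tissue in (ADIPOSE, MUSCLE)
        }
        labels = label_kines(secretomes)
        assert labels["PLG"] == "adipokine"
        assert labels["HPX"] == "adipomyokine"

    def test_rejects_other_tissue_labels(self):
        with pytest.raises(UnsupportedLabelingError):
            label_kines({"adipose": set(), "liver": set()})

    def test_accepts_result_objects_and_raw_sets(self):
        raw = label_kines({ADIPOSE: {"A"}, MUSCLE: {"B"}})
        wrapped = label_kines(
            {
                ADIPOSE: SecretomeResult(tissue=ADIPOSE, calls={}, unevaluated=[], uncovered=[]),
                MUSCLE: SecretomeResult(tissue=MUSCLE, calls={}, unevaluated=[], uncovered=[]),
            }
        )
        assert raw == {"A": "adipokine", "B": "myokine"}
        assert wrapped == {}
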