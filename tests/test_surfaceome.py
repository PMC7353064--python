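import numpy as np
import pytest

from secretalk.core import ADIPOSE, MUSCLE, PredictorFeatures, TissueProteome
from secretalk.surfaceome import (
    BASIS_ATLAS,
    BASIS_GPI,
    BASIS_TM,
    SurfaceomeAtlas,
    build_atlas,
    classify_surface_predicted,
    predict_surfaceome,
)


def _feat(**kw):
    defaults = dict(tm_helix_count=0, tm_barrel_count=0, gpi_anchor=False, go_terms=frozenset())
    defaults.update(kw)
    return PredictorFeatures(**defaults)


class TestSurfaceRule:
    def test_tm_helix_plus_plasma_membrane(self, dag, config):
        positive, basis = classify_surface_predicted(
            _feat(tm_helix_count=1, go_terms={"GO:0005886"}), dag, config
        )
        assert positive and basis == {BASIS_TM}

    def test_gpi_without_membrane_annotation_fails(self, dag, config):
        # anchoring alone is not enough; the GO conjunct is required
        positive, basis = classify_surface_predicted(
            _feat(gpi_anchor=True, go_terms={"GO:0005829"}), dag, config
        )
        assert not positive and basis == frozenset()

    def test_membrane_annotation_without_anchor_fails(self, dag, config):
        positive, _ = classify_surface_predicted(
            _feat(go_terms={"GO:0005886"}), dag, config
        )
        assert not positive

    def test_barrel_counts_as_anchor(self, dag, config):
        positive, basis = classify_surface_predicted(
            _feat(tm_barrel_count=1, go_terms={"GO:0009897"}), dag, config
        )
        assert positive and basis == {BASIS_TM}

    def test_dual_anchor_reports_both_bases(self, dag, config):
        positive, basis = classify_surface_predicted(
            _feat(tm_helix_count=2, gpi_anchor=True, go_terms={"GO:0005886"}), dag, config
        )
        assert positive and basis == {BASIS_TM, BASIS_GPI}


class TestBuildAtlas:
    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(11)
        universe = [f"G{i}" for i in range(120)]
        lists = [
            {universe[i] for i in rng.choice(120, size=size, replace=False)}
            for size in (30, 40, 50)
        ]
        atlas = build_atlas(lists)
        assert atlas.symbols == set().union(*lists)
        assert len(atlas) == len(set().union(*lists))

    def test_single_list_identity(self):
        atlas = build_atlas([{"A", "B"}])
        assert atlas.symbols == {"A", "B"}

    def test_full_overlap_collapses(self):
        atlas = build_atlas([{"A", "B"}, {"A", "B"}, {"B", "A"}])
        assert len(atlas) == 2

    def test_per_source_provenance(self):
        atlas = build_atlas([{"A"}, {"A", "B"}], names=["x", "y"])
        assert atlas.members["A"] == {"x", "y"}
        assert atlas.members["B"] == {"y"}

    def test_requires_at_least_one_list(self):
        with pytest.raises(ValueError):
            build_atlas([])


def _surface_setup(n_predicted=5, n_atlas=8, n_overlap=2, n_filler=10):
    """Random planted surfaceome; returns (proteome, features, atlas, truth)."""
    predicted = {f"P{i}" for i in range(n_predicted)}
    overlap = {f"P{i}" for i in range(min(n_overlap, n_predicted))}
    atlas_only = {f"Q{i}" for i in range(n_atlas - len(overlap))}
    filler = {f"F{i}" for i in range(n_filler)}
    symbols = predicted | atlas_only | filler
    features = {}
    for sym in symbols:
        if sym in predicted:
            features[sym] = _feat(tm_helix_count=1, go_terms={"GO:0005886"})
        else:
            features[sym] = _feat(go_terms={"GO:0005829"})
    atlas = build_atlas([overlap | atlas_only | {"NOTINPROTEOME"}])
    proteome = TissueProteome.from_symbols(ADIPOSE, symbols)
    return proteome, features, atlas, (predicted, atlas_only | overlap)


class TestPredictSurfaceome:
    def test_inclusion_exclusion_identity(self, dag, config):
        for n_pred, n_atl, n_ov in ((5, 8, 2), (7, 21, 2), (4, 11, 2), (3, 3, 3), (0, 5, 0)):
            proteome, features, atlas, (predicted, atlas_hits) = _surface_setup(
                n_pred, n_atl, n_ov
            )
            result = predict_surfaceome(proteome, features, dag, atlas, config)
            assert len(result.calls) == len(predicted | atlas_hits)
            counts = result.counts()
            assert counts["total"] == counts["predicted"] + counts["atlas"] - counts["both"]

    def test_atlas_member_absent_from_proteome_yields_no_call(self, dag, config):
        proteome, features, atlas, _ = _surface_setup()
        result = predict_surfaceome(proteome, features, dag, atlas, config)
        assert "NOTINPROTEOME" not in result.calls

    def test_dual_strategy_call_has_union_basis(self, dag, config):
        proteome, features, atlas, _ = _surface_setup(n_predicted=3, n_atlas=3, n_overlap=3)
        result = predict_surfaceome(proteome, features, dag, atlas, config)
        call = result.calls["P0"]
        assert call.basis == {BASIS_TM, BASIS_ATLAS}

    def test_atlas_basis_implies_proteome_membership(self, dag, config):
        proteome, features, atlas, _ = _surface_setup()
        result = predict_surfaceome(proteome, features, dag, atlas, config)
        for sym, call in result.calls.items():
            if BASIS_ATLAS in call.basis:
                assert sym in proteome

    def test_published_cardinalities_fixture(self, paper_fixtures, config):
        f = paper_fixtures["surfaceome_counts"]
        atlas = SurfaceomeAtlas(members={s: frozenset(t) for s, t in f.atlas_members.items()})
        for tissue, expected_union in ((ADIPOSE, 26), (MUSCLE, 13)):
            result = predict_surfaceome(f.proteomes[tissue], f.features, f.dag, atlas, config)
            counts = result.counts()
            assert counts["total"] == expected_union
            assert counts["predicted"] == f.expected[tissue]["predicted"]
            assert counts["atlas"] == f.expected[tissue]["atlas"]
            assert counts["both"] == f.expected[tissue]["overlap"]

    def test_predicted_in_both_tissues_named_proteins(self, paper_fixtures, config):
        # the two proteins predicted at the surface of both tissues
        f = paper_fixtures["surfaceome_counts"]
        atlas = SurfaceomeAtlas(members={s: frozenset(t) for s, t in f.atlas_members.items()})
        for tissue in (ADIPOSE, MUSCLE):
            result = predict_surfaceome(f.proteomes[tissue], f.features, f.dag, atlas, config)
            predicted = {s for s, c in result.calls.items() if c.basis - {BASIS_ATLAS}}
            assert {"PSMC1", "F3"} <= predicted
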