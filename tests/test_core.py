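import string

import pytest
from hypothesis import given, settings, strategies as st

from secretalk.core import (
    CriteriaConfig,
    InvalidSymbolError,
    MixedTissueError,
    ProteinRecord,
    TissueProteome,
    merge_proteomes,
    normalize_symbol,
    venn,
)

# uppercase-only so raw strategy values are already canonical symbols
symbols = st.text(alphabet=string.ascii_uppercase + string.digits, min_size=1, max_size=8)
symbol_sets = st.sets(symbols, max_size=40)


@pytest.mark.parametrize(
    "raw,expected",
    [("Eno1 ", "ENO1"), ("ENO1", "ENO1"), ("plg", "PLG"), ("  hpx\t", "HPX")],
)
def test_normalize_symbol_trims_and_uppercases(raw, expected):
    assert normalize_symbol(raw) == expected


@given(st.text(min_size=1))
def test_normalize_symbol_idempotent(raw):
    try:
        once = normalize_symbol(raw)
    except InvalidSymbolError:
        return
    assert normalize_symbol(once) == once


@pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
def test_normalize_symbol_rejects_blank(raw):
    with pytest.raises(InvalidSymbolError):
        normalize_symbol(raw)


def _proteome(tissue, syms, **kw):
    return TissueProteome.from_symbols(tissue, syms, **kw)


class TestMergeProteomes:
    def test_set_union(self):
        merged = merge_proteomes([_proteome("adipose", "AB"), _proteome("adipose", "BC")])
        assert merged.symbols == {"A", "B", "C"}

    def test_identity(self):
        merged = merge_proteomes([_proteome("muscle", ["A"])])
        assert merged.symbols == {"A"}

    def test_planted_overlap_compendium(self):
        # two lists of 400 and 500 with 150 shared must merge to 750
        shared = [f"S{i}" for i in range(150)]
        a = shared + [f"A{i}" for i in range(250)]
        b = shared + [f"B{i}" for i in range(350)]
        merged = merge_proteomes([_proteome("adipose", a), _proteome("adipose", b)])
        assert len(merged) == 750
        assert merged.symbols == set(a) | set(b)

    def test_mixed_tissue_rejected(self):
        with pytest.raises(MixedTissueError):
            merge_proteomes([_proteome("adipose", "A"), _proteome("muscle", "B")])

    def test_provenance_unioned_per_symbol(self):
        a = TissueProteome.from_records(
            "adipose", [ProteinRecord("PLG", accessions={"P1"}, source_tags={"study1"})]
        )
        b = TissueProteome.from_records(
            "adipose", [ProteinRecord("PLG", accessions={"P2"}, source_tags={"study2"})]
        )
        rec = merge_proteomes([a, b]).records["PLG"]
        assert rec.accessions == {"P1", "P2"}
        assert rec.source_tags == {"study1", "study2"}

    @given(st.lists(symbol_sets, min_size=1, max_size=5))
    @settings(max_examples=50)
    def test_associative_and_order_insensitive(self, lists):
        proteomes = [_proteome("adipose", s) for s in lists]
        forward = merge_proteomes(proteomes).symbols
        backward = merge_proteomes(list(reversed(proteomes))).symbols
        assert forward == backward == set().union(*lists)


class TestVenn:
    def test_empty_first_set(self):
        part = venn(set(), {"X", "Y"})
        assert part.a_only == frozenset()
        assert part.both == frozenset()
        assert part.b_only == {"X", "Y"}

    def test_planted_intersection(self):
        shared = {f"S{i}" for i in range(20)}
        a = shared | {f"A{i}" for i in range(30)}
        b = shared | {f"B{i}" for i in range(40)}
        assert venn(a, b).both == shared

    @given(symbol_sets, symbol_sets)
    def test_partition_disjoint_and_sums_to_union(self, a, b):
        part = venn(a, b)
        assert part.a_only.isdisjoint(part.both)
        assert part.a_only.isdisjoint(part.b_only)
        assert part.both.isdisjoint(part.b_only)
        assert part.union_size() == len(a | b)


class TestCriteriaConfig:
    def test_defaults_match_published_criteria(self):
        config = CriteriaConfig()
        assert config.signalp_threshold == 0.5
        assert config.targetp_rc_max == 2
        assert config.bh_alpha == 0.01
        assert config.min_annotated == 2
        assert config.plasma_membrane_root == "GO:0005886"
        assert config.extracellular_roots == {"GO:0005576", "GO:0005615", "GO:0070062"}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"signalp_threshold": 0.0},
            {"signalp_threshold": 1.5},
            {"targetp_rc_max": 0},
            {"targetp_rc_max": 6},
            {"bh_alpha": 0.0},
            {"unknown_expression_action": "maybe"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CriteriaConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        config = CriteriaConfig(signalp_threshold=0.6, bh_alpha=0.05)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert CriteriaConfig.from_yaml(path) == config

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            CriteriaConfig.from_dict({"not_a_field": 1})


def test_duplicate_records_collapse_within_proteome():
    proteome = TissueProteome.from_records(
        "adipose",
        [ProteinRecord("eno1", accessions={"Q1"}), ProteinRecord("ENO1 ", accessions={"Q2"})],
    )
    assert len(proteome) == 1
    assert proteome.records["ENO1"].accessions == {"Q1", "Q2"}
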