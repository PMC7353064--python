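"""Surfaceome classification: feature rules, reference atlas, and their union.

Two complementary strategies identify cell-surface proteins in a tissue
proteome. The *predicted* strategy requires membrane anchoring evidence (at
least one alpha-helical or beta-barrel transmembrane segment, or a GPI
anchor) conjoined with plasma-membrane GO annotation. The *atlas* strategy
intersects the proteome with a reference compendium of known cell-surface
proteins merged from published lists. The tissue surfaceome is the union of
the two, with each call recording which basis (or both) supported it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    CriteriaConfig,
    InsufficientEvidenceError,
    PredictorFeatures,
    TissueProteome,
    VennPartition,
    normalize_symbol,
    venn,
)
from .ontology import GODag, is_plasma_membrane

__all__ = [
    "SurfaceomeAtlas",
    "SurfaceCall",
    "SurfaceomeResult",
    "classify_surface_predicted",
    "build_atlas",
    "predict_surfaceome",
]

BASIS_TM = "predicted_tm"
BASIS_GPI = "predicted_gpi"
BASIS_ATLAS = "atlas"
_BASIS_ORDER = {BASIS_TM: 0, BASIS_GPI: 1, BASIS_ATLAS: 2}


@dataclass
class SurfaceomeAtlas:
    """Reference compendium of cell-surface proteins with per-source tags."""

    members: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def symbols(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members


def build_atlas(
    lists: Sequence[Iterable[str]], names: Sequence[str] | None = None
) -> SurfaceomeAtlas:
    """Merge contributing symbol lists into a deduplicated atlas.

    Each member records which contributing list(s) carried it.
    """
    if not lists:
        raise ValueError("at least one contributing list is required")
    if names is None:
        names = [f"list{i + 1}" for i in range(len(lists))]
    if len(names) != len(lists):
        raise ValueError("names must match lists one-to-one")
    members: dict[str, set[str]] = {}
    for name, symbols in zip(names, lists):
        for raw in symbols:
            members.setdefault(normalize_symbol(raw), set()).add(name)
    return SurfaceomeAtlas(members={s: frozenset(t) for s, t in members.items()})


@dataclass(frozen=True)
class SurfaceCall:
    """A cell-surface call with the basis (or bases) that supported it."""

    symbol: str
    tissue: str
    basis: frozenset[str]
    evidence: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        if not self.basis:
            raise ValueError("a surface call must carry at least one basis")

    @property
    def basis_sorted(self) -> tuple[str, ...]:
        return tuple(sorted(self.basis, key=_BASIS_ORDER.__getitem__))


def classify_surface_predicted(
    features: PredictorFeatures,
    dag: GODag,
    config: CriteriaConfig,
    strict: bool = False,
) -> tuple[bool, frozenset[str]]:
    """Feature-rule surface test: membrane anchor AND plasma-membrane GO.

    Returns ``(positive, basis)`` where basis names which anchor evidence
    fired (TM segment and/or GPI). Missing GO annotation simply fails the
    second conjunct; a wholly empty feature bundle raises in strict mode.
    """
    if strict and features.signalp_d_score is None and features.targetp_class is None and not features.go_terms:
        raise InsufficientEvidenceError("no predictor features available")
    anchored = features.tm_total >= 1 or features.gpi_anchor
    if not anchored:
        return False, frozenset()
    if not is_plasma_membrane(dag, features.go_terms, config):
        return False, frozenset()
    basis = set()
    if features.tm_total >= 1:
        basis.add(BASIS_TM)
    if features.gpi_anchor:
        basis.add(BASIS_GPI)
    return True, frozenset(basis)


@dataclass
class SurfaceomeResult:
    """Surface calls for one tissue plus the predicted-vs-atlas partition."""

    tissue: str
    calls: dict[str, SurfaceCall] = field(default_factory=dict)
    partition: VennPartition = None

    @property
    def symbols(self) -> set[str]:
        return set(self.calls)

    def basis_symbols(self, basis: str) -> set[str]:
        return {s for s, c in self.calls.items() if basis in c.basis}

    def counts(self) -> dict[str, int]:
        predicted = {s for s, c in self.calls.items() if c.basis - {BASIS_ATLAS}}
        atlas = self.basis_symbols(BASIS_ATLAS)
        return {
            "total": len(self.calls),
            "predicted": len(predicted),
            "atlas": len(atlas),
            "predicted_only": len(predicted - atlas),
            "both": len(predicted & atlas),
            "atlas_only": len(atlas - predicted),
        }


def predict_surfaceome(
    proteome: TissueProteome,
    features: Mapping[str, PredictorFeatures],
    dag: GODag,
    atlas: SurfaceomeAtlas,
    config: CriteriaConfig | None = None,
) -> SurfaceomeResult:
    """Union of feature-rule positives and the atlas-proteome intersection.

    A protein positive by both strategies yields one call whose basis
    records both. Atlas members absent from the proteome never produce
    calls.
    """
    config = config or CriteriaConfig()
    predicted: dict[str, frozenset[str]] = {}
    for symbol in sorted(proteome.symbols):
        feat = features.get(symbol)
        if feat is None:
            continue
        positive, basis = classify_surface_predicted(feat, dag, config)
        if positive:
            predicted[symbol] = basis
    atlas_hits = atlas.symbols & proteome.symbols
    result = SurfaceomeResult(
        tissue=proteome.tissue,
        partition=venn(set(predicted), atlas_hits),
    )
    for symbol in sorted(set(predicted) | atlas_hits):
        basis = set(predicted.get(symbol, frozenset()))
        evidence: list[tuple[str, object]] = []
        feat = features.get(symbol)
        if symbol in predicted and feat is not None:
            evidence.append(("tm_total", feat.tm_total))
            evidence.append(("gpi_anchor", feat.gpi_anchor))
        if symbol in atlas_hits:
            basis.add(BASIS_ATLAS)
            evidence.append(("atlas_sources", tuple(sorted(atlas.members[symbol]))))
        result.calls[symbol] = SurfaceCall(
            symbol=symbol,
            tissue=proteome.tissue,
            basis=frozenset(basis),
            evidence=tuple(evidence),
        )
    return result
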