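"""Two-route secretion classifier and per-tissue secretome assembly.

A protein is called secreted via the **classical** route when it carries a
predicted N-terminal signal peptide (D-score strictly above the configured
threshold), has no transmembrane segment, and its subcellular-targeting call
is reliable (RC <= the configured maximum). Proteins that fail the classical
route are then tested for the **non-classical** route (exosomes, membrane
flip-flop, transporters): targeting class "other", reliable RC, and at
least one GO annotation under an extracellular root. The two routes are
disjoint by construction, so a tissue secretome size is the sum of the two
route counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core import (
    ADIPOSE,
    MUSCLE,
    CriteriaConfig,
    InsufficientEvidenceError,
    PredictorFeatures,
    TissueProteome,
    venn,
)
from .ontology import GODag, is_extracellular

__all__ = [
    "SecretomeCall",
    "SecretomeResult",
    "UnsupportedLabelingError",
    "classify_classical",
    "classify_non_classical",
    "predict_secretome",
    "label_kines",
]

CLASSICAL = "classical"
NON_CLASSICAL = "non_classical"

ADIPOKINE = "adipokine"
MYOKINE = "myokine"
ADIPOMYOKINE = "adipomyokine"


class UnsupportedLabelingError(ValueError):
    """Kine labeling needs exactly the adipose and muscle secretomes."""


@dataclass(frozen=True)
class SecretomeCall:
    """A secretion call for one protein in one tissue, with its evidence."""

    symbol: str
    tissue: str
    route: str
    evidence: tuple[tuple[str, object], ...]

    @property
    def evidence_dict(self) -> dict:
        return dict(self.evidence)


def _require(features: PredictorFeatures, names: tuple[str, ...], strict: bool) -> bool:
    """True when all named features are present; strict mode raises instead."""
    missing = [n for n in names if getattr(features, n) is None]
    if missing and strict:
        raise InsufficientEvidenceError(f"missing features: {missing}")
    return not missing


def classify_classical(
    features: PredictorFeatures, config: CriteriaConfig, strict: bool = False
) -> bool | None:
    """Classical (signal-peptide) route test.

    True iff no transmembrane segment, D-score strictly > threshold, and
    RC <= the configured maximum. Returns ``None`` when a required feature
    is missing (or raises in strict mode).
    """
    if not _require(features, ("signalp_d_score", "targetp_rc"), strict):
        return None
    return (
        features.tm_total == 0
        and features.signalp_d_score > config.signalp_threshold
        and features.targetp_rc <= config.targetp_rc_max
    )


def classify_non_classical(
    features: PredictorFeatures, dag: GODag, config: CriteriaConfig, strict: bool = False
) -> bool | None:
    """Non-classical (no signal peptide) route test.

    Intended to be evaluated only on classical-route negatives. True iff the
    targeting class is "other", RC <= the configured maximum, and at least
    one GO term lies under an extracellular root.
    """
    if not _require(features, ("targetp_class", "targetp_rc"), strict):
        return None
    return (
        features.targetp_class == "other"
        and features.targetp_rc <= config.targetp_rc_max
        and is_extracellular(dag, features.go_terms, config)
    )


@dataclass
class SecretomeResult:
    """Calls for one tissue, plus the bookkeeping lists."""

    tissue: str
    calls: dict[str, SecretomeCall] = field(default_factory=dict)
    unevaluated: list[str] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)

    @property
    def symbols(self) -> set[str]:
        return set(self.calls)

    def route_symbols(self, route: str) -> set[str]:
        return {s for s, c in self.calls.items() if c.route == route}

    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.calls),
            CLASSICAL: len(self.route_symbols(CLASSICAL)),
            NON_CLASSICAL: len(self.route_symbols(NON_CLASSICAL)),
            "unevaluated": len(self.unevaluated),
            "uncovered": len(self.uncovered),
        }


def predict_secretome(
    proteome: TissueProteome,
    features: Mapping[str, PredictorFeatures],
    dag: GODag,
    config: CriteriaConfig | None = None,
) -> SecretomeResult:
    """Run both routes over a tissue proteome.

    The classical route is evaluated first; the non-classical route only on
    classical negatives, so the two call sets are disjoint. Proteins absent
    from the feature table are listed as uncovered; proteins whose features
    are too incomplete for either route are listed as unevaluated.
    """
    config = config or CriteriaConfig()
    result = SecretomeResult(tissue=proteome.tissue)
    for symbol in sorted(proteome.symbols):
        feat = features.get(symbol)
        if feat is None:
            result.uncovered.append(symbol)
            continue
        classical = classify_classical(feat, config)
        if classical:
            result.calls[symbol] = SecretomeCall(
                symbol=symbol,
                tissue=proteome.tissue,
                route=CLASSICAL,
                evidence=(
                    ("d_score", feat.signalp_d_score),
                    ("no_tm", feat.tm_total == 0),
                    ("rc", feat.targetp_rc),
                ),
            )
            continue
        non_classical = classify_non_classical(feat, dag, config)
        if non_classical:
            extracellular_hits = tuple(
                sorted(
                    t
                    for t in feat.go_terms
                    if t in dag and dag.ancestors(t) & config.extracellular_roots
                )
            )
            result.calls[symbol] = SecretomeCall(
                symbol=symbol,
                tissue=proteome.tissue,
                route=NON_CLASSICAL,
                evidence=(
                    ("targetp_class", feat.targetp_class),
                    ("rc", feat.targetp_rc),
                    ("extracellular_go", extracellular_hits),
                ),
            )
            continue
        if classical is None and non_classical is None:
            result.unevaluated.append(symbol)
    return result


def label_kines(secretomes: Mapping[str, SecretomeResult | set]) -> dict[str, str]:
    """Relabel the adipose/muscle secretome Venn partition as kine classes.

    Adipose-only proteins become adipokines, muscle-only myokines, shared
    proteins adipomyokines. Requires exactly the two canonical tissues.
    """
    if set(secretomes) != {ADIPOSE, MUSCLE}:
        raise UnsupportedLabelingError(
            f"kine labeling needs tissues {{'{ADIPOSE}', '{MUSCLE}'}}, got {sorted(secretomes)}"
        )

    def _symbols(v):
        return v.symbols if isinstance(v, SecretomeResult) else set(v)

    part = venn(_symbols(secretomes[ADIPOSE]), _symbols(secretomes[MUSCLE]))
    labels: dict[str, str] = {}
    for sym in part.a_only:
        labels[sym] = ADIPOKINE
    for sym in part.both:
        labels[sym] = ADIPOMYOKINE
    for sym in part.b_only:
        labels[sym] = MYOKINE
    return labels
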