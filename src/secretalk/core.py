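"""Core domain types for tissue proteome analysis.

The pipeline operates on *tissue proteomes* -- deduplicated sets of proteins
identified in a tissue, keyed by canonical (uppercased) gene symbol -- plus a
per-protein bundle of precomputed predictor features (signal-peptide score,
transmembrane/GPI evidence, subcellular-targeting class, GO annotation).
Every numeric decision threshold used anywhere downstream lives in
:class:`CriteriaConfig`; no module hard-codes a criterion constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ADIPOSE",
    "MUSCLE",
    "InvalidSymbolError",
    "MixedTissueError",
    "InsufficientEvidenceError",
    "ProteinRecord",
    "TissueProteome",
    "PredictorFeatures",
    "CriteriaConfig",
    "VennPartition",
    "normalize_symbol",
    "merge_proteomes",
    "venn",
]

ADIPOSE = "adipose"
MUSCLE = "muscle"

TARGETP_CLASSES = ("secretory_pathway", "mitochondrial", "other")


class InvalidSymbolError(ValueError):
    """Raised for empty or blank gene-symbol input."""


class MixedTissueError(ValueError):
    """Raised when proteomes of different tissues are merged."""


class InsufficientEvidenceError(ValueError):
    """Raised in strict mode when a classifier lacks a required feature."""


def normalize_symbol(raw: str) -> str:
    """Canonicalize a gene symbol: trim whitespace and uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.

    Raises
    ------
    InvalidSymbolError
        If the input is empty or blank after trimming.
    """
    if raw is None:
        raise InvalidSymbolError("gene symbol is None")
    sym = str(raw).strip().upper()
    if not sym:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    return sym


@dataclass(frozen=True)
class ProteinRecord:
    """One protein, keyed by its canonical gene symbol.

    Accessions and source tags are provenance only; all cross-dataset
    operations key on ``canonical_symbol``.
    """

    canonical_symbol: str
    accessions: frozenset[str] = frozenset()
    species: str = "bovine"
    source_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_symbol", normalize_symbol(self.canonical_symbol))
        object.__setattr__(self, "accessions", frozenset(self.accessions))
        object.__setattr__(self, "source_tags", frozenset(self.source_tags))

    def merged_with(self, other: "ProteinRecord") -> "ProteinRecord":
        """Union provenance of two records sharing one symbol."""
        if other.canonical_symbol != self.canonical_symbol:
            raise ValueError(
                f"cannot merge records for {self.canonical_symbol} and {other.canonical_symbol}"
            )
        return replace(
            self,
            accessions=self.accessions | other.accessions,
            source_tags=self.source_tags | other.source_tags,
        )


@dataclass
class TissueProteome:
    """Deduplicated set of proteins identified in one tissue."""

    tissue: str
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, tissue: str, records: Iterable[ProteinRecord]) -> "TissueProteome":
        """Build a proteome, collapsing duplicate symbols with merged provenance."""
        out: dict[str, ProteinRecord] = {}
        for rec in records:
            key = rec.canonical_symbol
            out[key] = out[key].merged_with(rec) if key in out else rec
        return cls(tissue=tissue, records=out)

    @classmethod
    def from_symbols(cls, tissue: str, symbols: Iterable[str], species: str = "bovine") -> "TissueProteome":
        return cls.from_records(
            tissue, (ProteinRecord(s, species=species) for s in symbols)
        )

    @property
    def symbols(self) -> set[str]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.records

    def __iter__(self):
        return iter(self.records.values())


def merge_proteomes(proteomes: Sequence[TissueProteome]) -> TissueProteome:
    """Merge several proteome lists for one tissue into a compendium.

    Records are deduplicated on canonical symbol; accessions and source tags
    are unioned per symbol. All inputs must carry the same tissue label.
    """
    if not proteomes:
        raise ValueError("no proteomes to merge")
    tissues = {p.tissue for p in proteomes}
    if len(tissues) > 1:
        raise MixedTissueError(f"cannot merge proteomes of mixed tissues: {sorted(tissues)}")
    merged: dict[str, ProteinRecord] = {}
    for prot in proteomes:
        for rec in prot:
            key = rec.canonical_symbol
            merged[key] = merged[key].merged_with(rec) if key in merged else rec
    return TissueProteome(tissue=proteomes[0].tissue, records=merged)


@dataclass(frozen=True)
class VennPartition:
    """Two-set Venn partition over symbol sets; the three parts are disjoint."""

    a_only: frozenset[str]
    both: frozenset[str]
    b_only: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.a_only), len(self.both), len(self.b_only))

    def union_size(self) -> int:
        return len(self.a_only) + len(self.both) + len(self.b_only)


def venn(a: Iterable[str], b: Iterable[str]) -> VennPartition:
    """Partition two symbol sets into a-only / both / b-only."""
    sa, sb = set(a), set(b)
    return VennPartition(
        a_only=frozenset(sa - sb),
        both=frozenset(sa & sb),
        b_only=frozenset(sb - sa),
    )


@dataclass(frozen=True)
class PredictorFeatures:
    """Precomputed per-protein features consumed by the classifiers.

    ``signalp_d_score`` is the signal-peptide discrimination score in [0, 1];
    ``targetp_rc`` is the 1..5 reliability class of the subcellular-targeting
    call (1 = most reliable). TM counts are predicted alpha-helical and
    beta-barrel transmembrane segments. Fields left ``None`` mean the
    corresponding predictor was not run for this protein.
    """

    signalp_d_score: float | None = None
    signalp_call: bool | None = None
    tm_helix_count: int = 0
    tm_barrel_count: int = 0
    gpi_anchor: bool = False
    targetp_class: str | None = None
    targetp_rc: int | None = None
    uniprot_locations: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.signalp_d_score is not None and not 0.0 <= self.signalp_d_score <= 1.0:
            raise ValueError(f"signal-peptide D-score outside [0,1]: {self.signalp_d_score}")
        if self.tm_helix_count < 0 or self.tm_barrel_count < 0:
            raise ValueError("transmembrane segment counts must be non-negative")
        if self.targetp_class is not None and self.targetp_class not in TARGETP_CLASSES:
            raise ValueError(f"unknown targeting class: {self.targetp_class!r}")
        if self.targetp_rc is not None and not 1 <= self.targetp_rc <= 5:
            raise ValueError(f"reliability class outside 1..5: {self.targetp_rc}")
        object.__setattr__(self, "uniprot_locations", frozenset(self.uniprot_locations))
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))

    @property
    def tm_total(self) -> int:
        return self.tm_helix_count + self.tm_barrel_count


@dataclass
class CriteriaConfig:
    """Every numeric criterion and policy switch of the workflow.

    Parameters
    ----------
    signalp_threshold : float
        Signal-peptide D-score must strictly exceed this for the classical
        route (default 0.5).
    targetp_rc_max : int
        Maximum accepted targeting reliability class, 1..5 (default 2).
    bh_alpha : float
        Benjamini--Hochberg adjusted-p cutoff for reporting enriched GO terms
        (default 0.01).
    min_annotated : int
        Minimum study proteins a reported GO term must annotate (default 2).
    extracellular_roots : set of GO ids
        Terms whose reflexive descendants count as "extracellular location".
    plasma_membrane_root : GO id
        Root of the plasma-membrane predicate.
    require_experimental_ppi : bool
        Keep only experimentally evidenced interactions in crosstalk.
    require_expression_check : bool
        Require both crosstalk endpoints expressed in their tissues.
    unknown_expression_action : {"pass", "reject"}
        Treatment of endpoints whose expression status is unknown.
    signalp_sensitivity_cutoff : float
        Upstream predictor's cleavage-site sensitivity D-cutoff; recorded as
        parser metadata only, never applied as a classification threshold.
    predicted_method_markers : tuple of str
        Substrings of an interaction-detection-method description that mark a
        PPI record as predicted/inferred rather than experimental.
    unknown_method_markers : tuple of str
        Substrings marking the detection method as unspecified.
    """

    signalp_threshold: float = 0.5
    targetp_rc_max: int = 2
    bh_alpha: float = 0.01
    min_annotated: int = 2
    extracellular_roots: frozenset[str] = frozenset({"GO:0005576", "GO:0005615", "GO:0070062"})
    plasma_membrane_root: str = "GO:0005886"
    require_experimental_ppi: bool = True
    require_expression_check: bool = True
    unknown_expression_action: str = "pass"
    signalp_sensitivity_cutoff: float = 0.34
    predicted_method_markers: tuple[str, ...] = (
        "predict",
        "inference",
        "inferred",
        "in silico",
        "computational",
        "text mining",
        "homology",
    )
    unknown_method_markers: tuple[str, ...] = ("unspecified", "unknown")

    def __post_init__(self) -> None:
        if not 0.0 < self.signalp_threshold < 1.0:
            raise ValueError("signalp_threshold must be in (0,1)")
        if not 1 <= self.targetp_rc_max <= 5:
            raise ValueError("targetp_rc_max must be in 1..5")
        if not 0.0 < self.bh_alpha < 1.0:
            raise ValueError("bh_alpha must be in (0,1)")
        if self.min_annotated < 0:
            raise ValueError("min_annotated must be non-negative")
        if self.unknown_expression_action not in ("pass", "reject"):
            raise ValueError("unknown_expression_action must be 'pass' or 'reject'")
        self.extracellular_roots = frozenset(self.extracellular_roots)
        self.predicted_method_markers = tuple(self.predicted_method_markers)
        self.unknown_method_markers = tuple(self.unknown_method_markers)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CriteriaConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CriteriaConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
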