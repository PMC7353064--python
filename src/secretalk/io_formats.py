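"""Readers and writers for the tabular formats the pipeline consumes.

Pinned dialects (the upstream tools ship several; one is fixed per format):

* **Signal-peptide table** (``read_signalp_table``): whitespace-delimited,
  ``#`` comments; columns ``name  d_score  decision(Y/N)  tm_count``.
  ``tm_count`` is the number of predicted transmembrane segments, so
  ``tm_count == 0`` is the noTM flag.
* **Targeting table** (``read_targetp_table``): whitespace-delimited,
  ``#`` comments; columns ``name  loc  rc`` with ``loc`` in ``S`` (secretory
  pathway), ``M`` (mitochondrial), anything else = "other", and ``rc`` the
  1..5 reliability class.
* **GAF 2.1**: 17 tab-separated columns, ``!`` comments.
* **OBO 1.2 subset**: ``[Term]`` stanzas with id/name/namespace/is_a,
  parsed through :mod:`obonet`; obsolete terms are excluded.
* **PSI-MITAB 2.5**: >= 15 tab-separated columns; gene symbol taken from the
  alias column's ``(gene name)`` entry, falling back to the identifier
  column. Unordered duplicate pairs are aggregated.
* **Expression TSV**: headered ``symbol  tissue  expressed`` with expressed
  in {0, 1}; absent lookups return unknown, never raise.
* **Proteome / atlas TSVs**: headered ``symbol [accession] [source]`` and
  ``symbol [source]``.

Every reader has a strict mode (malformed row -> :class:`FormatError`) and a
lenient mode (row skipped, counted, and logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .core import InvalidSymbolError, ProteinRecord, TissueProteome, CriteriaConfig, normalize_symbol
from .ontology import CycleError, GODag

__all__ = [
    "FormatError",
    "GafRecord",
    "MitabRecord",
    "ExpressionTable",
    "read_proteome_table",
    "write_proteome_table",
    "read_signalp_table",
    "write_signalp_table",
    "read_targetp_table",
    "write_targetp_table",
    "read_gaf",
    "write_gaf",
    "read_obo",
    "write_obo",
    "read_mitab",
    "write_mitab",
    "read_expression_table",
    "write_expression_table",
    "read_atlas_table",
    "write_atlas_table",
    "read_topology_table",
    "write_topology_table",
    "annotation_map",
    "assemble_features",
]

log = logging.getLogger(__name__)

_GO_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """Raised for malformed input in strict mode."""


@dataclass
class ParseLog:
    """Bookkeeping for lenient-mode parsing: skipped rows and warnings."""

    skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def skip(self, message: str, strict: bool) -> None:
        if strict:
            raise FormatError(message)
        self.skipped += 1
        self.warnings.append(message)
        log.warning("%s (row skipped)", message)


def _data_lines(path, comment: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# proteome lists

def read_proteome_table(
    path, tissue: str, species: str = "bovine", strict: bool = True
) -> tuple[TissueProteome, ParseLog]:
    """Read a headered TSV proteome list (symbol [accession] [source])."""
    plog = ParseLog()
    records: list[ProteinRecord] = []
    lines = list(_data_lines(path, "#"))
    if not lines:
        return TissueProteome(tissue=tissue), plog
    header = lines[0][1].split("\t")
    cols = {name.strip().lower(): i for i, name in enumerate(header)}
    if "symbol" not in cols:
        raise FormatError(f"{path}: proteome table lacks a 'symbol' column")
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        try:
            sym = normalize_symbol(parts[cols["symbol"]])
        except (IndexError, InvalidSymbolError):
            plog.skip(f"{path}:{lineno}: missing or blank symbol", strict)
            continue
        acc = set()
        tags = set()
        if "accession" in cols and len(parts) > cols["accession"] and parts[cols["accession"]].strip():
            acc.add(parts[cols["accession"]].strip())
        if "source" in cols and len(parts) > cols["source"] and parts[cols["source"]].strip():
            tags.add(parts[cols["source"]].strip())
        records.append(ProteinRecord(sym, accessions=acc, species=species, source_tags=tags))
    return TissueProteome.from_records(tissue, records), plog


def write_proteome_table(path, proteome: TissueProteome) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\taccession\tsource\n")
        for sym in sorted(proteome.records):
            rec = proteome.records[sym]
            fh.write(
                f"{sym}\t{';'.join(sorted(rec.accessions))}\t{';'.join(sorted(rec.source_tags))}\n"
            )


# ---------------------------------------------------------------------------
# predictor tables

def read_signalp_table(path, strict: bool = True) -> tuple[dict[str, tuple[float, bool, bool]], ParseLog]:
    """Read the signal-peptide score table.

    Returns a mapping ``symbol -> (d_score, call, no_tm)``.
    """
    plog = ParseLog()
    out: dict[str, tuple[float, bool, bool]] = {}
    for lineno, line in _data_lines(path, "#"):
        parts = line.split()
        if len(parts) < 4:
            plog.skip(f"{path}:{lineno}: expected 4 columns, got {len(parts)}", strict)
            continue
        name, d_raw, decision, tm_raw = parts[:4]
        try:
            sym = normalize_symbol(name)
            d = float(d_raw)
            tm = int(tm_raw)
        except (ValueError, InvalidSymbolError):
            plog.skip(f"{path}:{lineno}: malformed row {line!r}", strict)
            continue
        if not 0.0 <= d <= 1.0 or tm < 0 or decision not in ("Y", "N"):
            plog.skip(f"{path}:{lineno}: out-of-range values in {line!r}", strict)
            continue
        out[sym] = (d, decision == "Y", tm == 0)
    return out, plog


def write_signalp_table(
    path, entries: Mapping[str, tuple[float, bool, bool]], d_cutoff: float | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("# name D decision TM\n")
        if d_cutoff is not None:
            fh.write(f"# D-cutoff: {d_cutoff}\n")
        for sym in sorted(entries):
            d, call, no_tm = entries[sym]
            fh.write(f"{sym} {d:.3f} {'Y' if call else 'N'} {0 if no_tm else 1}\n")


_TP_CLASS = {"S": "secretory_pathway", "M": "mitochondrial"}
_TP_LETTER = {"secretory_pathway": "S", "mitochondrial": "M", "other": "_"}


def read_targetp_table(path, strict: bool = True) -> tuple[dict[str, tuple[str, int]], ParseLog]:
    """Read the targeting table; returns ``symbol -> (targetp_class, rc)``."""
    plog = ParseLog()
    out: dict[str, tuple[str, int]] = {}
    for lineno, line in _data_lines(path, "#"):
        parts = line.split()
        if len(parts) < 3:
            plog.skip(f"{path}:{lineno}: expected 3 columns, got {len(parts)}", strict)
            continue
        name, loc, rc_raw = parts[:3]
        try:
            sym = normalize_symbol(name)
            rc = int(rc_raw)
        except (ValueError, InvalidSymbolError):
            plog.skip(f"{path}:{lineno}: malformed row {line!r}", strict)
            continue
        if not 1 <= rc <= 5:
            plog.skip(f"{path}:{lineno}: reliability class {rc} outside 1..5", strict)
            continue
        out[sym] = (_TP_CLASS.get(loc.upper(), "other"), rc)
    return out, plog


def write_targetp_table(path, entries: Mapping[str, tuple[str, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("# name Loc RC\n")
        for sym in sorted(entries):
            cls, rc = entries[sym]
            fh.write(f"{sym} {_TP_LETTER[cls]} {rc}\n")


# ---------------------------------------------------------------------------
# GAF

@dataclass(frozen=True)
class GafRecord:
    """One GO annotation line (GAF 2.1)."""

    db: str
    db_object_id: str
    db_object_symbol: str
    qualifier: str
    go_id: str
    evidence_code: str
    aspect: str
    taxon: str

    def __post_init__(self) -> None:
        if not _GO_RE.match(self.go_id):
            raise FormatError(f"invalid GO id {self.go_id!r}")
        if self.aspect not in ("C", "F", "P"):
            raise FormatError(f"invalid GAF aspect {self.aspect!r}")


def read_gaf(path, strict: bool = True) -> tuple[set[GafRecord], ParseLog]:
    """Read a GAF 2.1 file into a set of :class:`GafRecord`."""
    plog = ParseLog()
    out: set[GafRecord] = set()
    for lineno, line in _data_lines(path, "!"):
        parts = line.split("\t")
        if len(parts) != 17:
            plog.skip(f"{path}:{lineno}: GAF line has {len(parts)} columns, expected 17", strict)
            continue
        try:
            out.add(
                GafRecord(
                    db=parts[0],
                    db_object_id=parts[1],
                    db_object_symbol=normalize_symbol(parts[2]),
                    qualifier=parts[3],
                    go_id=parts[4],
                    evidence_code=parts[6],
                    aspect=parts[8],
                    taxon=parts[12],
                )
            )
        except (FormatError, InvalidSymbolError) as exc:
            plog.skip(f"{path}:{lineno}: {exc}", strict)
    return out, plog


def write_gaf(path, records: Iterable[GafRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for rec in sorted(records, key=lambda r: (r.db_object_symbol, r.go_id, r.evidence_code)):
            cols = [""] * 17
            cols[0] = rec.db
            cols[1] = rec.db_object_id
            cols[2] = rec.db_object_symbol
            cols[3] = rec.qualifier
            cols[4] = rec.go_id
            cols[5] = "GO_REF:0000000"
            cols[6] = rec.evidence_code
            cols[8] = rec.aspect
            cols[9] = rec.db_object_symbol
            cols[11] = "protein"
            cols[12] = rec.taxon
            cols[13] = "20200101"
            cols[14] = "secretalk"
            fh.write("\t".join(cols) + "\n")


def annotation_map(
    records: Iterable[GafRecord],
    dag: GODag | None = None,
    propagate: bool = True,
    aspects: tuple[str, ...] = ("C", "F", "P"),
) -> dict[str, set[str]]:
    """Build a ``go_id -> annotated symbols`` map from GAF records.

    With a DAG and ``propagate=True`` (standard enrichment practice) each
    annotation also counts for every is_a ancestor of its term. NOT
    qualifiers are excluded. Terms absent from the DAG stay unpropagated.
    """
    out: dict[str, set[str]] = {}
    for rec in records:
        if "NOT" in rec.qualifier.split("|"):
            continue
        if rec.aspect not in aspects:
            continue
        terms = {rec.go_id}
        if propagate and dag is not None and rec.go_id in dag:
            terms = set(dag.ancestors(rec.go_id))
        for t in terms:
            out.setdefault(t, set()).add(rec.db_object_symbol)
    return out


# ---------------------------------------------------------------------------
# OBO

def read_obo(path) -> GODag:
    """Read a minimal OBO 1.2 subset (id/name/namespace/is_a) into a GODag.

    Obsolete terms are excluded. A cyclic is_a graph raises
    :class:`~secretalk.ontology.CycleError` naming one offending edge.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str]] = []
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", "cellular_component"))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    # obonet drops dangling parents; GODag validates the rest and acyclicity
    known_edges = [(c, p) for c, p in edges if c in terms and p in terms]
    check = nx.DiGraph(known_edges)
    if not nx.is_directed_acyclic_graph(check):
        cyc = nx.find_cycle(check)
        raise CycleError(f"is_a cycle detected at edge {cyc[0][0]} -> {cyc[0][1]}")
    return GODag.from_edges(terms, known_edges)


def write_obo(path, dag: GODag) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in sorted(dag.terms):
            name, namespace = dag.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {namespace}\n")
            for parent in sorted(dag.is_a_parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {dag.terms[parent][0]}\n")


# ---------------------------------------------------------------------------
# PSI-MITAB

@dataclass(frozen=True)
class MitabRecord:
    """One aggregated molecular-interaction record (unordered pair key).

    ``interactor_a <= interactor_b`` lexicographically; duplicate rows for
    the same unordered pair are merged, unioning detection methods, source
    databases and publications. ``evidence_class`` is "experimental" if any
    contributing row was experimentally detected.
    """

    interactor_a: str
    interactor_b: str
    detection_methods: frozenset[str] = frozenset()
    interaction_types: frozenset[str] = frozenset()
    evidence_class: str = "unknown"
    source_dbs: frozenset[str] = frozenset()
    publications: frozenset[str] = frozenset()

    @property
    def is_self_loop(self) -> bool:
        return self.interactor_a == self.interactor_b

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.interactor_a, self.interactor_b))


_PAREN_RE = re.compile(r"\(([^)]*)\)")


def _mitab_symbol(alias_field: str, id_field: str) -> str | None:
    """Extract a gene symbol from alias entries, falling back to the id."""
    for entry in alias_field.split("|"):
        m = _PAREN_RE.search(entry)
        if m and m.group(1).strip().lower() == "gene name":
            body = entry.split("(")[0]
            sym = body.split(":", 1)[-1].strip()
            if sym:
                return normalize_symbol(sym)
    for entry in id_field.split("|"):
        sym = entry.split(":", 1)[-1].strip()
        if sym and sym != "-":
            return normalize_symbol(sym)
    return None


def _method_text(field_: str) -> str:
    m = _PAREN_RE.search(field_)
    return m.group(1).strip() if m else field_.strip()


def classify_evidence(method: str, config: CriteriaConfig | None = None) -> str:
    """Map a detection-method description to an evidence class.

    The marker vocabularies are table-driven via :class:`CriteriaConfig`;
    anything neither predicted/inferred nor unspecified is experimental.
    """
    config = config or CriteriaConfig()
    text = method.lower()
    if not text or text == "-" or any(m in text for m in config.unknown_method_markers):
        return "unknown"
    if any(m in text for m in config.predicted_method_markers):
        return "predicted"
    return "experimental"


_EVIDENCE_RANK = {"unknown": 0, "predicted": 1, "experimental": 2}


def read_mitab(
    path, strict: bool = True, config: CriteriaConfig | None = None
) -> tuple[set[MitabRecord], ParseLog]:
    """Read PSI-MITAB 2.5 rows, aggregating unordered duplicate pairs."""
    plog = ParseLog()
    config = config or CriteriaConfig()
    agg: dict[frozenset, dict] = {}
    for lineno, line in _data_lines(path, "#"):
        parts = line.split("\t")
        if len(parts) < 15:
            plog.skip(f"{path}:{lineno}: MITAB line has {len(parts)} columns, expected >= 15", strict)
            continue
        sym_a = _mitab_symbol(parts[4], parts[0])
        sym_b = _mitab_symbol(parts[5], parts[1])
        if not sym_a or not sym_b:
            plog.skip(f"{path}:{lineno}: row lacks both interactor symbols", strict)
            continue
        method = _method_text(parts[6])
        itype = _method_text(parts[11])
        source = _method_text(parts[12])
        pubs = frozenset(p for p in parts[8].split("|") if p and p != "-")
        key = (min(sym_a, sym_b), max(sym_a, sym_b))
        slot = agg.setdefault(
            key,
            {"methods": set(), "types": set(), "sources": set(), "pubs": set(), "evidence": "unknown"},
        )
        slot["methods"].add(method)
        if itype:
            slot["types"].add(itype)
        if source:
            slot["sources"].add(source)
        slot["pubs"] |= pubs
        ev = classify_evidence(method, config)
        if _EVIDENCE_RANK[ev] > _EVIDENCE_RANK[slot["evidence"]]:
            slot["evidence"] = ev
    records = {
        MitabRecord(
            interactor_a=a,
            interactor_b=b,
            detection_methods=frozenset(slot["methods"]),
            interaction_types=frozenset(slot["types"]),
            evidence_class=slot["evidence"],
            source_dbs=frozenset(slot["sources"]),
            publications=frozenset(slot["pubs"]),
        )
        for (a, b), slot in agg.items()
    }
    for rec in records:
        if rec.is_self_loop:
            log.warning("self-interaction record: %s", rec.interactor_a)
    return records, plog


def write_mitab(path, records: Iterable[MitabRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#ID(A)\tID(B)\tAltID(A)\tAltID(B)\tAlias(A)\tAlias(B)\tMethod\t"
            "Author\tPubs\tTaxA\tTaxB\tType\tSourceDB\tInteractionID\tConfidence\n"
        )
        for rec in sorted(records, key=lambda r: (r.interactor_a, r.interactor_b)):
            method = sorted(rec.detection_methods)[0] if rec.detection_methods else "-"
            itype = sorted(rec.interaction_types)[0] if rec.interaction_types else "association"
            source = sorted(rec.source_dbs)[0] if rec.source_dbs else "-"
            pubs = "|".join(sorted(rec.publications)) or "-"
            row = [
                f"uniprotkb:{rec.interactor_a}",
                f"uniprotkb:{rec.interactor_b}",
                "-",
                "-",
                f"uniprotkb:{rec.interactor_a}(gene name)",
                f"uniprotkb:{rec.interactor_b}(gene name)",
                f'psi-mi:"MI:0000"({method})',
                "-",
                pubs,
                "taxid:9606",
                "taxid:9606",
                f'psi-mi:"MI:0000"({itype})',
                f'psi-mi:"MI:0000"({source})',
                "-",
                "-",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression and atlas tables

@dataclass
class ExpressionTable:
    """(symbol, tissue) -> expressed lookups; absent pairs are unknown."""

    values: dict[tuple[str, str], bool] = field(default_factory=dict)

    def lookup(self, symbol: str, tissue: str) -> bool | None:
        """Return True/False, or None when the pair is not in the table."""
        return self.values.get((normalize_symbol(symbol), tissue))

    def set(self, symbol: str, tissue: str, expressed: bool) -> None:
        self.values[(normalize_symbol(symbol), tissue)] = bool(expressed)


def read_expression_table(path, strict: bool = True) -> tuple[ExpressionTable, ParseLog]:
    plog = ParseLog()
    table = ExpressionTable()
    lines = list(_data_lines(path, "#"))
    for lineno, line in lines[1:] if lines else []:
        parts = line.split("\t")
        if len(parts) < 3:
            plog.skip(f"{path}:{lineno}: expected 3 columns", strict)
            continue
        try:
            sym = normalize_symbol(parts[0])
            expressed = {"0": False, "1": True}[parts[2].strip()]
        except (InvalidSymbolError, KeyError):
            plog.skip(f"{path}:{lineno}: malformed expression row {line!r}", strict)
            continue
        table.set(sym, parts[1].strip(), expressed)
    return table, plog


def write_expression_table(path, table: ExpressionTable) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\ttissue\texpressed\n")
        for (sym, tissue) in sorted(table.values):
            fh.write(f"{sym}\t{tissue}\t{1 if table.values[(sym, tissue)] else 0}\n")


def read_atlas_table(path, strict: bool = True) -> tuple[dict[str, set[str]], ParseLog]:
    """Read an atlas TSV (symbol [source]) into symbol -> source tags."""
    plog = ParseLog()
    out: dict[str, set[str]] = {}
    lines = list(_data_lines(path, "#"))
    for lineno, line in lines[1:] if lines else []:
        parts = line.split("\t")
        try:
            sym = normalize_symbol(parts[0])
        except (IndexError, InvalidSymbolError):
            plog.skip(f"{path}:{lineno}: missing symbol", strict)
            continue
        tags = out.setdefault(sym, set())
        if len(parts) > 1 and parts[1].strip():
            tags.add(parts[1].strip())
    return out, plog


def write_atlas_table(path, members: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tsource\n")
        for sym in sorted(members):
            tags = sorted(members[sym])
            if tags:
                for tag in tags:
                    fh.write(f"{sym}\t{tag}\n")
            else:
                fh.write(f"{sym}\t\n")


# ---------------------------------------------------------------------------
# membrane topology table

def read_topology_table(path, strict: bool = True) -> tuple[dict[str, tuple[int, int, bool]], ParseLog]:
    """Read a membrane-topology table: ``symbol tm_helix tm_barrel gpi``.

    Returns ``symbol -> (tm_helix_count, tm_barrel_count, gpi_anchor)``.
    """
    plog = ParseLog()
    out: dict[str, tuple[int, int, bool]] = {}
    for lineno, line in _data_lines(path, "#"):
        parts = line.split()
        if len(parts) < 4:
            plog.skip(f"{path}:{lineno}: expected 4 columns, got {len(parts)}", strict)
            continue
        try:
            sym = normalize_symbol(parts[0])
            helix, barrel = int(parts[1]), int(parts[2])
            gpi = {"0": False, "1": True}[parts[3]]
        except (ValueError, KeyError, InvalidSymbolError):
            plog.skip(f"{path}:{lineno}: malformed row {line!r}", strict)
            continue
        if helix < 0 or barrel < 0:
            plog.skip(f"{path}:{lineno}: negative segment count", strict)
            continue
        out[sym] = (helix, barrel, gpi)
    return out, plog


def write_topology_table(path, entries: Mapping[str, tuple[int, int, bool]]) -> None:
    with open(path, "w") as fh:
        fh.write("# name tm_helix tm_barrel gpi\n")
        for sym in sorted(entries):
            helix, barrel, gpi = entries[sym]
            fh.write(f"{sym} {helix} {barrel} {1 if gpi else 0}\n")


# ---------------------------------------------------------------------------
# feature assembly

def assemble_features(
    signalp: Mapping[str, tuple[float, bool, bool]] | None = None,
    targetp: Mapping[str, tuple[str, int]] | None = None,
    gaf_records: Iterable[GafRecord] = (),
    topology: Mapping[str, tuple[int, int, bool]] | None = None,
    locations: Mapping[str, Iterable[str]] | None = None,
):
    """Join per-tool tables into ``symbol -> PredictorFeatures``.

    The topology table, when present for a symbol, supplies TM segment
    counts and the GPI flag; otherwise the signal-peptide table's noTM flag
    stands in (noTM -> 0 helices, else 1). Symbols present in any table get
    an entry.
    """
    from .core import PredictorFeatures

    signalp = signalp or {}
    targetp = targetp or {}
    topology = topology or {}
    locations = locations or {}
    go_by_symbol: dict[str, set[str]] = {}
    for rec in gaf_records:
        go_by_symbol.setdefault(rec.db_object_symbol, set()).add(rec.go_id)
    symbols = set(signalp) | set(targetp) | set(go_by_symbol) | set(topology) | set(locations)
    out = {}
    for sym in symbols:
        d_score, call, no_tm = signalp.get(sym, (None, None, True))
        tp_class, rc = targetp.get(sym, (None, None))
        if sym in topology:
            helix, barrel, gpi = topology[sym]
        else:
            helix, barrel, gpi = (0 if no_tm else 1), 0, False
        out[sym] = PredictorFeatures(
            signalp_d_score=d_score,
            signalp_call=call,
            tm_helix_count=helix,
            tm_barrel_count=barrel,
            gpi_anchor=gpi,
            targetp_class=tp_class,
            targetp_rc=rc,
            uniprot_locations=frozenset(locations.get(sym, ())),
            go_terms=frozenset(go_by_symbol.get(sym, ())),
        )
    return out
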