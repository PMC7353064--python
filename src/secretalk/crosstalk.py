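"""Directed bipartite tissue-crosstalk network from filtered PPI records.

Given the secretome of tissue A and the surfaceome of tissue B, an
interaction record is retained iff one interactor is secreted by A and the
other sits on the surface of B, the interaction is experimentally evidenced
(when required), and both endpoints are expressed in their respective
tissues (when required). Retained records become directed edges
secreted(A) -> surface(B); every rejected record is tallied under the
single first filter it failed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .core import CriteriaConfig
from .io_formats import ExpressionTable, MitabRecord

__all__ = ["CrosstalkNetwork", "build_crosstalk", "network_summary"]

log = logging.getLogger(__name__)

REASON_SELF_LOOP = "self_loop"
REASON_NON_EXPERIMENTAL = "non_experimental"
REASON_WRONG_COMPARTMENT = "wrong_compartment"
REASON_NON_MEMBER = "non_member"
REASON_NOT_EXPRESSED = "not_expressed"

ROLE_SECRETED = "secreted"
ROLE_SURFACE = "surface"


@dataclass
class CrosstalkNetwork:
    """Directed bipartite graph secreted(A) -> surface(B) with provenance."""

    tissue_a: str
    tissue_b: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    rejections: Counter = field(default_factory=Counter)
    warnings: list[str] = field(default_factory=list)
    retained_records: int = 0

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    def sources(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if ROLE_SECRETED in d["roles"]}

    def targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if ROLE_SURFACE in d["roles"]}

    def add_edge(self, secreted: str, surface: str, record: MitabRecord, expression_flags) -> None:
        for node, role in ((secreted, ROLE_SECRETED), (surface, ROLE_SURFACE)):
            if node in self.graph:
                self.graph.nodes[node]["roles"] = self.graph.nodes[node]["roles"] | {role}
            else:
                self.graph.add_node(node, roles=frozenset({role}))
        if not self.graph.has_edge(secreted, surface):
            self.graph.add_edge(
                secreted,
                surface,
                detection_methods=sorted(record.detection_methods),
                source_dbs=sorted(record.source_dbs),
                publications=sorted(record.publications),
                evidence_class=record.evidence_class,
                expression_verified=expression_flags,
            )

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, roles=",".join(sorted(data["roles"])))
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                evidence_class=data["evidence_class"],
                source_dbs=";".join(data["source_dbs"]),
                publications=";".join(data["publications"]),
            )
        nx.write_graphml(g, path)


def _expression_ok(
    table: ExpressionTable | None,
    symbol: str,
    tissue: str,
    config: CriteriaConfig,
    warnings: list[str],
) -> bool:
    status = table.lookup(symbol, tissue) if table is not None else None
    if status is None:
        if config.unknown_expression_action == "pass":
            warnings.append(f"expression of {symbol} in {tissue} unknown; passing")
            return True
        return False
    return status


def build_crosstalk(
    secretome_a: Iterable[str],
    surfaceome_b: Iterable[str],
    ppi: Iterable[MitabRecord],
    expression: ExpressionTable | None,
    tissue_a: str,
    tissue_b: str,
    config: CriteriaConfig | None = None,
) -> CrosstalkNetwork:
    """Filter PPI records into the A-secreted -> B-surface network.

    Filter order per record: self-loop; experimental evidence (when
    ``require_experimental_ppi``); role membership (an orientable pair needs
    one endpoint in the secretome of A and the other in the surfaceome of
    B); endpoint expression (when ``require_expression_check``; unknown
    status passes or rejects per ``unknown_expression_action``). A pair
    orientable both ways yields one edge per satisfiable orientation.
    """
    config = config or CriteriaConfig()
    sec_a = set(secretome_a)
    surf_b = set(surfaceome_b)
    net = CrosstalkNetwork(tissue_a=tissue_a, tissue_b=tissue_b)
    for record in sorted(ppi, key=lambda r: (r.interactor_a, r.interactor_b)):
        a, b = record.interactor_a, record.interactor_b
        if record.is_self_loop:
            net.rejections[REASON_SELF_LOOP] += 1
            continue
        if config.require_experimental_ppi and record.evidence_class != "experimental":
            net.rejections[REASON_NON_EXPERIMENTAL] += 1
            continue
        orientations = []
        if a in sec_a and b in surf_b:
            orientations.append((a, b))
        if b in sec_a and a in surf_b:
            orientations.append((b, a))
        if not orientations:
            known = (a in sec_a or a in surf_b) and (b in sec_a or b in surf_b)
            net.rejections[REASON_WRONG_COMPARTMENT if known else REASON_NON_MEMBER] += 1
            continue
        retained = False
        for secreted, surface in dict.fromkeys(orientations):
            if config.require_expression_check:
                ok_a = _expression_ok(expression, secreted, tissue_a, config, net.warnings)
                ok_b = _expression_ok(expression, surface, tissue_b, config, net.warnings)
                if not (ok_a and ok_b):
                    continue
                flags = (
                    expression.lookup(secreted, tissue_a) if expression else None,
                    expression.lookup(surface, tissue_b) if expression else None,
                )
            else:
                flags = (None, None)
            net.add_edge(secreted, surface, record, flags)
            retained = True
        if retained:
            net.retained_records += 1
        else:
            net.rejections[REASON_NOT_EXPRESSED] += 1
    return net


def network_summary(net: CrosstalkNetwork) -> dict:
    """Edge/node counts plus the rejection tally."""
    return {
        "tissue_a": net.tissue_a,
        "tissue_b": net.tissue_b,
        "edges": net.graph.number_of_edges(),
        "nodes": net.graph.number_of_nodes(),
        "sources": len(net.sources()),
        "targets": len(net.targets()),
        "retained_records": net.retained_records,
        "rejections": dict(net.rejections),
        "warnings": len(net.warnings),
    }
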