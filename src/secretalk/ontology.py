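"""GO DAG storage, ancestor closure, and location predicates.

The classifiers need two semantic questions answered for a protein's GO
annotation set: "is any term an extracellular location?" and "is any term
the plasma membrane (or a descendant)?". Both are evaluated by reflexive
transitive closure over ``is_a`` edges; ``part_of`` and other relations are
not traversed (a documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .core import CriteriaConfig

__all__ = ["GODag", "UnknownTermError", "CycleError", "is_extracellular", "is_plasma_membrane"]

log = logging.getLogger(__name__)


class UnknownTermError(KeyError):
    """Raised when a queried term is absent from the DAG."""


class CycleError(ValueError):
    """Raised when the supplied is_a graph contains a cycle."""


@dataclass
class GODag:
    """A GO term DAG over ``is_a`` parent links.

    ``terms`` maps a GO id to ``(name, namespace)``; ``is_a_parents`` maps a
    term to its direct parents. Construction validates that every referenced
    parent exists and that the graph is acyclic.
    """

    terms: dict[str, tuple[str, str]]
    is_a_parents: dict[str, frozenset[str]]
    _closure: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for term, parents in self.is_a_parents.items():
            if term not in self.terms:
                raise ValueError(f"edge from unknown term {term}")
            missing = set(parents) - set(self.terms)
            if missing:
                raise ValueError(f"term {term} has unknown parents {sorted(missing)}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term, parents in self.is_a_parents.items():
            g.add_edges_from((term, p) for p in parents)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"is_a cycle detected at edge {cyc[0][0]} -> {cyc[0][1]}")

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, tuple[str, str]] | Iterable[str],
        edges: Iterable[tuple[str, str]],
    ) -> "GODag":
        """Build from (child, parent) pairs; bare term iterables get empty names."""
        if not isinstance(terms, Mapping):
            terms = {t: (t, "cellular_component") for t in terms}
        parents: dict[str, set[str]] = {t: set() for t in terms}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
        return cls(
            terms=dict(terms),
            is_a_parents={t: frozenset(ps) for t, ps in parents.items()},
        )

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive is_a closure of ``term`` (includes itself)."""
        if term not in self.terms:
            raise UnknownTermError(term)
        cached = self._closure.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.is_a_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.is_a_parents.get(t, ()))
        result = frozenset(out)
        self._closure[term] = result
        return result

    def descendant_of(self, term: str, root: str) -> bool:
        """True iff ``root`` is in the reflexive ancestor closure of ``term``."""
        return root in self.ancestors(term)


def _known_terms(dag: GODag, go_terms: Iterable[str]) -> set[str]:
    known, unknown = set(), set()
    for t in go_terms:
        (known if t in dag else unknown).add(t)
    if unknown:
        log.warning("ignoring %d GO term(s) absent from the DAG: %s", len(unknown), sorted(unknown))
    return known


def is_extracellular(dag: GODag, go_terms: Iterable[str], config: CriteriaConfig) -> bool:
    """True iff any annotated term lies under an extracellular root.

    A term counts if any of ``config.extracellular_roots`` is in its
    reflexive is_a ancestor closure. Terms absent from the DAG are ignored
    with a logged warning.
    """
    roots = config.extracellular_roots
    return any(dag.ancestors(t) & roots for t in _known_terms(dag, go_terms))


def is_plasma_membrane(
    dag: GODag,
    go_terms: Iterable[str],
    config: CriteriaConfig,
    exact: bool = False,
) -> bool:
    """True iff annotation includes the plasma-membrane term or a descendant.

    With ``exact=True`` only the literal root term counts (strict mode;
    default accepts descendants, matching annotation practice of annotating
    to specific children).
    """
    root = config.plasma_membrane_root
    known = _known_terms(dag, go_terms)
    if exact:
        return root in known
    return any(root in dag.ancestors(t) for t in known)
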