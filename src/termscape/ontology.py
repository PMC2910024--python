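"""Gene Ontology DAG handling.

The ontology is a directed acyclic graph of terms connected by typed
child-to-parent edges (``is_a``, ``part_of``, ``regulates``).  Under the
true-path rule an annotation to a term implies annotation to every
ancestor of that term, so the central queries here are ancestor sets and
their sizes (the "specificity level" of a term: the number of its
predecessors in the DAG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("cellular_component", "biological_process", "molecular_function")

#: Relations the true-path rule is conventionally propagated over.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: All relation types the graph stores.
KNOWN_RELATIONS = frozenset({"is_a", "part_of", "regulates"})


@dataclass
class OntologyGraph:
    """A parsed ontology restricted to its typed child->parent edges.

    Attributes
    ----------
    terms:
        term id -> ``(name, namespace)``.
    graph:
        :class:`networkx.MultiDiGraph` with child->parent edges keyed by
        relation type.  Contains only non-obsolete terms.
    roots:
        namespace -> root term id (the term without outgoing edges).
    obsolete:
        ids of obsolete terms; recorded but excluded from traversal.
    alt_ids:
        secondary id -> canonical id.
    """

    terms: dict[str, tuple[str, str]]
    graph: nx.MultiDiGraph
    roots: dict[str, str]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def canonical(self, term: str) -> str:
        """Resolve an alt_id to its canonical term id (identity otherwise)."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            canon = self.alt_ids[term]
            logger.debug("canonicalized alt_id %s -> %s", term, canon)
            return canon
        return term

    def namespace_of(self, term: str) -> str:
        return self.terms[term][1]

    def name_of(self, term: str) -> str:
        return self.terms[term][0]

    def edges(self) -> Iterable[tuple[str, str, str]]:
        """Yield (child, parent, relation) triples."""
        return self.graph.edges(keys=True)

    def parents(self, term: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        term = self._check_term(term)
        return {
            p
            for _, p, rel in self.graph.out_edges(term, keys=True)
            if rel in relations
        }

    def children(self, term: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        term = self._check_term(term)
        return {
            c
            for c, _, rel in self.graph.in_edges(term, keys=True)
            if rel in relations
        }

    def ancestors(self, term: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        """All terms reachable from ``term`` by following parent edges.

        ``term`` itself is excluded; each ancestor appears once regardless
        of how many paths reach it (true-path rule closure).
        """
        term = self._check_term(term)
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, rel in self.graph.out_edges(node, keys=True):
                if rel in relations and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def descendants(self, term: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        """All terms from which ``term`` is reachable (inverse of ancestors)."""
        term = self._check_term(term)
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for child, _, rel in self.graph.in_edges(node, keys=True):
                if rel in relations and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen

    def specificity_level(self, term: str, relations: frozenset[str] = DEFAULT_RELATIONS) -> int:
        """Number of predecessors (ancestors) of ``term`` in the DAG."""
        return len(self.ancestors(term, relations))

    def _check_term(self, term: str) -> str:
        term = self.canonical(term)
        if term in self.obsolete:
            raise KeyError(f"term {term!r} is obsolete")
        if term not in self.terms:
            raise KeyError(f"unknown term id {term!r}")
        return term


def parse_obo(source: str | IO[str], namespace_filter: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 ontology into an :class:`OntologyGraph`.

    Parameters
    ----------
    source:
        Path or open text handle of the OBO file.
    namespace_filter:
        If given, keep only terms of this namespace.

    Raises
    ------
    ValueError
        On a cycle (naming one member), a dangling parent id, or an
        unknown namespace filter.
    """
    if namespace_filter is not None and namespace_filter not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace_filter!r}")

    raw = obonet.read_obo(source, ignore_obsolete=False)

    terms: dict[str, tuple[str, str]] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        if "name" not in data and "namespace" not in data:
            continue  # dangling target; reported below if referenced by a kept term
        ns = data.get("namespace", "")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        if namespace_filter is not None and ns != namespace_filter:
            continue
        terms[node] = (data.get("name", node), ns)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    graph = nx.MultiDiGraph()
    graph.add_nodes_from(terms)
    for child, parent, rel in raw.edges(keys=True):
        if child not in terms:
            continue
        if rel not in KNOWN_RELATIONS:
            continue
        if parent in obsolete:
            continue
        if parent not in terms:
            if namespace_filter is not None and parent in raw and (
                raw.nodes[parent].get("namespace", "") != namespace_filter
                and "name" in raw.nodes[parent]
            ):
                continue  # cross-namespace edge dropped under the filter
            raise ValueError(f"dangling parent id {parent!r} referenced by {child!r}")
        graph.add_edge(child, parent, key=rel)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")

    roots: dict[str, str] = {}
    for node in graph.nodes:
        if graph.out_degree(node) == 0:
            ns = terms[node][1]
            if ns in roots:
                raise ValueError(
                    f"multiple roots in namespace {ns!r}: {roots[ns]!r} and {node!r}"
                )
            roots[ns] = node

    return OntologyGraph(terms=terms, graph=graph, roots=roots, obsolete=obsolete, alt_ids=alt_ids)


def ancestors(graph: OntologyGraph, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
    """Functional form of :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term, frozenset(relations))


def specificity_level(graph: OntologyGraph, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> int:
    """Functional form of :meth:`OntologyGraph.specificity_level`."""
    return graph.specificity_level(term, frozenset(relations))
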