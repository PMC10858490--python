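"""Phenotype ontology graphs, information content and MICA lookup.

The ontology is a DAG of terms linked by ``is_a`` edges (child -> parent).
Information content is defined structurally: ``IC(p) = -log(n_p / N)`` with
``n_p`` the number of terms subsumed by ``p`` (including ``p`` itself) and
``N`` the total number of terms in the loaded graph.  The most informative
common ancestor (MICA) of two terms is the shared reflexive ancestor with
maximal IC.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

SYNTHETIC_ROOT = "SYNTHETIC:ROOT"


class OntologyError(ValueError):
    """Structural or lookup problem with an ontology graph."""


@dataclass(frozen=True)
class OntologyGraph:
    """Validated DAG of phenotype terms.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point child -> parent
    (is_a direction).  ``root`` is the unique parentless term; when the input
    had several parentless terms a synthetic root is inserted above them and
    ``synthetic_root`` is True.
    """

    graph: nx.DiGraph
    root: str
    synthetic_root: bool = False
    names: Mapping[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def _check(self, term: str) -> None:
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term!r}")

    def ancestors(self, term: str, reflexive: bool = False) -> set[str]:
        """Terms reachable from ``term`` by following is_a edges upward."""
        self._check(term)
        anc = nx.descendants(self.graph, term)  # edges point child->parent
        if reflexive:
            anc.add(term)
        return anc

    def descendants(self, term: str, reflexive: bool = False) -> set[str]:
        """Terms subsumed by ``term`` (its is_a descendants)."""
        self._check(term)
        dec = nx.ancestors(self.graph, term)
        if reflexive:
            dec.add(term)
        return dec

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        self._check(term)
        return set(self.graph.predecessors(term))


@dataclass(frozen=True)
class TermStats:
    """Per-term reflexive descendant counts and information content.

    ``ic`` is in natural-log units by default; Lin similarity is a ratio of
    ICs and therefore invariant to the log base.
    """

    descendant_count: Mapping[str, int]
    total_terms: int
    ic: Mapping[str, float]


def _validate(graph: nx.DiGraph) -> str:
    if graph.number_of_nodes() == 0:
        raise OntologyError("empty term set")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"cycle detected involving term {cycle[0][0]!r}")
    roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
    if not roots:  # pragma: no cover - acyclic graphs always have a sink
        raise OntologyError("no root term found")
    if len(roots) > 1:
        logger.warning(
            "%d parentless terms; bridging under synthetic root %s",
            len(roots), SYNTHETIC_ROOT,
        )
        graph.add_node(SYNTHETIC_ROOT)
        for r in roots:
            graph.add_edge(r, SYNTHETIC_ROOT)
        return SYNTHETIC_ROOT
    return roots[0]


def _from_edges(terms: Iterable[str], edges: Iterable[tuple[str, str]],
                names: Mapping[str, str] | None = None) -> OntologyGraph:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parent in edges:
        if child == parent:
            raise OntologyError(f"self-edge on term {child!r}")
        g.add_edge(child, parent)
    root = _validate(g)
    return OntologyGraph(
        graph=g, root=root,
        synthetic_root=(root == SYNTHETIC_ROOT),
        names=dict(names or {}),
    )


def load_obo(source: str | io.TextIOBase) -> OntologyGraph:
    """Load an ontology from OBO text (path, handle or literal text).

    Only ``is_a`` relations are used; obsolete terms are skipped.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    multi = obonet.read_obo(source, ignore_obsolete=True)
    terms = list(multi.nodes)
    names = {t: d["name"] for t, d in multi.nodes(data=True) if "name" in d}
    edges = {
        (child, parent)
        for child, parent, key in multi.edges(keys=True)
        if key == "is_a"
    }
    return _from_edges(terms, edges, names)


def load_edge_table(source: str | io.TextIOBase) -> OntologyGraph:
    """Load a 2-column tab-separated child<TAB>parent edge table.

    Lines starting with ``#`` are comments.  Terms appearing only as parents
    are added to the term set.
    """
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            handle: io.TextIOBase = io.StringIO(source)
        else:
            handle = open(source)
    else:
        handle = source
    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            child, parent = parts
            terms.update((child, parent))
            edges.add((child, parent))
    if not terms:
        raise OntologyError("empty term set")
    return _from_edges(terms, edges)


def load_ontology(source: str | io.TextIOBase) -> OntologyGraph:
    """Load an ontology from OBO text or a child-parent edge table.

    Format is sniffed: content containing a ``[Term]`` stanza is parsed as
    OBO, anything else as an edge table.  ``source`` may be a path or text.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    if "[Term]" in text:
        return load_obo(io.StringIO(text))
    return load_edge_table(io.StringIO(text))


def ancestors(graph: OntologyGraph, term: str, reflexive: bool = False) -> set[str]:
    return graph.ancestors(term, reflexive=reflexive)


def descendant_counts(graph: OntologyGraph) -> dict[str, int]:
    """Reflexive descendant count per term, by reverse-topological accumulation.

    In a DAG a plain sum over children would double-count terms reachable by
    several paths, so counts are computed from explicit descendant sets.
    """
    counts: dict[str, int] = {}
    for term in graph.terms:
        counts[term] = len(graph.descendants(term, reflexive=True))
    return counts


def information_content(graph: OntologyGraph, *, base: float | None = None) -> TermStats:
    """Build :class:`TermStats` with ``IC(p) = -log(n_p / N)``.

    ``base=None`` means natural log.  ``ic(root) = 0`` and IC never decreases
    from parent to child.
    """
    counts = descendant_counts(graph)
    n_total = len(graph)
    log = math.log if base is None else (lambda x: math.log(x, base))
    ic = {t: -log(n / n_total) + 0.0 for t, n in counts.items()}  # +0.0 avoids -0.0 at the root
    return TermStats(descendant_count=counts, total_terms=n_total, ic=ic)


def mica(graph: OntologyGraph, stats: TermStats, p1: str, p2: str) -> str:
    """Most informative common ancestor of ``p1`` and ``p2``.

    Ties on IC are broken by term id for determinism; downstream code only
    uses the IC value, which is unique.
    """
    common = graph.ancestors(p1, reflexive=True) & graph.ancestors(p2, reflexive=True)
    if not common:  # pragma: no cover - a single root guarantees a common ancestor
        raise OntologyError(f"no common ancestor for {p1!r}, {p2!r}")
    return max(sorted(common), key=lambda t: stats.ic[t])
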