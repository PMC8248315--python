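"""Labeled-graph construction from axioms, associations and interactions.

The transformation maps each axiom in the supported fragment onto one or
more subject–predicate–object triples:

* ``A SubClassOf B`` (empty chain, named filler) -> ``<A, SubClassOf, B>``
* ``A EquivalentTo B``                            -> ``<A, EquivalentTo, B>``
* ``A (SubClassOf|EquivalentTo) Q R0 ... Q Rm (B1 u ... u Bn)`` ->
  one triple ``<A, R0.R1...Rm, Bi>`` per filler member ``Bi``; the
  quantifier chain becomes a single composed edge label (relations joined
  with ``.``) and the quantifier kinds themselves are deliberately
  ignored — existential, universal and cardinality restrictions all
  produce the same edge.  Unions and intersections are treated alike.

Gene/disease annotations become direct ``<entity, relation, class>``
edges and protein interactions become ``<a, interacts-with, b>`` edges.
Triples are directed but the adjacency structure lists every edge from
both endpoints with its forward label, so walkers traverse the graph as
undirected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .axioms import Axiom, AxiomSet

logger = logging.getLogger(__name__)

SUBCLASS_LABEL = "SubClassOf"
EQUIVALENCE_LABEL = "EquivalentTo"
INTERACTS_LABEL = "interacts-with"
RELATION_SEPARATOR = "."


class Triple(NamedTuple):
    """A directed labeled edge."""

    subject: str
    predicate: str
    object: str


def compose_relations(relations: Iterable[str]) -> str:
    """Join a quantifier chain's relation names into one edge-label token."""
    label = RELATION_SEPARATOR.join(relations)
    if not label:
        raise ValueError("cannot compose an empty relation chain")
    return label


def transform_axiom(axiom: Axiom) -> list[Triple]:
    """Apply the transformation rules to a single axiom.

    Returns the triples in filler order.  An axiom with an empty
    quantifier chain and a single named filler maps to one
    SubClassOf/EquivalentTo triple; any axiom with a non-empty chain
    (or a boolean filler) maps to one composed-relation triple per
    filler member.
    """
    rhs = axiom.rhs
    if not rhs.chain:
        if rhs.filler_kind == "single":
            label = SUBCLASS_LABEL if axiom.kind == "subclass" else EQUIVALENCE_LABEL
            return [Triple(axiom.subject, label, rhs.filler[0])]
        # chain-less boolean filler: rule 1 with m = -1 has no relation to
        # compose, so fall back to the subclass/equivalence label per member
        label = SUBCLASS_LABEL if axiom.kind == "subclass" else EQUIVALENCE_LABEL
        return [Triple(axiom.subject, label, member) for member in rhs.filler]
    label = compose_relations(rhs.relations)
    return [Triple(axiom.subject, label, member) for member in rhs.filler]


@dataclass
class LabeledGraph:
    """Node set plus deduplicated labeled triples with undirected adjacency.

    ``adjacency`` maps every node to the list of ``(edge_label, neighbor)``
    pairs reachable by traversing an incident triple in either direction;
    reverse traversal reuses the forward label.
    """

    nodes: set[str] = field(default_factory=set)
    triples: set[Triple] = field(default_factory=set)
    adjacency: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def add_node(self, node: str) -> None:
        if node not in self.nodes:
            self.nodes.add(node)
            self.adjacency[node] = []

    def add_triple(self, triple: Triple) -> bool:
        """Insert a triple; returns False if it was already present."""
        if not triple.predicate:
            raise ValueError(f"empty predicate in {triple}")
        if triple in self.triples:
            return False
        self.triples.add(triple)
        self.add_node(triple.subject)
        self.add_node(triple.object)
        self.adjacency[triple.subject].append((triple.predicate, triple.object))
        if triple.object != triple.subject:
            self.adjacency[triple.object].append((triple.predicate, triple.subject))
        return True

    def neighbors(self, node: str) -> list[tuple[str, str]]:
        return self.adjacency[node]

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    @property
    def edge_labels(self) -> set[str]:
        return {t.predicate for t in self.triples}

    def has_edge(self, a: str, label: str, b: str) -> bool:
        """True if <a,label,b> exists in either direction."""
        return Triple(a, label, b) in self.triples or Triple(b, label, a) in self.triples

    def __len__(self) -> int:
        return len(self.nodes)


def add_axioms(graph: LabeledGraph, axioms: AxiomSet | Iterable[Axiom]) -> LabeledGraph:
    for axiom in axioms:
        for triple in transform_axiom(axiom):
            graph.add_triple(triple)
    return graph


def add_associations(graph: LabeledGraph, associations) -> LabeledGraph:
    """Add one ``<entity, relation, class>`` edge per association."""
    for assoc in associations:
        graph.add_triple(Triple(assoc.entity_id, assoc.relation, assoc.class_id))
    return graph


def add_interactions(graph: LabeledGraph, interactions) -> LabeledGraph:
    """Add one ``<a, interacts-with, b>`` edge per interaction.

    The pair is canonicalized (lexicographically smaller endpoint first)
    so that both orders of the same undirected interaction dedup to a
    single triple.
    """
    for edge in interactions:
        a, b = sorted((edge.entity_a, edge.entity_b))
        graph.add_triple(Triple(a, INTERACTS_LABEL, b))
    return graph


def build_graph(
    axioms: AxiomSet | None = None,
    associations=None,
    interactions=None,
) -> LabeledGraph:
    """Build the walk substrate from axioms, annotations and interactions."""
    graph = LabeledGraph()
    if axioms is not None:
        add_axioms(graph, axioms)
    if associations is not None:
        add_associations(graph, associations)
    if interactions is not None:
        add_interactions(graph, interactions)
    if not graph.triples:
        logger.warning("built an empty graph: no triples produced from inputs")
    return graph


def write_edgelist(graph: LabeledGraph, path: str | Path) -> None:
    """Serialize as a sorted 3-column TSV edge list."""
    with open(path, "w") as fh:
        for s, p, o in sorted(graph.triples):
            fh.write(f"{s}\t{p}\t{o}\n")


def read_edgelist(path: str | Path) -> LabeledGraph:
    graph = LabeledGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            graph.add_triple(Triple(*parts))
    return graph
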