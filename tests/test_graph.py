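"""Axiom-to-triple transformation rules and labeled-graph assembly."""

import numpy as np
import pytest

from ontorank.associations import Association, InteractionEdge
from ontorank.axioms import Axiom, AxiomSet, ClassExpr
from ontorank.graph import (
    LabeledGraph,
    Triple,
    add_associations,
    add_interactions,
    build_graph,
    read_edgelist,
    transform_axiom,
    write_edgelist,
)


def brute_force_rules(axiom: Axiom) -> set[tuple[str, str, str]]:
    """Independent rule applier: pattern-match the axiom shape directly.

    Empty chain + named filler -> one SubClassOf/EquivalentTo triple;
    otherwise one triple per filler member whose predicate is the
    dot-joined relation chain (or the axiom keyword when the chain is
    empty).
    """
    keyword = {"subclass": "SubClassOf", "equivalence": "EquivalentTo"}[axiom.kind]
    relations = [rel for _kind, rel in axiom.rhs.chain]
    predicate = ".".join(relations) if relations else keyword
    return {(axiom.subject, predicate, member) for member in axiom.rhs.filler}


def random_axiom(rng: np.random.Generator) -> Axiom:
    classes = [f"C{i}" for i in range(30)]
    rels = [f"r{i}" for i in range(6)]
    kinds = ["existential", "universal", "cardinality"]
    chain = tuple(
        (kinds[rng.integers(3)], rels[rng.integers(len(rels))])
        for _ in range(rng.integers(0, 4))
    )
    shape = rng.integers(3)
    if shape == 0 or (not chain and rng.random() < 0.5):
        filler, fkind = (classes[rng.integers(len(classes))],), "single"
    else:
        size = int(rng.integers(2, 5))
        members = rng.choice(len(classes), size=size, replace=False)
        filler = tuple(classes[i] for i in members)
        fkind = "union" if shape == 1 else "intersection"
    return Axiom(
        "subclass" if rng.random() < 0.5 else "equivalence",
        classes[rng.integers(len(classes))],
        ClassExpr(chain, filler, fkind),
    )


class TestTransformAxiom:
    def test_plain_subclass_triple(self):
        ax = Axiom("subclass", "feeding_behavior", ClassExpr((), ("behavior",), "single"))
        assert transform_axiom(ax) == [Triple("feeding_behavior", "SubClassOf", "behavior")]

    def test_equivalence_triple(self):
        ax = Axiom("equivalence", "A", ClassExpr((), ("B",), "single"))
        assert transform_axiom(ax) == [Triple("A", "EquivalentTo", "B")]

    def test_union_filler_yields_one_triple_per_member(self):
        ax = Axiom("subclass", "A", ClassExpr((("existential", "R"),), ("B1", "B2"), "union"))
        assert transform_axiom(ax) == [Triple("A", "R", "B1"), Triple("A", "R", "B2")]

    def test_quantifier_chain_composes_into_one_label(self):
        ax = Axiom(
            "subclass",
            "A",
            ClassExpr((("existential", "R0"), ("existential", "R1")), ("C",), "single"),
        )
        assert transform_axiom(ax) == [Triple("A", "R0.R1", "C")]

    def test_quantifier_kinds_map_to_identical_edges(self):
        triples = {
            transform_axiom(
                Axiom("subclass", "A", ClassExpr(((kind, "R"),), ("B",), "single"))
            )[0]
            for kind in ("existential", "universal", "cardinality")
        }
        assert triples == {Triple("A", "R", "B")}

    def test_matches_brute_force_rule_applier_on_random_axioms(self):
        """Oracle equivalence, triple-for-triple, on 200 random axioms."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            ax = random_axiom(rng)
            assert set(transform_axiom(ax)) == brute_force_rules(ax)


class TestGraphAssembly:
    def test_association_edges(self):
        g = add_associations(LabeledGraph(), [Association("g1", "has-function", "GO:1")])
        assert g.triples == {Triple("g1", "has-function", "GO:1")}
        assert g.adjacency["GO:1"] == [("has-function", "g1")]

    def test_empty_associations_leave_graph_unchanged(self):
        g = LabeledGraph()
        g.add_triple(Triple("a", "R", "b"))
        before = set(g.triples)
        add_associations(g, [])
        assert g.triples == before

    def test_interaction_edges_dedup_both_orders(self):
        g = add_interactions(
            LabeledGraph(),
            [InteractionEdge("p1", "p2", 900), InteractionEdge("p2", "p1", 900)],
        )
        assert len(g.triples) == 1
        assert g.has_edge("p1", "interacts-with", "p2")
        assert g.has_edge("p2", "interacts-with", "p1")

    def test_build_graph_toy_enumeration(self):
        """Hand-applied rules on a 3-axiom + 2-association toy input."""
        axioms = AxiomSet.from_axioms(
            [
                Axiom("subclass", "P1", ClassExpr((), ("P0",), "single")),
                Axiom("subclass", "P1", ClassExpr((("existential", "has-part"),), ("F1", "F2"), "union")),
                Axiom("equivalence", "P2", ClassExpr((), ("P1",), "single")),
            ]
        )
        assocs = [
            Association("d1", "has-phenotype", "P1"),
            Association("g1", "has-function", "F1"),
        ]
        g = build_graph(axioms, assocs)
        assert g.triples == {
            Triple("P1", "SubClassOf", "P0"),
            Triple("P1", "has-part", "F1"),
            Triple("P1", "has-part", "F2"),
            Triple("P2", "EquivalentTo", "P1"),
            Triple("d1", "has-phenotype", "P1"),
            Triple("g1", "has-function", "F1"),
        }

    def test_axioms_only_graph_has_only_class_nodes(self):
        axioms = AxiomSet.from_axioms(
            [Axiom("subclass", "A", ClassExpr((), ("B",), "single"))]
        )
        g = build_graph(axioms)
        assert g.nodes == {"A", "B"}

    def test_defined_phenotype_links_disease_to_gene_within_three_edges(self):
        """A phenotype defined via a process class puts an annotated gene
        within 3 edges of a disease annotated with that phenotype."""
        axioms = AxiomSet.from_axioms(
            [
                Axiom(
                    "equivalence",
                    "visual_impairment",
                    ClassExpr((("existential", "has-part"),), ("visual_perception",), "single"),
                )
            ]
        )
        assocs = [
            Association("disease", "has-phenotype", "visual_impairment"),
            Association("CRYGC", "has-function", "visual_perception"),
        ]
        g = build_graph(axioms, assocs)
        # breadth-first distance over undirected adjacency
        frontier, seen = {"disease"}, {"disease"}
        for _hop in range(3):
            frontier = {n for f in frontier for _l, n in g.neighbors(f)} - seen
            seen |= frontier
            if "CRYGC" in seen:
                break
        assert "CRYGC" in seen

    def test_monotonicity_adding_inputs_never_removes_triples(self):
        rng = np.random.default_rng(7)
        axioms = [random_axiom(rng) for _ in range(20)]
        g1 = build_graph(AxiomSet.from_axioms(axioms[:10]))
        g2 = build_graph(AxiomSet.from_axioms(axioms))
        assert g1.triples <= g2.triples

    def test_every_matching_axiom_subject_and_filler_become_nodes(self):
        rng = np.random.default_rng(11)
        axioms = AxiomSet.from_axioms([random_axiom(rng) for _ in range(50)])
        g = build_graph(axioms)
        for ax in axioms:
            assert ax.subject in g.nodes
            assert set(ax.rhs.filler) <= g.nodes

    def test_edgelist_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        g = build_graph(AxiomSet.from_axioms([random_axiom(rng) for _ in range(30)]))
        path = tmp_path / "edges.tsv"
        write_edgelist(g, path)
        g2 = read_edgelist(path)
        assert g2.triples == g.triples
        assert g2.nodes == g.nodes

    def test_empty_predicate_rejected(self):
        with pytest.raises(ValueError):
            LabeledGraph().add_triple(Triple("a", "", "b"))
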