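"""Edge-label-aware uniform random walks producing a sentence corpus.

Each walk starts at a node and repeatedly moves to a uniformly chosen
neighbor over the undirected adjacency multiset, emitting the traversed
edge's label between the two node tokens, so a sentence alternates
``node, label, node, label, ...``.  A walk of ``steps`` edge traversals
yields at most ``2 * steps + 1`` tokens; it ends early only at a node
with no neighbors.  Walks are unbiased first-order walks: immediate
backtracking is allowed and no restart or node2vec-style p/q bias is
applied.

Default regime: 80 walks per node of 20 steps; with protein-interaction
edges in the graph, 200 walks of 30 steps compensate for the higher node
degree.

Reproducibility: each start node gets its own RNG stream derived from
(seed, node index in sorted node order), so the corpus is byte-identical
for a fixed seed even if walk generation is parallelized or reordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .graph import LabeledGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Walk-generation parameters.

    ``walks_per_node`` and ``steps`` default to the ontology-only regime
    (80 walks of 20 edge traversals); use :meth:`with_interactions` for
    the denser interaction-augmented graphs (200 walks of 30 steps).
    """

    walks_per_node: int = 80
    steps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")

    @classmethod
    def with_interactions(cls, seed: int = 0) -> "WalkConfig":
        return cls(walks_per_node=200, steps=30, seed=seed)


@dataclass
class WalkCorpus:
    """Sentences of alternating node / edge-label tokens."""

    sentences: list[list[str]] = field(default_factory=list)

    @property
    def vocabulary(self) -> set[str]:
        return {tok for sent in self.sentences for tok in sent}

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[list[str]]:
        return iter(self.sentences)

    def save(self, path: str | Path) -> None:
        """One sentence per line, space-separated tokens."""
        with open(path, "w") as fh:
            for sent in self.sentences:
                fh.write(" ".join(sent) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WalkCorpus":
        with open(path) as fh:
            return cls([line.split() for line in fh if line.strip()])


def random_walk(
    graph: LabeledGraph,
    start: str,
    steps: int,
    rng: np.random.Generator,
) -> list[str]:
    """One uniform random walk; returns the token sentence.

    Raises ``KeyError`` if ``start`` is not a node of the graph.
    """
    if start not in graph.nodes:
        raise KeyError(f"start node {start!r} not in graph")
    sentence = [start]
    node = start
    if steps == 0:
        return sentence
    # draw all step variates up front; unused tail is discarded on dead ends
    u = rng.random(steps)
    for i in range(steps):
        neighbors = graph.adjacency[node]
        if not neighbors:
            break
        label, node = neighbors[int(u[i] * len(neighbors))]
        sentence.append(label)
        sentence.append(node)
    return sentence


def build_corpus(graph: LabeledGraph, config: WalkConfig) -> WalkCorpus:
    """Generate ``walks_per_node`` sentences from every node of the graph."""
    corpus = WalkCorpus()
    if not graph.nodes:
        logger.warning("walking an empty graph: corpus is empty")
        return corpus
    for index, node in enumerate(sorted(graph.nodes)):
        stream = np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
        rng = np.random.Generator(np.random.PCG64(stream))
        for _ in range(config.walks_per_node):
            corpus.sentences.append(random_walk(graph, node, config.steps, rng))
    return corpus


def validate_corpus(corpus: WalkCorpus, graph: LabeledGraph) -> int:
    """Re-verify every consecutive (node, label, node) triple against the
    edge set (either direction); returns the number of sentences checked,
    raising ``AssertionError`` on the first invalid one."""
    for sent in corpus:
        if sent[0] not in graph.nodes:
            raise AssertionError(f"sentence starts at unknown node {sent[0]!r}")
        for i in range(0, len(sent) - 2, 2):
            a, label, b = sent[i], sent[i + 1], sent[i + 2]
            if not graph.has_edge(a, label, b):
                raise AssertionError(f"no edge <{a},{label},{b}> in graph")
    return len(corpus.sentences)
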