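"""End-to-end pipeline: graph -> walks -> embeddings -> ranking -> metrics.

``run_pipeline`` wires the stages together for a synthetic bundle (or
any axiom set + associations + gold standard) and returns the evaluation
report along with the pooled test rankings.  The walk/embedding defaults
here are the benchmark protocol (smaller than the full-scale regime the
individual modules default to; see docs/methods.md for the rationale and
the module docstrings for the full-scale values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .associations import Association, InteractionEdge
from .axioms import AxiomSet
from .embedding import EmbeddingTable, SkipGramEmbedder
from .evaluate import EvalReport, RankingResult, evaluate
from .graph import LabeledGraph, build_graph
from .ranker import cross_validate
from .synthetic import SynthBundle, shuffled_gold
from .walks import WalkConfig, build_corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Benchmark-scale pipeline parameters.

    ``walks_per_node``/``steps`` and the skip-gram settings are sized for
    the synthetic benchmark graphs (~1000 nodes); at full ontology scale
    the module defaults (80 walks of 20 steps, 200 dimensions, 20
    epochs) apply instead.
    """

    walks_per_node: int = 20
    steps: int = 20
    dim: int = 100
    window: int = 10
    sg_epochs: int = 5
    n_folds: int = 10
    negatives_per_positive: int = 20
    ranker_max_epochs: int = 200
    seed: int = 0


def embed_graph(graph: LabeledGraph, config: PipelineConfig) -> EmbeddingTable:
    corpus = build_corpus(
        graph, WalkConfig(config.walks_per_node, config.steps, seed=config.seed)
    )
    embedder = SkipGramEmbedder(
        n_components=config.dim,
        window=config.window,
        epochs=config.sg_epochs,
        min_count=1,
        seed=config.seed,
    )
    return embedder.fit(corpus).embedding_table_


def run_pipeline(
    axiom_set: AxiomSet,
    associations: Sequence[Association],
    gold_pairs: Sequence[tuple[str, str]],
    gene_universe: Sequence[str],
    interactions: Sequence[InteractionEdge] = (),
    config: PipelineConfig = PipelineConfig(),
) -> tuple[EvalReport, RankingResult]:
    """Build the labeled graph, embed it, cross-validate the ranker on
    the gold standard and evaluate the pooled test rankings."""
    graph = build_graph(axiom_set, associations, interactions or None)
    embeddings = embed_graph(graph, config)
    _models, results = cross_validate(
        gold_pairs,
        gene_universe,
        embeddings,
        n_folds=config.n_folds,
        negatives_per_positive=config.negatives_per_positive,
        seed=config.seed,
        max_epochs=config.ranker_max_epochs,
    )
    return evaluate(results), results


def run_benchmark(
    bundle: SynthBundle,
    config: PipelineConfig = PipelineConfig(),
    shuffle_labels: bool = False,
) -> tuple[EvalReport, RankingResult]:
    """Run the full pipeline on a synthetic bundle.

    With ``shuffle_labels`` the disease column of the gold pairs is
    permuted before cross-validation (negative control: embeddings keep
    their structure but the supervision is random, so ranking should be
    at chance).
    """
    gold = bundle.gold_pairs if not shuffle_labels else shuffled_gold(bundle, seed=config.seed)
    return run_pipeline(
        bundle.axiom_set,
        bundle.associations,
        gold,
        bundle.gene_universe,
        interactions=bundle.interactions,
        config=config,
    )
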