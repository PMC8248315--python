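"""Fold protocol, negative sampling, and the two-tower ranking model."""

import numpy as np
import pytest

from ontorank.embedding import EmbeddingTable
from ontorank.ranker import (
    FoldSplit,
    PairRanker,
    cross_validate,
    make_folds,
    sample_negatives,
    train_fold,
)


class TestMakeFolds:
    def test_test_sets_partition_disease_universe(self):
        diseases = [f"d{i}" for i in range(100)]
        folds = make_folds(diseases, n_folds=10, seed=0)
        test_sets = [set(f.test) for f in folds]
        assert all(len(t) == 10 for t in test_sets)
        for i in range(10):
            for j in range(i + 1, 10):
                assert not test_sets[i] & test_sets[j]
        assert set().union(*test_sets) == set(diseases)

    def test_within_fold_sets_are_disjoint_and_complete(self):
        folds = make_folds([f"d{i}" for i in range(40)], n_folds=10, seed=1)
        for f in folds:
            assert set(f.test) | set(f.train) | set(f.validation) == {
                f"d{i}" for i in range(40)
            }
            assert not set(f.test) & (set(f.train) | set(f.validation))

    def test_validation_is_about_ten_percent_of_non_test(self):
        folds = make_folds([f"d{i}" for i in range(100)], n_folds=10, seed=2)
        for f in folds:
            assert len(f.validation) == 9  # round(0.1 * 90)

    def test_seed_reproducibility(self):
        d = [f"d{i}" for i in range(30)]
        assert make_folds(d, 5, seed=3) == make_folds(d, 5, seed=3)
        assert make_folds(d, 5, seed=3) != make_folds(d, 5, seed=4)

    def test_fewer_diseases_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["d1", "d2"], n_folds=10)

    def test_overlapping_fold_construction_rejected(self):
        with pytest.raises(ValueError):
            FoldSplit(0, test=("a",), train=("a", "b"), validation=("c",))


class TestSampleNegatives:
    def test_twenty_negatives_per_positive_disjoint_from_positives(self):
        universe = [f"g{i}" for i in range(50)]
        negs = sample_negatives([("g0", "d")], universe, k=20, rng=0)
        assert len(negs) == 20
        assert all(d == "d" for _g, d in negs)
        assert "g0" not in {g for g, _d in negs}
        assert len(set(negs)) == 20

    def test_no_duplicates_within_disease_across_positives(self):
        universe = [f"g{i}" for i in range(100)]
        negs = sample_negatives([("g0", "d"), ("g1", "d")], universe, k=20, rng=1)
        assert len(negs) == len(set(negs)) == 40

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="cannot supply"):
            sample_negatives([("g0", "d")], [f"g{i}" for i in range(10)], k=20, rng=0)

    def test_sampling_is_uniform_over_eligible_genes(self):
        """Over 10^4 resamples each eligible gene is drawn with equal
        frequency within 3 standard errors."""
        universe = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        counts = {g: 0 for g in universe if g != "g0"}
        n_rounds, k = 10_000, 2
        for _ in range(n_rounds):
            for g, _d in sample_negatives([("g0", "d")], universe, k=k, rng=rng):
                counts[g] += 1
        p = k / 9
        expected = n_rounds * p
        se = np.sqrt(n_rounds * p * (1 - p))
        for g, c in counts.items():
            assert abs(c - expected) <= 3 * se, g


def planted_embeddings(n_genes=60, n_diseases=12, dim=100, seed=0):
    """Synthetic embedding table where each disease vector sits near the
    mean of its two causal genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    diseases = [f"d{i:02d}" for i in range(n_diseases)]
    gv = rng.normal(size=(n_genes, dim))
    positives = []
    dv = np.empty((n_diseases, dim))
    for i, d in enumerate(diseases):
        causal = [genes[2 * i], genes[2 * i + 1]]
        positives += [(g, d) for g in causal]
        dv[i] = gv[2 * i : 2 * i + 2].mean(axis=0) + 0.05 * rng.normal(size=dim)
    vectors = np.vstack([gv, dv]).astype(np.float32)
    index = {t: i for i, t in enumerate(genes + diseases)}
    return EmbeddingTable(index=index, vectors=vectors), positives, genes, diseases


@pytest.fixture(scope="module")
def planted():
    return planted_embeddings()


class TestPairRanker:
    def fit_small(self, seed=0, **kw):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 32))
        y = (rng.random(80) < 0.3).astype(float)
        model = PairRanker(seed=seed, max_epochs=5, **kw)
        return model.fit(X, y), X, y

    def test_scores_strictly_inside_unit_interval(self, planted):
        emb, positives, genes, diseases = planted
        folds = make_folds(diseases, n_folds=3, seed=0)
        model, _ = train_fold(folds[0], positives, genes, emb, seed=0, max_epochs=10)
        scores = model.score_pairs(emb.lookup(genes), emb[diseases[0]])
        assert np.all((scores > 0) & (scores < 1))

    def test_evaluation_mode_scoring_is_deterministic(self):
        model, X, _y = self.fit_small()
        assert np.array_equal(model.decision_function(X), model.decision_function(X))

    def test_score_is_not_symmetric_in_its_inputs(self):
        """The towers are independent: score(g, d) != score(d, g)."""
        model, X, _y = self.fit_small()
        d = X.shape[1] // 2
        swapped = np.hstack([X[:, d:], X[:, :d]])
        assert not np.allclose(model.decision_function(X), model.decision_function(swapped))

    def test_validation_loss_improves_from_initialization(self, planted):
        emb, positives, genes, diseases = planted
        folds = make_folds(diseases, n_folds=3, seed=0)
        model, _ = train_fold(folds[0], positives, genes, emb, seed=0, max_epochs=50)
        val = model.loss_history_["val"]
        assert model.best_loss_ <= val[0]
        assert len(val) >= 1

    def test_training_is_deterministic_to_six_decimals(self, planted):
        emb, positives, genes, diseases = planted
        folds = make_folds(diseases, n_folds=3, seed=0)
        m1, _ = train_fold(folds[0], positives, genes, emb, seed=7, max_epochs=20)
        m2, _ = train_fold(folds[0], positives, genes, emb, seed=7, max_epochs=20)
        assert round(m1.best_loss_, 6) == round(m2.best_loss_, 6)

    def test_planted_structure_is_recovered(self, planted):
        """On embeddings with planted gene-disease proximity, held-out
        diseases rank their causal genes highly."""
        emb, positives, genes, diseases = planted
        _models, results = cross_validate(
            positives, genes, emb, n_folds=3, seed=0, max_epochs=30
        )
        from ontorank.evaluate import per_disease_auc

        aucs = per_disease_auc(results)
        assert len(aucs) == len(diseases)
        assert np.mean(list(aucs.values())) > 0.9
        # separation: true genes outscore decoys on average
        r = results.rankings[0]
        pos_scores = [s for g, s in zip(r.genes, r.scores) if g in r.positives]
        neg_scores = [s for g, s in zip(r.genes, r.scores) if g not in r.positives]
        assert np.mean(pos_scores) > np.mean(neg_scores)

    def test_missing_embeddings_error_lists_ids(self, planted):
        emb, positives, genes, diseases = planted
        folds = make_folds(diseases, n_folds=3, seed=0)
        positives_bad = positives + [("ghost_gene", diseases[0])]
        with pytest.raises(KeyError, match="ghost_gene"):
            train_fold(
                folds[2], positives_bad, genes + ["ghost_gene"], emb,
                negatives_per_positive=5, seed=0,
            )

    def test_untrained_model_refuses_to_score(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            PairRanker().score_pairs(np.zeros((2, 8)), np.zeros(8))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            PairRanker().fit(np.zeros((4, 8)), np.array([0.0, 0.5, 1.0, 1.0]))

    def test_sklearn_param_interface(self):
        model = PairRanker(lr=0.01)
        assert model.get_params()["lr"] == 0.01
        model.set_params(dropout=0.5)
        assert model.dropout == 0.5


def test_no_test_disease_appears_in_training_pairs(planted):
    """Leakage guard: the fold protocol never trains on test diseases."""
    emb, positives, genes, diseases = planted
    for fold in make_folds(diseases, n_folds=3, seed=1):
        train_diseases = {d for _g, d in positives if d in set(fold.train) | set(fold.validation)}
        assert not train_diseases & set(fold.test)
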