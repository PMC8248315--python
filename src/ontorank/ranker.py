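"""Pointwise learning-to-rank model for (gene, disease) embedding pairs.

Two independent feed-forward towers transform the gene and the disease
embedding (hidden widths 256 then 50, each linear layer followed by 20%
dropout and a leaky-rectifier activation); the association score is the
sigmoid of the inner product of the tower outputs.  The model is trained
as a binary classifier with binary cross-entropy on known associations
(label 1) against sub-sampled unknown pairs (label 0, 20 negatives per
positive by default), optimized with Adam.

Cross-validation splits by *disease identity* — never by association
pair — so test diseases are wholly unseen during training: 10 folds,
each holding out 10% of diseases for testing, with the remaining
diseases split 90/10 into training and validation sets.  Epoch selection
uses validation loss (early stopping).

The forward/backward pass is written directly in numpy; all randomness
(weight init, dropout masks, batch order, negative sampling, fold
assignment) is seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .embedding import EmbeddingTable
from .evaluate import DiseaseRanking, RankingResult

logger = logging.getLogger(__name__)

DEFAULT_NEGATIVES_PER_POSITIVE = 20
DEFAULT_FOLDS = 10


# ---------------------------------------------------------------------------
# Protocol: folds and negative sampling


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold, split by disease identity."""

    fold: int
    test: tuple[str, ...]
    train: tuple[str, ...]
    validation: tuple[str, ...]

    def __post_init__(self) -> None:
        t, tr, v = set(self.test), set(self.train), set(self.validation)
        if t & tr or t & v or tr & v:
            raise ValueError("fold disease sets must be pairwise disjoint")


def make_folds(
    diseases: Sequence[str],
    n_folds: int = DEFAULT_FOLDS,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> list[FoldSplit]:
    """Partition diseases into ``n_folds`` disjoint test sets; within each
    fold the remaining diseases are split ~(1-val_fraction)/val_fraction
    into training and validation."""
    diseases = sorted(set(diseases))
    if len(diseases) < n_folds:
        raise ValueError(f"need >= {n_folds} diseases, got {len(diseases)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(diseases))
    test_sets = [list(chunk) for chunk in np.array_split(order, n_folds)]
    folds = []
    for i, test in enumerate(test_sets):
        rest = [d for d in order if d not in set(test)]
        rest = list(rng.permutation(rest))
        n_val = max(1, int(round(val_fraction * len(rest))))
        folds.append(
            FoldSplit(
                fold=i,
                test=tuple(test),
                train=tuple(rest[n_val:]),
                validation=tuple(rest[:n_val]),
            )
        )
    return folds


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    gene_universe: Sequence[str],
    k: int = DEFAULT_NEGATIVES_PER_POSITIVE,
    rng: np.random.Generator | int = 0,
) -> list[tuple[str, str]]:
    """Sub-sample unknown (gene, disease) pairs as negatives.

    For each positive pair of disease ``d``, ``k`` genes are drawn
    uniformly without replacement from the universe minus ``d``'s known
    positive genes, so negatives are distinct within a disease.
    """
    if k < 1:
        raise ValueError("negatives per positive must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    universe = sorted(set(gene_universe))
    by_disease: dict[str, list[str]] = {}
    for g, d in positives:
        by_disease.setdefault(d, []).append(g)
    out: list[tuple[str, str]] = []
    for d in sorted(by_disease):
        pos = set(by_disease[d])
        eligible = [g for g in universe if g not in pos]
        need = k * len(by_disease[d])
        if len(eligible) < need:
            raise ValueError(
                f"disease {d}: universe of {len(eligible)} eligible genes cannot "
                f"supply {need} distinct negatives"
            )
        drawn = rng.choice(len(eligible), size=need, replace=False)
        out.extend((eligible[int(i)], d) for i in drawn)
    return out


# ---------------------------------------------------------------------------
# The two-tower network


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


class _Tower:
    """Two-layer feed-forward transform with dropout and leaky ReLU."""

    def __init__(self, dim_in: int, hidden: tuple[int, int], slope: float, rng: np.random.Generator):
        h1, h2 = hidden
        self.slope = slope
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / dim_in), (dim_in, h1)),
            "b1": np.zeros(h1),
            "W2": rng.normal(0, np.sqrt(2.0 / h1), (h1, h2)),
            "b2": np.zeros(h2),
        }

    @classmethod
    def similarity_pair(
        cls,
        dim_in: int,
        hidden: tuple[int, int],
        slope: float,
        rng: np.random.Generator,
        scale: float,
        bias: float,
        b_proj: np.ndarray | None = None,
    ) -> tuple["_Tower", "_Tower"]:
        """Initialize two towers so their inner product starts as a
        calibrated bilinear similarity, ``scale * <P g, P d> + bias``.

        The first hidden layer stacks an orthonormal map M with its
        negation; because ``leaky(u) - leaky(-u) = (1 + slope) * u``, a
        second-layer weight of the form ``[N; -N]`` makes the tower an
        exactly linear map at initialization despite the activations.
        Output coordinate 0 is reserved for a constant bias pair
        (gene tower emits 1, disease tower emits ``bias``), giving the
        score head a well-calibrated operating point from the start;
        training is free to reshape all of it.

        ``b_proj`` (dim_in x k, k <= second hidden width - 1, orthonormal
        columns) selects the shared subspace the initial similarity is
        computed in; by default a random orthogonal projection is drawn,
        but callers pass the leading principal directions of the input
        embeddings so that the initial score preserves as much of the
        similarity structure as the output width allows.
        """
        h1, h2 = hidden
        half = h1 // 2
        if half < 1 or h2 < 2:
            raise ValueError("hidden widths too small for similarity initialization")
        if half >= dim_in:
            # orthonormal rows: m @ m.T = I_dim_in, so the map is exact
            m = np.linalg.qr(rng.normal(size=(half, dim_in)))[0].T
        else:
            # narrow tower: m @ m.T is an orthogonal projector instead
            m = np.linalg.qr(rng.normal(size=(dim_in, half)))[0]
        w1 = np.zeros((dim_in, h1))
        w1[:, :half] = m
        w1[:, half : 2 * half] = -m
        if b_proj is None:
            b_proj = np.linalg.qr(rng.normal(size=(dim_in, min(dim_in, h2 - 1))))[0]
        if b_proj.shape[0] != dim_in or b_proj.shape[1] > h2 - 1:
            raise ValueError("b_proj must be dim_in x k with k <= output width - 1")
        k = b_proj.shape[1]
        n = m.T @ b_proj * (np.sqrt(scale) / (1.0 + slope))  # half x k
        w2 = np.zeros((h1, h2))
        w2[:half, 1 : 1 + k] = n
        w2[half : 2 * half, 1 : 1 + k] = -n
        gene = cls.__new__(cls)
        gene.slope = slope
        gene.params = {"W1": w1, "b1": np.zeros(h1), "W2": w2, "b2": np.zeros(h2)}
        gene.params["b2"][0] = 1.0
        disease = cls.__new__(cls)
        disease.slope = slope
        disease.params = {k_: v.copy() for k_, v in gene.params.items()}
        # post-activation bias: invert the leaky slope for negative values
        disease.params["b2"][0] = bias if bias >= 0 else bias / slope
        return gene, disease

    def forward(self, x: np.ndarray, dropout: float, rng: np.random.Generator | None):
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        a1 = _leaky(z1, self.slope)
        if rng is not None and dropout > 0:
            m1 = (rng.random(a1.shape) >= dropout) / (1.0 - dropout)
        else:
            m1 = None
        d1 = a1 * m1 if m1 is not None else a1
        z2 = d1 @ p["W2"] + p["b2"]
        a2 = _leaky(z2, self.slope)
        if rng is not None and dropout > 0:
            m2 = (rng.random(a2.shape) >= dropout) / (1.0 - dropout)
        else:
            m2 = None
        out = a2 * m2 if m2 is not None else a2
        cache = (x, z1, d1, z2, m1, m2)
        return out, cache

    def backward(self, grad_out: np.ndarray, cache) -> dict[str, np.ndarray]:
        x, z1, d1, z2, m1, m2 = cache
        p = self.params
        if m2 is not None:
            grad_out = grad_out * m2
        dz2 = grad_out * _leaky_grad(z2, self.slope)
        grads = {
            "W2": d1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dd1 = dz2 @ p["W2"].T
        if m1 is not None:
            dd1 = dd1 * m1
        dz1 = dd1 * _leaky_grad(z1, self.slope)
        grads["W1"] = x.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PairRanker(ClassifierMixin, BaseEstimator):
    """Two-tower pointwise ranking model, scikit-learn estimator style.

    ``fit`` takes ``X`` of shape (n_samples, 2 * embedding_dim): each row
    is a gene embedding concatenated with a disease embedding, and ``y``
    the binary association label.  ``predict_proba`` returns association
    probabilities; the score head is sigma(<tower1(g), tower2(d)>), so the
    score is not symmetric in the two inputs.

    Parameters follow the reference architecture: hidden widths
    (256, 50), dropout 0.2, leaky-rectifier slope 0.01, Adam, binary
    cross-entropy loss, batch size 128, early stopping on validation
    loss with patience 10 within at most ``max_epochs`` epochs.

    With ``init="similarity"`` (default) the two towers share a
    similarity-preserving initialization: the composed linear map of
    both towers is the same orthogonal projection, and one output
    coordinate is reserved for a constant bias pair, so the score starts
    as a calibrated scaled inner product of the (unit-normalized) input
    embeddings.  This matters when known associations are scarce: a
    randomly initialized metric network of this capacity can reach the
    base-rate loss by memorizing the training diseases without ever
    discovering the embedding-similarity structure that generalizes to
    unseen diseases.  ``init="random"`` gives plain He initialization.
    ``normalize`` L2-normalizes each input embedding half.
    """

    def __init__(
        self,
        hidden: tuple[int, int] = (256, 50),
        dropout: float = 0.2,
        negative_slope: float = 0.01,
        lr: float = 1e-4,
        batch_size: int = 128,
        max_epochs: int = 200,
        patience: int = 10,
        init: str = "similarity",
        sim_scale: float = 10.0,
        sim_bias: float = -3.0,
        normalize: bool = True,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.dropout = dropout
        self.negative_slope = negative_slope
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.init = init
        self.sim_scale = sim_scale
        self.sim_bias = sim_bias
        self.normalize = normalize
        self.seed = seed

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _unit(x: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        return x / np.maximum(norms, 1e-12)

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if X.shape[1] != 2 * self.embedding_dim_:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected {2 * self.embedding_dim_}"
            )
        g, d = X[:, : self.embedding_dim_], X[:, self.embedding_dim_ :]
        if self.normalize:
            g, d = self._unit(g), self._unit(d)
        return g, d

    def _forward(self, Xg, Xd, rng=None):
        hg, cg = self.tower_gene_.forward(Xg, self.dropout, rng)
        hd, cd = self.tower_disease_.forward(Xd, self.dropout, rng)
        logits = np.sum(hg * hd, axis=1)
        probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
        return probs, (hg, hd, cg, cd)

    @staticmethod
    def _bce(probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

    def _loss(self, X: np.ndarray, y: np.ndarray) -> float:
        Xg, Xd = self._split(X)
        probs, _ = self._forward(Xg, Xd, rng=None)
        return self._bce(probs, y)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n_samples, 2 * embedding_dim)")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary")
        self.embedding_dim_ = X.shape[1] // 2
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0.0, 1.0])
        rng = np.random.default_rng(self.seed)
        if self.init == "similarity":
            # shared projection = leading principal directions of the
            # (unit-normalized) input embeddings, unsupervised
            Xg, Xd = self._split(X)
            stacked = np.vstack([Xg, Xd])
            _, _, vt = np.linalg.svd(stacked, full_matrices=False)
            k = min(self.hidden[1] - 1, vt.shape[0])
            self.tower_gene_, self.tower_disease_ = _Tower.similarity_pair(
                self.embedding_dim_, self.hidden, self.negative_slope, rng,
                self.sim_scale, self.sim_bias, b_proj=vt[:k].T,
            )
        elif self.init == "random":
            self.tower_gene_ = _Tower(self.embedding_dim_, self.hidden, self.negative_slope, rng)
            self.tower_disease_ = _Tower(self.embedding_dim_, self.hidden, self.negative_slope, rng)
        else:
            raise ValueError("init must be 'similarity' or 'random'")
        shapes = {f"g_{k}": v.shape for k, v in self.tower_gene_.params.items()}
        shapes.update({f"d_{k}": v.shape for k, v in self.tower_disease_.params.items()})
        adam = _Adam(shapes, self.lr)

        monitor_val = X_val is not None and y_val is not None
        if monitor_val:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).ravel()

        n = X.shape[0]
        # the freshly initialized model is itself an early-stopping
        # candidate: training must beat it on the monitored loss
        best_loss = self._loss(X_val, y_val) if monitor_val else self._loss(X, y)
        best_state = {
            "g": {k: v.copy() for k, v in self.tower_gene_.params.items()},
            "d": {k: v.copy() for k, v in self.tower_disease_.params.items()},
        }
        best_epoch = -1
        wait = 0
        history = {"train": [], "val": []}
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xg, Xd = self._split(X[idx])
                yb = y[idx]
                probs, (hg, hd, cg, cd) = self._forward(Xg, Xd, rng=rng)
                # d(BCE)/d(logit) = (p - y) / batch
                dlogit = (probs - yb) / len(yb)
                g_grads = self.tower_gene_.backward(dlogit[:, None] * hd, cg)
                d_grads = self.tower_disease_.backward(dlogit[:, None] * hg, cd)
                grads = {f"g_{k}": v for k, v in g_grads.items()}
                grads.update({f"d_{k}": v for k, v in d_grads.items()})
                params = {f"g_{k}": v for k, v in self.tower_gene_.params.items()}
                params.update({f"d_{k}": v for k, v in self.tower_disease_.params.items()})
                adam.step(params, grads)
            train_loss = self._loss(X, y)
            history["train"].append(train_loss)
            monitored = train_loss
            if monitor_val:
                val_loss = self._loss(X_val, y_val)
                history["val"].append(val_loss)
                monitored = val_loss
            if monitored < best_loss - 1e-9:
                best_loss = monitored
                best_epoch = epoch
                best_state = {
                    "g": {k: v.copy() for k, v in self.tower_gene_.params.items()},
                    "d": {k: v.copy() for k, v in self.tower_disease_.params.items()},
                }
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            self.tower_gene_.params = best_state["g"]
            self.tower_disease_.params = best_state["d"]
        self.best_epoch_ = best_epoch
        self.best_loss_ = float(best_loss)
        self.loss_history_ = history
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "tower_gene_")
        X = np.asarray(X, dtype=float)
        Xg, Xd = self._split(X)
        probs, _ = self._forward(Xg, Xd, rng=None)
        return probs

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(float)

    def score_pairs(self, gene_vectors: np.ndarray, disease_vector: np.ndarray) -> np.ndarray:
        """Score many genes against one disease; evaluation mode
        (dropout off), deterministic."""
        check_is_fitted(self, "tower_gene_")
        gene_vectors = np.atleast_2d(np.asarray(gene_vectors, dtype=float))
        disease = np.broadcast_to(
            np.asarray(disease_vector, dtype=float), gene_vectors.shape
        )
        if self.normalize:
            gene_vectors = self._unit(gene_vectors)
            disease = self._unit(disease)
        probs, _ = self._forward(gene_vectors, disease, rng=None)
        return probs


# ---------------------------------------------------------------------------
# Fold training and scoring on top of an embedding table


def _pairs_to_xy(
    pos: Sequence[tuple[str, str]],
    neg: Sequence[tuple[str, str]],
    embeddings: EmbeddingTable,
) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(pos) + list(neg)
    missing = sorted({e for g, d in pairs for e in (g, d) if e not in embeddings})
    if missing:
        raise KeyError(f"entities without embeddings: {missing}")
    genes = embeddings.lookup([g for g, _ in pairs])
    diseases = embeddings.lookup([d for _, d in pairs])
    X = np.hstack([genes, diseases])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return X, y


def train_fold(
    fold: FoldSplit,
    positives: Sequence[tuple[str, str]],
    gene_universe: Sequence[str],
    embeddings: EmbeddingTable,
    negatives_per_positive: int = DEFAULT_NEGATIVES_PER_POSITIVE,
    seed: int = 0,
    **ranker_params,
) -> tuple[PairRanker, RankingResult]:
    """Train on one fold and rank the whole gene universe for each test
    disease.  Negatives are drawn once, before training (seeded per fold).
    """
    test = set(fold.test)
    train_d = set(fold.train)
    val_d = set(fold.validation)
    assert not test & (train_d | val_d), "test diseases leaked into training"
    pos_train = [(g, d) for g, d in positives if d in train_d]
    pos_val = [(g, d) for g, d in positives if d in val_d]
    rng = np.random.default_rng([seed, fold.fold])
    neg_train = sample_negatives(pos_train, gene_universe, negatives_per_positive, rng)
    neg_val = sample_negatives(pos_val, gene_universe, negatives_per_positive, rng)
    X_tr, y_tr = _pairs_to_xy(pos_train, neg_train, embeddings)
    X_va, y_va = _pairs_to_xy(pos_val, neg_val, embeddings)
    model = PairRanker(seed=seed, **ranker_params)
    model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)

    universe = sorted(set(gene_universe))
    gene_matrix = embeddings.lookup(universe)
    by_disease: dict[str, set[str]] = {}
    for g, d in positives:
        by_disease.setdefault(d, set()).add(g)
    rankings = []
    for d in sorted(test):
        scores = model.score_pairs(gene_matrix, embeddings[d])
        rankings.append(
            DiseaseRanking.from_scores(
                d, universe, scores, sorted(by_disease.get(d, set()) & set(universe)), fold.fold
            )
        )
    return model, RankingResult(rankings)


def cross_validate(
    positives: Sequence[tuple[str, str]],
    gene_universe: Sequence[str],
    embeddings: EmbeddingTable,
    n_folds: int = DEFAULT_FOLDS,
    negatives_per_positive: int = DEFAULT_NEGATIVES_PER_POSITIVE,
    seed: int = 0,
    **ranker_params,
) -> tuple[list[PairRanker], RankingResult]:
    """Disease-wise k-fold cross-validation of the full protocol.

    Returns the per-fold models and the pooled test rankings (each
    disease appears exactly once, from the fold where it was held out).
    """
    diseases = sorted({d for _, d in positives})
    folds = make_folds(diseases, n_folds=n_folds, seed=seed)
    models: list[PairRanker] = []
    rankings: list[DiseaseRanking] = []
    for fold in folds:
        model, result = train_fold(
            fold,
            positives,
            gene_universe,
            embeddings,
            negatives_per_positive=negatives_per_positive,
            seed=seed,
            **ranker_params,
        )
        models.append(model)
        rankings.extend(result.rankings)
    return models, RankingResult(rankings)
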