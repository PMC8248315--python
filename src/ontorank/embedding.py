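"""Skip-gram embedding of walk corpora.

:class:`SkipGramEmbedder` is a scikit-learn-style estimator: ``fit`` on
an iterable of token sentences (a :class:`~ontorank.walks.WalkCorpus`),
``transform`` a list of tokens into their vectors.  Defaults match the
regime used for ontology-walk corpora: window 10, ``min_count`` 1,
20 epochs, 200-dimensional vectors, skip-gram with 5 negative samples.
Edge-label tokens are embedded alongside node tokens; downstream ranking
only consumes the node vectors.

Training is single-threaded and deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._sgns import _sgns_epochs, build_noise_table

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    """Token -> fixed-dimension real vector, with training metadata."""

    index: dict[str, int]
    vectors: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def __len__(self) -> int:
        return len(self.index)

    @property
    def tokens(self) -> list[str]:
        order = sorted(self.index, key=self.index.get)
        return order

    def lookup(self, ids: Sequence[str], missing: str = "error") -> np.ndarray:
        """Rows in input order.  ``missing`` is ``"error"`` (raise, listing
        the absent ids) or ``"drop"`` (omit with a warning)."""
        absent = [i for i in ids if i not in self.index]
        if absent:
            if missing == "error":
                raise KeyError(f"ids without embeddings: {absent}")
            if missing != "drop":
                raise ValueError(f"missing must be 'error' or 'drop', got {missing!r}")
            logger.warning("dropping %d id(s) without embeddings", len(absent))
            ids = [i for i in ids if i in self.index]
        rows = np.array([self.index[i] for i in ids], dtype=np.intp)
        return self.vectors[rows]

    def save_word2vec(self, path: str | Path) -> None:
        """word2vec text format: header ``vocab dim``, then token + floats."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.index)} {self.dim}\n")
            for token in self.tokens:
                vec = " ".join(f"{x:.6g}" for x in self.vectors[self.index[token]])
                fh.write(f"{token} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            index: dict[str, int] = {}
            vectors = np.empty((n, dim), dtype=np.float32)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                index[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(index=index, vectors=vectors)


def _corpus_fingerprint(counts: Counter) -> str:
    h = hashlib.sha1()
    for token, count in sorted(counts.items()):
        h.update(f"{token}\t{count}\n".encode())
    return h.hexdigest()[:16]


class SkipGramEmbedder(TransformerMixin, BaseEstimator):
    """Skip-gram-with-negative-sampling embedder for token sentences.

    Parameters
    ----------
    n_components : int, default=200
        Embedding dimension.
    window : int, default=10
        Maximum context window; per-position windows are uniformly
        reduced as in word2vec.
    min_count : int, default=1
        Minimum corpus frequency for a token to receive a vector.
    epochs : int, default=20
        Passes over the corpus.
    negative : int, default=5
        Negative samples per positive pair (unigram^0.75 noise).
    alpha, min_alpha : float
        Linearly decayed learning rate bounds.
    seed : int, default=0
        Controls initialization and sampling; fixed seed gives
        identical vectors across runs.

    Attributes
    ----------
    vocabulary_ : dict mapping token -> row index
    embeddings_ : ndarray of shape (n_tokens, n_components)
    counts_ : ndarray of token corpus frequencies
    embedding_table_ : EmbeddingTable view over the fitted vectors
    """

    def __init__(
        self,
        n_components: int = 200,
        window: int = 10,
        min_count: int = 1,
        epochs: int = 20,
        negative: int = 5,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed

    def fit(self, X: Iterable[Sequence[str]], y=None) -> "SkipGramEmbedder":
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        sentences = [list(s) for s in X]
        counts = Counter(tok for sent in sentences for tok in sent)
        if not counts:
            raise ValueError("cannot fit on an empty corpus")
        # frequency-descending order, ties broken lexicographically, so the
        # vocabulary layout (and hence training) is deterministic
        vocab = [t for t, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])) if c >= self.min_count]
        index = {t: i for i, t in enumerate(vocab)}
        count_arr = np.array([counts[t] for t in vocab], dtype=np.int64)

        flat: list[int] = []
        offsets = [0]
        for sent in sentences:
            flat.extend(index[t] for t in sent if t in index)
            offsets.append(len(flat))
        tokens = np.asarray(flat, dtype=np.int32)
        offs = np.asarray(offsets, dtype=np.int64)

        rng = np.random.default_rng(self.seed)
        dim = int(self.n_components)
        syn0 = ((rng.random((len(vocab), dim)) - 0.5) / dim).astype(np.float32)
        syn1 = np.zeros((len(vocab), dim), dtype=np.float32)
        noise = build_noise_table(count_arr)
        _sgns_epochs(
            tokens,
            offs,
            syn0,
            syn1,
            noise,
            int(self.window),
            int(self.negative),
            float(self.alpha),
            float(self.min_alpha),
            int(self.epochs),
            np.uint64(self.seed if self.seed >= 0 else -self.seed),
        )
        if not np.all(np.isfinite(syn0)):
            raise FloatingPointError("non-finite values in trained embeddings")
        self.vocabulary_ = index
        self.embeddings_ = syn0
        self.counts_ = count_arr
        self.embedding_table_ = EmbeddingTable(
            index=index,
            vectors=syn0,
            metadata={
                "config": self.get_params(),
                "corpus_fingerprint": _corpus_fingerprint(counts),
            },
        )
        return self

    def transform(self, tokens: Sequence[str], missing: str = "error") -> np.ndarray:
        check_is_fitted(self, "embeddings_")
        return self.embedding_table_.lookup(tokens, missing=missing)


def train_embeddings(corpus, **params) -> EmbeddingTable:
    """Functional wrapper: fit a :class:`SkipGramEmbedder` on ``corpus``
    and return its :class:`EmbeddingTable`."""
    return SkipGramEmbedder(**params).fit(corpus).embedding_table_
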