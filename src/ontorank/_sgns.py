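"""Numba kernel for skip-gram with negative sampling.

Single-threaded, fully deterministic for a fixed seed.  The layout
follows the classic word2vec training loop: for each token position, a
reduced context window is drawn, and for each context token the input
vector (``syn0`` row of the context token) is trained against the output
vector (``syn1`` row) of the center token plus ``negative`` draws from a
unigram^0.75 noise table, with a linearly decaying learning rate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LCG_MULT = np.uint64(25214903917)
_LCG_ADD = np.uint64(11)


@njit(cache=True, fastmath=True)
def _sgns_epochs(
    tokens,  # int32[:] token ids, all sentences concatenated
    offsets,  # int64[:] sentence boundaries, len = n_sentences + 1
    syn0,  # float32[:, :] input vectors (the embeddings)
    syn1,  # float32[:, :] output vectors
    noise_table,  # int32[:] unigram^0.75 sampling table
    window,  # int
    negative,  # int
    alpha0,  # float
    alpha_min,  # float
    epochs,  # int
    seed,  # uint64
):
    dim = syn0.shape[1]
    table_size = noise_table.shape[0]
    total = float(epochs) * float(tokens.shape[0])
    processed = 0.0
    grad = np.zeros(dim, dtype=np.float32)
    state = np.uint64(seed) * _LCG_MULT + _LCG_ADD
    for _epoch in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                alpha = alpha0 - (alpha0 - alpha_min) * (processed / total)
                if alpha < alpha_min:
                    alpha = alpha_min
                processed += 1.0
                center = tokens[i]
                state = state * _LCG_MULT + _LCG_ADD
                b = int((state >> np.uint64(16)) % np.uint64(window))
                lo = i - (window - b)
                hi = i + (window - b)
                if lo < start:
                    lo = start
                if hi > end - 1:
                    hi = end - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    ctx = tokens[j]
                    for d in range(dim):
                        grad[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = np.float32(1.0)
                        else:
                            state = state * _LCG_MULT + _LCG_ADD
                            target = noise_table[
                                int((state >> np.uint64(16)) % np.uint64(table_size))
                            ]
                            if target == center:
                                continue
                            label = np.float32(0.0)
                        f = np.float32(0.0)
                        for d in range(dim):
                            f += syn0[ctx, d] * syn1[target, d]
                        if f > 6.0:
                            sig = np.float32(1.0)
                        elif f < -6.0:
                            sig = np.float32(0.0)
                        else:
                            sig = np.float32(1.0) / (np.float32(1.0) + np.exp(-f))
                        g = (label - sig) * np.float32(alpha)
                        for d in range(dim):
                            grad[d] += g * syn1[target, d]
                        for d in range(dim):
                            syn1[target, d] += g * syn0[ctx, d]
                    for d in range(dim):
                        syn0[ctx, d] += grad[d]


def build_noise_table(counts: np.ndarray, ns_exponent: float = 0.75, size: int = 1_000_000) -> np.ndarray:
    """Unigram**ns_exponent sampling table of token indices."""
    weights = counts.astype(np.float64) ** ns_exponent
    cum = np.cumsum(weights / weights.sum())
    grid = (np.arange(size) + 0.5) / size
    return np.searchsorted(cum, grid).astype(np.int32)
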