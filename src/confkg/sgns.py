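"""Skip-gram negative-sampling (SGNS) training on walk corpora.

A minibatch-SGD implementation in vectorized numpy.  For each (center,
context) pair within a dynamically reduced window, the input vector of the
center token is trained to score its true context above k noise tokens drawn
from the unigram^0.75 distribution:

    loss = -log sigma(u_o . v_c) - sum_k log sigma(-u_nk . v_c)

The input matrix is returned as the embedding table.  Training is fully
deterministic given the seed (single stream, fixed batch order), and the
vocabulary is ordered by (frequency, first occurrence) so a pure relabeling of
tokens reproduces the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingTable
from .walker import WalkCorpus

__all__ = ["SGNSParams", "train_sgns"]


@dataclass(frozen=True)
class SGNSParams:
    """Skip-gram hyperparameters.

    ``alpha`` is the initial learning rate, decayed linearly to ``min_alpha``
    over training.  ``window`` is the maximum one-sided context distance; the
    effective window of each center token is drawn uniformly from 1..window,
    the standard distance-discounting trick.  ``min_count`` defaults to 0 so
    that every graph vertex appearing in the corpus receives an embedding.
    """

    dimension: int = 256
    window: int = 4
    alpha: float = 0.025
    negative_samples: int = 5
    epochs: int = 5
    min_count: int = 0
    seed: int = 0
    batch_size: int = 512
    min_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negative_samples < 0:
            raise ValueError("negative_samples must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _build_vocab(
    corpus: WalkCorpus, min_count: int
) -> tuple[list[str], dict[str, int]]:
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    pos = 0
    for seq in corpus.sequences:
        for tok in seq:
            counts[tok] = counts.get(tok, 0) + 1
            if tok not in first_seen:
                first_seen[tok] = pos
            pos += 1
    tokens = [t for t, c in counts.items() if c >= max(min_count, 1)]
    # frequency-major order with first-occurrence tie-break: invariant under
    # token relabeling, which keeps training relabel-equivariant
    tokens.sort(key=lambda t: (-counts[t], first_seen[t]))
    return tokens, counts


def _skipgram_pairs(
    encoded: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs for one epoch, with dynamic windows."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for arr in encoded:
        n = arr.size
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)
        for d in range(1, window + 1):
            fwd = np.nonzero(b[: n - d] >= d)[0]
            if fwd.size:
                centers.append(arr[fwd])
                contexts.append(arr[fwd + d])
            bwd = np.nonzero(b[d:] >= d)[0] + d
            if bwd.size:
                centers.append(arr[bwd])
                contexts.append(arr[bwd - d])
    if not centers:
        raise ValueError("corpus has no token pairs within the window")
    return np.concatenate(centers), np.concatenate(contexts)


def train_sgns(corpus: WalkCorpus, params: SGNSParams = SGNSParams()) -> EmbeddingTable:
    """Train SGNS embeddings from a walk corpus.

    Returns one vector per retained token (input matrix), not L2-normalized;
    apply :func:`confkg.embeddings.l2_normalize` for unit-norm output.
    Reproducible bit-for-bit given the seed.
    """
    if not corpus.sequences:
        raise ValueError("cannot train on an empty corpus")
    tokens, counts = _build_vocab(corpus, params.min_count)
    if not tokens:
        raise ValueError("vocabulary is empty after applying min_count")
    index = {t: i for i, t in enumerate(tokens)}
    vocab_size = len(tokens)
    dim = params.dimension

    encoded = []
    for seq in corpus.sequences:
        ids = [index[t] for t in seq if t in index]
        if ids:
            encoded.append(np.asarray(ids, dtype=np.int64))

    # unigram^0.75 noise distribution over the vocabulary
    freq = np.array([counts[t] for t in tokens], dtype=np.float64) ** 0.75
    noise_cum = np.cumsum(freq / freq.sum())

    rng = np.random.default_rng(int(params.seed) % (2**31))
    w_in = (rng.random((vocab_size, dim)) - 0.5) / dim
    w_out = np.zeros((vocab_size, dim))

    k = params.negative_samples
    batch = params.batch_size
    # one epoch's pair count is window-draw dependent; estimate total batches
    # for the linear learning-rate schedule from the first epoch's pairs
    total_steps = None
    step = 0
    for _ in range(params.epochs):
        c, o = _skipgram_pairs(encoded, params.window, rng)
        perm = rng.permutation(c.size)
        c, o = c[perm], o[perm]
        n_batches = (c.size + batch - 1) // batch
        if total_steps is None:
            total_steps = n_batches * params.epochs
        for bi in range(n_batches):
            lr = params.alpha + (params.min_alpha - params.alpha) * min(
                step / max(total_steps - 1, 1), 1.0
            )
            step += 1
            cb = c[bi * batch : (bi + 1) * batch]
            ob = o[bi * batch : (bi + 1) * batch]
            m = cb.size
            if k > 0:
                neg = np.searchsorted(noise_cum, rng.random((m, k)))
                targets = np.concatenate([ob[:, None], neg], axis=1)
            else:
                targets = ob[:, None]
            labels = np.zeros((m, targets.shape[1]))
            labels[:, 0] = 1.0

            v = w_in[cb]                                # (m, dim)
            u = w_out[targets]                          # (m, 1+k, dim)
            s = 1.0 / (1.0 + np.exp(-np.einsum("mkd,md->mk", u, v)))
            g = s - labels                              # (m, 1+k)
            grad_v = np.einsum("mk,mkd->md", g, u)
            grad_u = g[:, :, None] * v[:, None, :]
            np.add.at(w_in, cb, -lr * grad_v)
            np.add.at(
                w_out, targets.ravel(), -lr * grad_u.reshape(-1, dim)
            )
    return EmbeddingTable(tokens, w_in, normalized=False)
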