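"""Compact skip-gram word-embedding trainer with negative sampling (SGNS).

Plain numpy SGD implementation of the skip-gram objective: for each (center,
context) pair within the window, the center vector is pushed toward the
context output vector and away from ``negative`` sampled noise words drawn
from the unigram^(3/4) distribution. Deliberately small and deterministic;
intended for the modest corpus sizes this package works with.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

__all__ = ["train_skipgram"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    docs,
    dimension: int = 100,
    window: int = 6,
    negative: int = 5,
    epochs: int = 5,
    min_count: int = 1,
    lr: float = 0.025,
    seed: int = 0,
):
    """Train embeddings; returns ``(vocab, vectors)``.

    ``vocab`` maps token -> row index into ``vectors`` (the input/center
    matrix, shape ``(V, dimension)``). Learning rate decays linearly over all
    center positions; the RNG (negative draws, init) is fully seeded.
    """
    counts = Counter(t for doc in docs for t in doc)
    vocab = {
        t: i
        for i, (t, c) in enumerate(sorted(counts.items()))
        if c >= min_count
    }
    vocab = {t: i for i, t in enumerate(sorted(vocab))}  # compact, sorted ids
    V = len(vocab)
    rng = np.random.default_rng(seed)
    if V == 0:
        return vocab, np.zeros((0, dimension))
    freq = np.array([counts[t] for t in sorted(vocab)], dtype=float)
    noise = freq**0.75
    noise /= noise.sum()
    w_in = (rng.random((V, dimension)) - 0.5) / dimension
    w_out = np.zeros((V, dimension))

    encoded = [[vocab[t] for t in doc if t in vocab] for doc in docs]
    total = max(1, epochs * sum(len(d) for d in encoded))
    step = 0
    for _ in range(epochs):
        for doc in encoded:
            n = len(doc)
            for i in range(n):
                alpha = max(1e-4, lr * (1.0 - step / total))
                step += 1
                center = doc[i]
                lo, hi = max(0, i - window), min(n, i + window + 1)
                ctx = [doc[j] for j in range(lo, hi) if j != i]
                if not ctx:
                    continue
                for c in ctx:
                    targets = np.empty(1 + negative, dtype=int)
                    targets[0] = c
                    if negative:
                        targets[1:] = rng.choice(V, size=negative, p=noise)
                    labels = np.zeros(1 + negative)
                    labels[0] = 1.0
                    v = w_in[center]
                    u = w_out[targets]
                    g = (_sigmoid(u @ v) - labels) * alpha
                    w_in[center] = v - g @ u
                    w_out[targets] -= np.outer(g, v)
    return vocab, w_in
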