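"""Comparison vectorizations: n-gram counts with IDF, and skip-gram document embeddings.

These are the two standard document representations the positional method is
benchmarked against. They operate on the same normalized token sequences, so
all methods see identical preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

from ._skipgram import train_skipgram

__all__ = [
    "NGramConfig",
    "EmbeddingConfig",
    "NGRAM_RANGE_GRID",
    "ngram_matrix",
    "idf_transform",
    "embed_documents",
]

#: n-gram ranges used in the benchmark grid.
NGRAM_RANGE_GRID = ((1, 2), (2, 2), (1, 3), (2, 3), (3, 3))


@dataclass(frozen=True)
class NGramConfig:
    range: tuple = (1, 2)
    idf: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not (1 <= lo <= hi):
            raise ValueError("require 1 <= min_n <= max_n")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Skip-gram settings; defaults: 100-dim vectors, window 6, 5 negatives."""

    dimension: int = 100
    window: int = 6
    negative_samples: int = 5
    epochs: int = 5
    min_count: int = 1
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.window < 1 or self.negative_samples < 0:
            raise ValueError("invalid embedding configuration")
        if self.aggregation != "mean":
            raise ValueError("only mean aggregation is supported")


def _token_lists(corpus) -> list:
    return [list(getattr(seq, "tokens", seq)) for seq in corpus]


def ngram_matrix(corpus, config: NGramConfig = NGramConfig()):
    """Document-term count matrix of contiguous token n-grams.

    Returns ``(counts, vocabulary)`` with the vocabulary in lexicographic
    order (n-gram tokens joined by spaces); counts is a sparse CSR matrix.
    """
    docs = _token_lists(corpus)
    if not docs:
        raise ValueError("empty corpus")
    lo, hi = config.range

    def analyzer(tokens):
        grams = []
        for n in range(lo, hi + 1):
            grams.extend(
                " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
            )
        return grams

    vec = CountVectorizer(analyzer=analyzer)
    try:
        counts = vec.fit_transform(docs)
    except ValueError as err:  # no n-gram anywhere (all blocks too short)
        raise ValueError("corpus yields an empty n-gram vocabulary") from err
    return counts, list(vec.get_feature_names_out())


def idf_transform(counts):
    """Smoothed inverse-document-frequency weighting, ln((1+N)/(1+df)) + 1.

    No length normalization; a term present in every document receives the
    floor weight 1. Deterministic in the document frequencies.
    """
    return TfidfTransformer(norm=None, smooth_idf=True, sublinear_tf=False).fit_transform(
        counts
    )


def embed_documents(
    corpus, config: EmbeddingConfig = EmbeddingConfig(), seed: int = 0
) -> np.ndarray:
    """Mean-pooled skip-gram document features, shape (m, dimension).

    Trains skip-gram embeddings with negative sampling on the corpus itself,
    then represents each document as the unweighted mean of its in-vocabulary
    token vectors; documents with no in-vocabulary token get a zero row.
    Seeded and single-threaded, hence run-to-run reproducible.
    """
    docs = _token_lists(corpus)
    if not docs:
        raise ValueError("empty corpus")
    vocab, vectors = train_skipgram(
        docs,
        dimension=config.dimension,
        window=config.window,
        negative=config.negative_samples,
        epochs=config.epochs,
        min_count=config.min_count,
        seed=seed,
    )
    out = np.zeros((len(docs), config.dimension))
    for i, doc in enumerate(docs):
        idx = [vocab[t] for t in doc if t in vocab]
        if idx:
            out[i] = vectors[idx].mean(axis=0)
    return out
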