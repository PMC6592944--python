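"""End-to-end convenience wrappers: corpus -> normalized tokens -> features."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import NGramConfig, idf_transform, ngram_matrix
from .core import RWOVMatrix, vectorize_corpus
from .normalize import NormalizationConfig, normalize_block
from .vocab import RelevantWordIndex, TOISpec, default_toi, select_relevant_words

__all__ = ["normalize_corpus", "rwov_features", "ngram_features"]


def normalize_corpus(corpus, config: NormalizationConfig = NormalizationConfig()):
    """Normalize a corpus into a list of TokenSequences.

    Accepts a DataFrame with ``observation_id``/``text`` columns, a list of
    objects with those attributes (e.g. synthetic LabelledReports), or a list
    of ``(observation_id, text)`` pairs.
    """
    if isinstance(corpus, pd.DataFrame):
        pairs = zip(corpus["observation_id"].astype(str), corpus["text"].astype(str))
    elif corpus and hasattr(corpus[0], "text"):
        pairs = ((r.observation_id, r.text) for r in corpus)
    else:
        pairs = corpus
    return [normalize_block(text, config, observation_id=oid) for oid, text in pairs]


def rwov_features(
    sequences,
    toi,
    k: int = 30,
    config: NormalizationConfig = NormalizationConfig(),
):
    """Relevant-word index plus RWOV matrix for an already-normalized corpus.

    ``toi`` may be a built-in TOI name ("er", "pr", "her2") or a TOISpec.
    Returns ``(matrix, index)``.
    """
    spec = default_toi(toi, config) if isinstance(toi, str) else toi
    index = select_relevant_words(sequences, spec, k=k)
    matrix = vectorize_corpus(sequences, spec, index)
    return matrix, index


def ngram_features(sequences, config: NGramConfig = NGramConfig()):
    """Dense (optionally IDF-weighted) n-gram matrix plus vocabulary."""
    counts, vocabulary = ngram_matrix(sequences, config)
    if config.idf:
        counts = idf_transform(counts)
    return np.asarray(counts.todense()), vocabulary
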