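"""Relevant Word Order Vectorization.

Each observation (block) becomes a row over the k relevant words. The cell
for word j is 0 if j does not occur in the block, otherwise the signed
reciprocal 1/(d+1) where d is the number of relevant-word occurrences
strictly between j's chosen occurrence and the TOI anchor; the sign encodes
whether j lies before (negative) or after (positive) the anchor. Values hence
decay nonlinearly from +-1 (adjacent to the TOI) toward 0 (absent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import TokenSequence
from .vocab import RelevantWordIndex, TOISpec, find_toi_occurrences

__all__ = ["Side", "RWOVMatrix", "signed_reciprocal_value", "vectorize_block", "vectorize_corpus"]


class Side(enum.Enum):
    BEFORE = "before"
    AFTER = "after"


def signed_reciprocal_value(d: int, side: Side) -> float:
    """Signed 1/(d+1): negative before the TOI, positive after."""
    if d < 0:
        raise ValueError("d must be a nonnegative integer")
    value = 1.0 / (d + 1)
    return -value if side is Side.BEFORE else value


def vectorize_block(
    seq: TokenSequence, anchors, index: RelevantWordIndex
) -> np.ndarray:
    """RWOV row for one block.

    The anchor is the first TOI occurrence. For each column word, the
    occurrence minimizing the between-count d is chosen (ties between an
    equal-d occurrence before and after the anchor resolve to AFTER); blocks
    without the TOI, or without any relevant word, give an all-zero row.
    """
    columns = index.tokens
    row = np.zeros(len(columns))
    anchors = list(anchors)
    if not anchors:
        return row
    anchor = anchors[0]
    tokens = seq.tokens
    relevant = set(columns)
    # prefix[i] = number of relevant-word occurrences among tokens[:i]
    prefix = np.zeros(len(tokens) + 1, dtype=int)
    for i, tok in enumerate(tokens):
        prefix[i + 1] = prefix[i] + (tok in relevant)
    positions: dict = {}
    for p, tok in enumerate(tokens):
        if tok in relevant and p != anchor:
            positions.setdefault(tok, []).append(p)
    for col, word in enumerate(columns):
        best = None
        for p in positions.get(word, ()):
            if p < anchor:
                d = int(prefix[anchor] - prefix[p + 1])
                key = (d, 1)  # BEFORE loses equal-d ties
                side = Side.BEFORE
            else:
                d = int(prefix[p] - prefix[anchor + 1])
                key = (d, 0)
                side = Side.AFTER
            if best is None or key < best[0]:
                best = (key, d, side)
        if best is not None:
            row[col] = signed_reciprocal_value(best[1], best[2])
    return row


def vectorize_corpus(corpus, toi: TOISpec, index: RelevantWordIndex) -> "RWOVMatrix":
    """Stack :func:`vectorize_block` rows for a corpus (rows independent)."""
    corpus = list(corpus)
    ids = [seq.observation_id for seq in corpus]
    values = np.zeros((len(corpus), len(index.tokens)))
    for i, seq in enumerate(corpus):
        anchors = find_toi_occurrences(seq, toi)
        values[i] = vectorize_block(seq, anchors, index)
    return RWOVMatrix(observation_ids=ids, columns=list(index.tokens), values=values)


@dataclass
class RWOVMatrix:
    """m x k matrix of signed reciprocal-distance values in [-1, 1]."""

    observation_ids: list
    columns: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.observation_ids), len(self.columns)):
            raise ValueError("values shape must be (m, k)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.observation_ids, name="observation_id"),
            columns=self.columns,
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RWOVMatrix":
        df = pd.read_csv(path_or_buf, index_col="observation_id")
        return cls(
            observation_ids=[str(i) for i in df.index],
            columns=list(df.columns),
            values=df.to_numpy(),
        )
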