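"""Text normalization for free-text clinical report blocks.

A report block is turned into one ordered stream of normalized tokens:
sentence split, word/symbol tokenization, case folding, stop-word removal,
symbol substitution ("," -> "comm", "/" -> "slash", "+" -> "plu"), collapsing
of polarity-qualified percentages ("Positive (85%)" -> ... "pospct" ...), and
suffix-stripping stemming. Sentence boundaries do not reset token positions:
the positional vectorization downstream operates on the whole block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from ._porter import porter_stem

__all__ = [
    "DEFAULT_STOP_WORDS",
    "DEFAULT_SUBSTITUTIONS",
    "NormalizationConfig",
    "TokenSequence",
    "split_sentences",
    "tokenize",
    "normalize_token",
    "normalize_block",
]

#: Stop words excluded from every token stream.
DEFAULT_STOP_WORDS = frozenset(
    {"the", "are", "of", "as", "is", "and", "or", "report", "pathology"}
)

#: Ordered surface-pattern -> identifier substitutions (first match wins).
DEFAULT_SUBSTITUTIONS = ((",", "comm"), ("/", "slash"), ("+", "plu"))

_STEMMERS = {"porter": porter_stem, "none": lambda w: w}

# alphanumeric runs (keeping internal hyphens: "ki-67", "her-2"), else any
# single non-space symbol
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*|[^\sA-Za-z0-9]")
_SENT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9\(])")
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")
_ALPHA_RE = re.compile(r"^[a-z]+$")


@dataclass(frozen=True)
class NormalizationConfig:
    """Settings for :func:`normalize_block`.

    ``percent_window`` is the maximum number of tokens between a polarity word
    ("positive"/"negative") and a following percentage for the percentage to be
    collapsed into the ``pospct``/``negpct`` identifier.
    """

    stop_words: frozenset = DEFAULT_STOP_WORDS
    substitutions: tuple = DEFAULT_SUBSTITUTIONS
    stemmer: str = "porter"
    lowercase: bool = True
    collapse_percent: bool = True
    percent_window: int = 3

    def __post_init__(self) -> None:
        if self.stemmer not in _STEMMERS:
            raise ValueError(
                f"unknown stemmer {self.stemmer!r}; choose from {sorted(_STEMMERS)}"
            )

    @property
    def stem(self):
        return _STEMMERS[self.stemmer]

    @classmethod
    def from_yaml(cls, path) -> "NormalizationConfig":
        """Load from a key-value YAML file (stop_words list, substitutions
        as ordered [pattern, identifier] pairs, stemmer, flags)."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "stop_words" in data:
            kwargs["stop_words"] = frozenset(str(w).lower() for w in data["stop_words"])
        if "substitutions" in data:
            kwargs["substitutions"] = tuple(
                (str(p), str(i)) for p, i in data["substitutions"]
            )
        for key in ("stemmer", "lowercase", "collapse_percent", "percent_window"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "stop_words": sorted(self.stop_words),
            "substitutions": [list(pair) for pair in self.substitutions],
            "stemmer": self.stemmer,
            "lowercase": self.lowercase,
            "collapse_percent": self.collapse_percent,
            "percent_window": self.percent_window,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class TokenSequence:
    """One observation's ordered, normalized tokens.

    ``source_positions[i]`` is the 0-based index of ``tokens[i]`` in the
    pre-filter (raw) token stream of the whole block; it is strictly
    increasing. The sequence may be empty for degenerate input.
    """

    observation_id: str
    tokens: tuple = ()
    source_positions: tuple = ()

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.source_positions):
            raise ValueError("tokens and source_positions must align")
        if any(
            b <= a for a, b in zip(self.source_positions, self.source_positions[1:])
        ):
            raise ValueError("source_positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)


def split_sentences(text: str) -> list:
    """Split raw text into sentences.

    Rule-based: a boundary is terminal punctuation followed by whitespace and
    an uppercase letter, digit or opening parenthesis. Total function; the
    concatenation of the result covers all non-whitespace content in order.
    """
    if not text or not text.strip():
        return []
    return [s for s in _SENT_RE.split(text) if s.strip()]


def tokenize(sentence: str) -> list:
    """Break a sentence into words or symbols.

    Alphanumeric runs (with internal hyphens, so "Ki-67" and "HER-2" survive
    intact) become word tokens; every other non-space character becomes its
    own symbol token.
    """
    return _TOKEN_RE.findall(sentence)


def normalize_token(token: str, config: NormalizationConfig = NormalizationConfig()) -> Optional[str]:
    """Normalize one raw token; ``None`` marks a dropped (stop-word) token."""
    low = token.lower() if config.lowercase else token
    if low in config.stop_words:
        return None
    for pattern, ident in config.substitutions:
        if low == pattern:
            return ident
    if _ALPHA_RE.match(low):
        return config.stem(low)
    return low  # numbers, mixed tokens ("her2", "ki-67") and bare symbols


def _polarity(raw: str) -> Optional[str]:
    low = raw.lower()
    if low.startswith("posit") or low == "pos":
        return "pospct"
    if low.startswith("negat") or low == "neg":
        return "negpct"
    return None


def normalize_block(
    text: str,
    config: NormalizationConfig = NormalizationConfig(),
    observation_id: str = "",
) -> TokenSequence:
    """Normalize a whole report block into a :class:`TokenSequence`.

    Composition of :func:`split_sentences`, :func:`tokenize` and
    :func:`normalize_token`, with dropped tokens removed and raw-stream
    positions recorded. A percentage within ``percent_window`` tokens after a
    polarity word (same sentence) collapses to ``pospct``/``negpct``, taking
    the position of its number token.
    """
    out_tokens: list = []
    out_pos: list = []
    offset = 0  # raw-stream position of the current sentence's first token
    for sentence in split_sentences(text):
        raws = tokenize(sentence)
        # (raw_or_identifier, local_index, is_identifier)
        items: list = []
        i = 0
        while i < len(raws):
            if (
                config.collapse_percent
                and i + 1 < len(raws)
                and raws[i + 1] == "%"
                and _NUMBER_RE.match(raws[i])
            ):
                ident = None
                for j in range(max(0, i - config.percent_window), i):
                    ident = _polarity(raws[j]) or ident
                if ident is not None:
                    items.append((ident, i, True))
                    i += 2  # the "%" is consumed with its number
                    continue
            items.append((raws[i], i, False))
            i += 1
        for raw, local, is_ident in items:
            norm = raw if is_ident else normalize_token(raw, config)
            if norm is not None:
                out_tokens.append(norm)
                out_pos.append(offset + local)
        offset += len(raws)
    return TokenSequence(
        observation_id=observation_id,
        tokens=tuple(out_tokens),
        source_positions=tuple(out_pos),
    )
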