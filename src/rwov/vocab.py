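"""Term-of-interest resolution and relevant-word selection.

The term of interest (TOI) is the anchor concept a block is classified for
(e.g. "er" for estrogen-receptor status). Occurrences are matched in
normalized token space, including multi-token aliases ("estrogen receptor").
The *relevant words* for a TOI are the k tokens that co-occur most frequently
with it across the corpus, ranked by mean frequency per observation.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

from .normalize import NormalizationConfig, TokenSequence, normalize_block

__all__ = [
    "TOISpec",
    "RelevantWordIndex",
    "default_toi",
    "DEFAULT_TOI_ALIASES",
    "find_toi_occurrences",
    "select_relevant_words",
]

#: Raw alias phrases for the three breast-cancer receptor TOIs.
DEFAULT_TOI_ALIASES = {
    "er": ("estrogen", "estrogen receptor"),
    "pr": ("progesterone receptor",),
    "her2": ("her-2", "her/"),
}


@dataclass(frozen=True)
class TOISpec:
    """A TOI: canonical token plus alias token-tuples, all normalized.

    ``aliases`` are tuples of normalized tokens (a phrase like "her/" becomes
    ``("her", "slash")`` after symbol substitution); use :meth:`compile` to
    build a spec from raw phrases with the corpus-wide normalization config.
    """

    canonical: str
    aliases: tuple = ()

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical TOI token must be nonempty")

    @classmethod
    def compile(
        cls,
        canonical: str,
        alias_phrases=(),
        config: NormalizationConfig = NormalizationConfig(),
    ) -> "TOISpec":
        aliases = []
        for phrase in alias_phrases:
            toks = normalize_block(phrase, config).tokens
            if toks and toks not in aliases and toks != (canonical,):
                aliases.append(toks)
        return cls(canonical=canonical, aliases=tuple(aliases))

    @property
    def patterns(self) -> tuple:
        """All match patterns, longest first (longest match wins)."""
        pats = [(self.canonical,), *self.aliases]
        return tuple(sorted(set(pats), key=lambda p: (-len(p), p)))


def default_toi(
    name: str, config: NormalizationConfig = NormalizationConfig()
) -> TOISpec:
    """Compiled spec for one of the built-in TOIs ("er", "pr", "her2")."""
    if name not in DEFAULT_TOI_ALIASES:
        raise KeyError(f"no default TOI named {name!r}")
    return TOISpec.compile(name, DEFAULT_TOI_ALIASES[name], config)


def _toi_matches(tokens, toi: TOISpec) -> list:
    """Non-overlapping (start, length) TOI matches, longest match first."""
    patterns = toi.patterns
    matches = []
    i, n = 0, len(tokens)
    while i < n:
        hit = None
        for pat in patterns:
            if tuple(tokens[i : i + len(pat)]) == pat:
                hit = len(pat)
                break
        if hit is not None:
            matches.append((i, hit))
            i += hit
        else:
            i += 1
    return matches


def find_toi_occurrences(seq: TokenSequence, toi: TOISpec) -> list:
    """0-based token indices where the TOI (canonical or alias) begins.

    Multi-token aliases report the index of their first token; overlapping
    matches are deduplicated with the longest match winning.
    """
    return [start for start, _ in _toi_matches(seq.tokens, toi)]


@dataclass(frozen=True)
class RelevantWordIndex:
    """Ranked top-k relevant words for a TOI.

    ``words`` is a tuple of ``(token, mean_frequency_per_observation)`` sorted
    by descending frequency, ties broken lexicographically; the mean divides
    raw counts (within TOI-containing blocks) by the total number of
    observations m.
    """

    toi: TOISpec
    words: tuple
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.words) > self.k:
            raise ValueError("more words than k")
        freqs = [f for _, f in self.words]
        if any(f < 0 for f in freqs):
            raise ValueError("frequencies must be nonnegative")
        if any(b > a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("words must be sorted by descending frequency")

    @property
    def tokens(self) -> tuple:
        return tuple(t for t, _ in self.words)

    def to_csv(self, path_or_buf) -> None:
        """Two-column file (token, mean_frequency); header names TOI and k."""
        buf = io.StringIO()
        buf.write(f"# toi={self.toi.canonical}\tk={self.k}\n")
        aliases = ";".join(" ".join(a) for a in self.toi.aliases)
        buf.write(f"# aliases={aliases}\n")
        buf.write("token\tmean_frequency\n")
        for tok, freq in self.words:
            buf.write(f"{tok}\t{freq!r}\n")
        data = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(data)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(data)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RelevantWordIndex":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        head = dict(
            kv.split("=", 1)
            for line in lines[:2]
            for kv in line.lstrip("# ").split("\t")
        )
        aliases = tuple(
            tuple(a.split(" ")) for a in head.get("aliases", "").split(";") if a
        )
        toi = TOISpec(canonical=head["toi"], aliases=aliases)
        words = []
        for line in lines[3:]:
            if not line.strip():
                continue
            tok, freq = line.split("\t")
            words.append((tok, float(freq)))
        return cls(toi=toi, words=tuple(words), k=int(head["k"]))


def select_relevant_words(corpus, toi: TOISpec, k: int = 30) -> RelevantWordIndex:
    """Top-k words co-occurring with the TOI across the corpus.

    Every token occurrence inside a block containing at least one TOI match is
    counted, excluding positions covered by the matches themselves; each TOI
    match after the first in a block counts as one occurrence of the canonical
    token (repeated TOI mentions are themselves informative). Mean frequency
    divides by the total number of observations ``m``. Ties at equal frequency
    break lexicographically. ``k=30`` is the method's default vocabulary size.

    Raises ``ValueError`` if no block contains the TOI.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be nonempty")
    m = len(corpus)
    counts: Counter = Counter()
    seen_toi = False
    for seq in corpus:
        matches = _toi_matches(seq.tokens, toi)
        if not matches:
            continue
        seen_toi = True
        covered = {
            idx for start, length in matches for idx in range(start, start + length)
        }
        for idx, tok in enumerate(seq.tokens):
            if idx not in covered:
                counts[tok] += 1
        counts[toi.canonical] += len(matches) - 1
    if not seen_toi:
        raise ValueError(
            f"TOI {toi.canonical!r} does not occur in any block of the corpus"
        )
    counts = +counts  # drop zero entries (canonical with a single match)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    words = tuple((tok, cnt / m) for tok, cnt in ranked)
    return RelevantWordIndex(toi=toi, words=words, k=k)
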