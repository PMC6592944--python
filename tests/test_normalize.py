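"""Normalization: sentence split, word/symbol tokens, stop words, substitutions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwov import (
    DEFAULT_STOP_WORDS,
    NormalizationConfig,
    normalize_block,
    normalize_token,
    split_sentences,
    tokenize,
)
from rwov._porter import porter_stem


class TestSplitSentences:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("", []),
            ("   ", []),
            ("ER: Positive (85%) PR: Positive (80%).",
             ["ER: Positive (85%) PR: Positive (80%)."]),
            ("Positive for ER. Negative for PR.",
             ["Positive for ER.", "Negative for PR."]),
            ("No terminal punctuation here", ["No terminal punctuation here"]),
        ],
    )
    def test_examples(self, text, expected):
        assert split_sentences(text) == expected

    @given(st.text(alphabet=" .ABCdef123!?", max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_covers_all_content(self, text):
        joined = "".join(split_sentences(text))
        assert joined.replace(" ", "") .replace("\t", "") == \
            text.strip().replace(" ", "").replace("\t", "") or not text.strip()


class TestTokenize:
    @pytest.mark.parametrize(
        "sentence,expected",
        [
            ("ER+", ["ER", "+"]),
            ("HER2/neu", ["HER2", "/", "neu"]),
            ("Ki-67: 23%", ["Ki-67", ":", "23", "%"]),
            ("positive for ER, negative for PR",
             ["positive", "for", "ER", ",", "negative", "for", "PR"]),
            ("(85%)", ["(", "85", "%", ")"]),
            ("", []),
        ],
    )
    def test_words_and_symbols(self, sentence, expected):
        assert tokenize(sentence) == expected


class TestNormalizeToken:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (",", "comm"),
            ("/", "slash"),
            ("+", "plu"),
            ("the", None),
            ("Pathology", None),
            ("1", "1"),
            ("23", "23"),
            ("her2", "her2"),
            ("Ki-67", "ki-67"),
            ("positive", "posit"),
            ("negative", "neg"),
            ("received", "receiv"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_token(raw) == expected

    @pytest.mark.parametrize(
        "word,stem",
        [
            ("caresses", "caress"),
            ("ponies", "poni"),
            ("motoring", "motor"),
            ("happy", "happi"),
            ("relational", "relat"),
            ("conditional", "condit"),
            ("agreed", "agre"),
            ("sky", "sky"),
        ],
    )
    def test_porter_reference_forms(self, word, stem):
        assert porter_stem(word) == stem

    def test_stemmer_can_be_disabled(self):
        config = NormalizationConfig(stemmer="none")
        assert normalize_token("positive", config) == "positive"

    def test_unknown_stemmer_rejected(self):
        with pytest.raises(ValueError):
            NormalizationConfig(stemmer="snowball9000")


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        config = NormalizationConfig(stemmer="none", percent_window=2)
        path = tmp_path / "norm.yaml"
        config.to_yaml(path)
        assert NormalizationConfig.from_yaml(path) == config

    def test_default_stop_words_serialized_verbatim(self, tmp_path):
        path = tmp_path / "norm.yaml"
        NormalizationConfig().to_yaml(path)
        back = NormalizationConfig.from_yaml(path)
        assert back.stop_words == DEFAULT_STOP_WORDS


class TestNormalizeBlock:
    def test_worked_example(self):
        seq = normalize_block("positive for ER, negative for PR")
        assert seq.tokens == ("posit", "for", "er", "comm", "neg", "for", "pr")
        assert seq.source_positions == (0, 1, 2, 3, 4, 5, 6)

    def test_all_stop_words_gives_empty_sequence(self):
        seq = normalize_block("the of and")
        assert len(seq) == 0

    def test_polarity_qualified_percent_collapses(self):
        assert "pospct" in normalize_block("ER: Positive (85%)").tokens
        assert "negpct" in normalize_block("PR: Negative (0%)").tokens

    def test_unqualified_percent_stays_numeric(self):
        assert normalize_block("ER: 30%").tokens == ("er", ":", "30", "%")

    def test_positions_skip_dropped_tokens(self):
        seq = normalize_block("the tumor is large")
        # raw stream: the(0) tumor(1) is(2) large(3)
        assert seq.tokens == ("tumor", "larg")
        assert seq.source_positions == (1, 3)

    def test_positions_span_sentences_without_reset(self):
        seq = normalize_block("Positive for ER. Negative for PR.")
        assert seq.source_positions == (0, 1, 2, 3, 4, 5, 6, 7)

    def test_deterministic_on_synthetic_corpus(self, small_reports):
        a = [normalize_block(r.text, observation_id=r.observation_id) for r in small_reports]
        b = [normalize_block(r.text, observation_id=r.observation_id) for r in small_reports]
        assert a == b

    def test_stop_words_never_survive_from_raw(self, small_reports):
        """No raw stop-word token reaches the output stream."""
        for r in small_reports:
            seq = normalize_block(r.text)
            raws = [t for s in split_sentences(r.text) for t in tokenize(s)]
            for pos in seq.source_positions:
                assert raws[pos].lower() not in DEFAULT_STOP_WORDS

    def test_substituted_symbols_absent_from_output(self, small_sequences):
        for seq in small_sequences:
            assert not set(seq.tokens) & {",", "/", "+"}

    def test_position_fidelity(self, small_reports):
        """Each output token is the normalization of its raw source token."""
        for r in small_reports:
            seq = normalize_block(r.text)
            raws = [t for s in split_sentences(r.text) for t in tokenize(s)]
            for tok, pos in zip(seq.tokens, seq.source_positions):
                if tok in {"pospct", "negpct"}:
                    continue  # collapsed from a number + "%" pair
                assert normalize_token(raws[pos]) == tok

    def test_idempotent_on_normalized_single_tokens(self, small_sequences):
        for seq in small_sequences[:10]:
            for tok in seq.tokens:
                if tok in {"pospct", "negpct", "comm", "slash", "plu"}:
                    continue  # identifiers are not re-derivable surface forms
                renorm = normalize_block(tok)
                assert renorm.tokens in ((tok,), ())
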