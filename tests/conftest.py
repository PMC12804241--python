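"""Shared fixtures: a toy English-like configuration and lexicon builders."""

from __future__ import annotations

import pytest

from orthodepth.config import LanguageConfig
from orthodepth.lexicon import Lexicon, LexiconEntry, tokenize_phonemes


@pytest.fixture(scope="session")
def en_config() -> LanguageConfig:
    """Inventories covering the classic toy words (mint, pint, cat, that...)."""
    return LanguageConfig(
        letters=set("abcefghilmnprst"),
        phonemes={
            "m", "n", "t", "s", "h", "p", "k", "g", "f", "l", "b", "r",
            "ɪ", "ɑɪ", "æ", "aɪ", "iː", "a", "ʃ", "tʃ", "dʒ", "θ",
        },
        vowel_letters=set("aei"),
        vowel_phonemes={"ɪ", "ɑɪ", "æ", "aɪ", "iː", "a"},
        strip_symbols={"ˈ"},
    )


def build_lexicon(words: dict[str, str], config: LanguageConfig, tag: str = "toy") -> Lexicon:
    """Lexicon from {orthography: transcription-string} under a config."""
    entries = tuple(
        LexiconEntry(o, tokenize_phonemes(p, config)) for o, p in words.items()
    )
    return Lexicon(entries, config, tag)


MINT_WORDS = {
    "mint": "mɪnt",
    "mints": "mɪnts",
    "tint": "tɪnt",
    "mist": "mɪst",
    "hint": "hɪnt",
    "pint": "pɑɪnt",
}


@pytest.fixture(scope="session")
def mint_lexicon(en_config) -> Lexicon:
    return build_lexicon(MINT_WORDS, en_config)
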