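"""Language configurations: symbol inventories against which lexicons are read.

A :class:`LanguageConfig` declares the letter inventory (diacritic forms such
as *ř* or *á* are atomic symbols, never decomposed), the phoneme inventory
(tokens may span several characters, e.g. a diphthong /ɑɪ/ or affricate /tʃ/),
which letters and phonemes act as syllable nuclei, and which suprasegmental
marks (stress, length, stød) are stripped on load.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["LanguageConfig"]


def _nfc(symbols) -> frozenset[str]:
    return frozenset(unicodedata.normalize("NFC", s) for s in symbols)


@dataclass(frozen=True)
class LanguageConfig:
    """Symbol inventories for one orthography.

    Parameters
    ----------
    letters
        Letter symbols; one Unicode code point each after NFC normalization.
    phonemes
        Phoneme tokens; may be multi-character (diphthongs, affricates).
    vowel_letters
        Subset of ``letters`` that can form an orthographic syllable nucleus.
    vowel_phonemes
        Subset of ``phonemes`` counting as phonological nuclei.
    syllabic_consonants
        Extra phonemes (e.g. Czech /r̩/) that also count as nuclei.
    strip_symbols
        Suprasegmental marks removed from transcriptions on load.
    """

    letters: frozenset[str]
    phonemes: frozenset[str]
    vowel_letters: frozenset[str]
    vowel_phonemes: frozenset[str]
    syllabic_consonants: frozenset[str] = field(default_factory=frozenset)
    strip_symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for name in (
            "letters",
            "phonemes",
            "vowel_letters",
            "vowel_phonemes",
            "syllabic_consonants",
            "strip_symbols",
        ):
            object.__setattr__(self, name, _nfc(getattr(self, name)))
        if not self.letters or not self.phonemes:
            raise ConfigError("letter and phoneme inventories must be nonempty")
        if not self.vowel_letters <= self.letters:
            raise ConfigError("vowel_letters must be a subset of letters")
        if not (self.vowel_phonemes | self.syllabic_consonants) <= self.phonemes:
            raise ConfigError(
                "vowel_phonemes and syllabic_consonants must be subsets of phonemes"
            )
        if self.strip_symbols & self.phonemes:
            raise ConfigError("strip_symbols may not overlap the phoneme inventory")

    @property
    def nucleus_phonemes(self) -> frozenset[str]:
        """Phonemes that can carry a syllable: vowels plus syllabic consonants."""
        return self.vowel_phonemes | self.syllabic_consonants

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "letters": sorted(self.letters),
            "phonemes": sorted(self.phonemes),
            "vowel_letters": sorted(self.vowel_letters),
            "vowel_phonemes": sorted(self.vowel_phonemes),
            "syllabic_consonants": sorted(self.syllabic_consonants),
            "strip_symbols": sorted(self.strip_symbols),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LanguageConfig":
        try:
            return cls(
                letters=frozenset(d["letters"]),
                phonemes=frozenset(d["phonemes"]),
                vowel_letters=frozenset(d["vowel_letters"]),
                vowel_phonemes=frozenset(d["vowel_phonemes"]),
                syllabic_consonants=frozenset(d.get("syllabic_consonants", ())),
                strip_symbols=frozenset(d.get("strip_symbols", ())),
            )
        except KeyError as e:  # pragma: no cover - trivial
            raise ConfigError(f"missing config field: {e}") from e

    @classmethod
    def from_file(cls, path: str | Path) -> "LanguageConfig":
        """Load a config from a YAML or JSON document (UTF-8)."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(
                json.dumps(self.to_dict(), ensure_ascii=False, indent=1),
                encoding="utf-8",
            )
        else:
            path.write_text(
                yaml.safe_dump(self.to_dict(), allow_unicode=True),
                encoding="utf-8",
            )
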