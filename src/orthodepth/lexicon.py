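"""Pronunciation lexicons: reading, tokenization, and monosyllable filtering.

A lexicon row pairs an orthographic word form with its phonemic
transcription, e.g. ``cat`` with /kæt/.  Transcriptions arrive as plain
strings and are tokenized against the declared phoneme inventory by greedy
longest match, so multi-character phonemes (/ɑɪ/ in *pint*) come out as
single tokens.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from .config import LanguageConfig
from .errors import LexiconFormatError, UnknownSymbolError

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "tokenize_phonemes",
    "read_lexicon",
    "write_lexicon",
    "filter_monosyllabic",
    "count_syllables",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One word: its letter string, phoneme-token sequence, optional frequency."""

    orthography: str
    phonology: tuple[str, ...]
    frequency: Optional[float] = None

    def __post_init__(self):
        if not self.orthography:
            raise LexiconFormatError("empty orthography")
        if not self.phonology:
            raise LexiconFormatError(f"empty phonology for {self.orthography!r}")
        if self.frequency is not None and self.frequency < 0:
            raise LexiconFormatError(f"negative frequency for {self.orthography!r}")

    def validate(self, config: LanguageConfig) -> None:
        for i, ch in enumerate(self.orthography):
            if ch not in config.letters:
                raise UnknownSymbolError(ch, i, self.orthography)
        for i, tok in enumerate(self.phonology):
            if tok not in config.phonemes:
                raise UnknownSymbolError(tok, i, "".join(self.phonology))


@dataclass(frozen=True)
class Lexicon:
    """A validated collection of entries under one language configuration."""

    entries: tuple[LexiconEntry, ...]
    config: LanguageConfig
    language_tag: str = ""

    def __post_init__(self):
        for e in self.entries:
            e.validate(self.config)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __getitem__(self, i) -> LexiconEntry:
        return self.entries[i]


def tokenize_phonemes(transcription: str, config: LanguageConfig) -> tuple[str, ...]:
    """Split a transcription string into phoneme tokens.

    Symbols in ``config.strip_symbols`` are removed first; the remainder is
    segmented greedily left to right, always taking the longest inventory
    token that matches.  The concatenation of the returned tokens equals the
    stripped input.

    Raises
    ------
    UnknownSymbolError
        If at some position no inventory token matches.
    LexiconFormatError
        If the transcription is empty after stripping.
    """
    s = unicodedata.normalize("NFC", transcription)
    for mark in config.strip_symbols:
        s = s.replace(mark, "")
    if not s:
        raise LexiconFormatError(f"transcription {transcription!r} empty after stripping")
    max_len = max(len(p) for p in config.phonemes)
    tokens: list[str] = []
    i = 0
    while i < len(s):
        for length in range(min(max_len, len(s) - i), 0, -1):
            cand = s[i : i + length]
            if cand in config.phonemes:
                tokens.append(cand)
                i += length
                break
        else:
            raise UnknownSymbolError(s[i], i, s)
    return tuple(tokens)


def read_lexicon(
    path: str | Path,
    config: LanguageConfig,
    *,
    language_tag: str = "",
    sep: str = "\t",
    orth_col: str = "orthography",
    phon_col: str = "phonology",
    freq_col: Optional[str] = None,
    phon_sep: Optional[str] = None,
) -> Lexicon:
    """Read a delimited lexicon file (UTF-8, header row required).

    Orthography is case-folded to lower case and NFC-normalized; the
    transcription column is stripped of suprasegmentals and tokenized
    (or split on ``phon_sep`` if given).  Exact duplicate
    (orthography, phonology) rows are merged with frequencies summed;
    homophones and homographs remain distinct entries.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as e:
        raise LexiconFormatError(f"cannot parse {path}: {e}") from e
    for col in [orth_col, phon_col] + ([freq_col] if freq_col else []):
        if col not in df.columns:
            raise LexiconFormatError(f"missing column {col!r} in {path}")

    merged: dict[tuple[str, tuple[str, ...]], Optional[float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        orth = unicodedata.normalize("NFC", getattr(row, orth_col).strip().lower())
        raw_phon = getattr(row, phon_col).strip()
        if not orth and not raw_phon:
            continue
        try:
            if phon_sep is not None:
                phon = tuple(t for t in raw_phon.split(phon_sep) if t)
                phon = tuple(
                    t
                    for t in (unicodedata.normalize("NFC", t) for t in phon)
                    if t not in config.strip_symbols
                )
            else:
                phon = tokenize_phonemes(raw_phon, config)
            freq = None
            if freq_col:
                raw = getattr(row, freq_col).strip()
                freq = float(raw) if raw else 0.0
            entry = LexiconEntry(orth, phon, freq)
            entry.validate(config)
        except (LexiconFormatError, ValueError) as e:
            raise LexiconFormatError(f"{path}, row {row_no}: {e}") from e
        key = (orth, phon)
        if key in merged:
            old = merged[key]
            merged[key] = None if (old is None and freq is None) else (old or 0.0) + (freq or 0.0)
        else:
            merged[key] = freq
    entries = tuple(
        LexiconEntry(orth, phon, freq) for (orth, phon), freq in merged.items()
    )
    return Lexicon(entries, config, language_tag)


def write_lexicon(
    lexicon: Lexicon,
    path: str | Path,
    *,
    sep: str = "\t",
    phon_sep: str = "",
) -> None:
    """Write a lexicon back to a delimited text file (transcriptions joined)."""
    has_freq = any(e.frequency is not None for e in lexicon)
    cols = ["orthography", "phonology"] + (["frequency"] if has_freq else [])
    rows = []
    for e in lexicon:
        row = {"orthography": e.orthography, "phonology": phon_sep.join(e.phonology)}
        if has_freq:
            row["frequency"] = "" if e.frequency is None else e.frequency
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, encoding="utf-8")


def count_syllables(entry: LexiconEntry, config: LanguageConfig) -> int:
    """Number of maximal runs of nucleus phonemes in the transcription."""
    nuclei = config.nucleus_phonemes
    runs = 0
    in_run = False
    for tok in entry.phonology:
        if tok in nuclei:
            if not in_run:
                runs += 1
            in_run = True
        else:
            in_run = False
    return runs


def filter_monosyllabic(lexicon: Lexicon) -> Lexicon:
    """Keep exactly the entries with one nucleus run (monosyllables).

    *cat* /kæt/ stays; *reklama* /rɛklama/ (three vowel runs) goes; Czech
    *krk* /kr̩k/ stays when /r̩/ is declared a syllabic consonant.
    """
    kept = tuple(e for e in lexicon if count_syllables(e, lexicon.config) == 1)
    return replace(lexicon, entries=kept)
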