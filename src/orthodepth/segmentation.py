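"""Segmenting words into graphemes, syllable parts, and positional alignments.

Three segmentations feed the depth measures:

* **Grapheme parsing** splits a word into (grapheme, phoneme) pairs under a
  GPC rule table, constrained by the word's attested pronunciation — *that*
  /θæt/ becomes (th, θ)(a, æ)(t, t).  Irregular words, whose pronunciation no
  rule sequence derives, can be parsed in a minimum-mismatch mode.
* **Syllable parsing** splits a monosyllable into onset / vowel grapheme /
  coda (orthography) and onset / nucleus / coda (phonology); the *body* is
  the vowel grapheme plus the following consonant letters (-int in *mint*).
* **Positional alignment** pairs the i-th letter with the i-th phoneme,
  discarding trailing unmatched units (the *e* of *bite*), as the
  letter-level mutual-information measure requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Optional, Sequence

from .config import LanguageConfig
from .errors import AmbiguousParseError, MeasureError, NoParseError
from .lexicon import LexiconEntry
from .rules import GPCRule, sort_rules

__all__ = [
    "GraphemeParse",
    "SyllableParse",
    "AlignedUnits",
    "parse_graphemes",
    "parse_syllable",
    "align_positional",
    "SILENT",
]

#: Explicit token for the phonological side of a silent grapheme.
SILENT = "∅"


@dataclass(frozen=True)
class GraphemeParse:
    """A word segmented into aligned (grapheme, phoneme-sequence) pairs."""

    pairs: tuple[tuple[str, tuple[str, ...]], ...]
    n_mismatches: int = 0

    @property
    def orthography(self) -> str:
        return "".join(g for g, _ in self.pairs)

    @property
    def phonology(self) -> tuple[str, ...]:
        return tuple(tok for _, p in self.pairs for tok in p)

    def check(self, entry: LexiconEntry) -> "GraphemeParse":
        assert self.orthography == entry.orthography, (self, entry)
        assert self.phonology == entry.phonology, (self, entry)
        assert all(g for g, _ in self.pairs)
        return self


@dataclass(frozen=True)
class SyllableParse:
    """Onset / vowel / coda split of a monosyllabic word, both sides."""

    onset_letters: str
    vowel_grapheme: str
    coda_letters: str
    onset_phonemes: tuple[str, ...]
    nucleus_phonemes: tuple[str, ...]
    coda_phonemes: tuple[str, ...]

    @property
    def body(self) -> str:
        """Orthographic body: the vowel grapheme and any following letters."""
        return self.vowel_grapheme + self.coda_letters

    @property
    def rime_phonemes(self) -> tuple[str, ...]:
        return self.nucleus_phonemes + self.coda_phonemes


@dataclass(frozen=True)
class AlignedUnits:
    """Position-aligned orthographic/phonological unit pairs for one word."""

    level: str  # letters | bigrams | graphemes
    pairs: tuple[tuple[str, str], ...]


# --------------------------------------------------------------------------
# grapheme parsing
# --------------------------------------------------------------------------


def _candidates(
    orth: str,
    phon: tuple[str, ...],
    i: int,
    j: int,
    sorted_rules: Sequence[GPCRule],
    allow_mismatch: bool,
):
    """Transitions from state (i, j), best-precedence first.

    Yields ``(cost, grapheme, phoneme_span)``: cost 0 when the rule's own
    phonemes match the next unconsumed phonology, cost 1 for a
    grapheme-shaped mismatch pairing (used only in minimum-mismatch mode).
    """
    seen: set[tuple[str, tuple[str, ...]]] = set()
    mismatches: list[tuple[int, str, tuple[str, ...]]] = []
    for rule in sorted_rules:
        if not rule.matches(orth, i):
            continue
        k = len(rule.phonemes)
        if phon[j : j + k] == rule.phonemes:
            if (rule.grapheme, rule.phonemes) not in seen:
                seen.add((rule.grapheme, rule.phonemes))
                yield 0, rule.grapheme, rule.phonemes
        if allow_mismatch:
            for span_len in range(0, k + 2):
                span = phon[j : j + span_len]
                if len(span) < span_len or span == rule.phonemes:
                    continue
                if (rule.grapheme, span) not in seen:
                    seen.add((rule.grapheme, span))
                    mismatches.append((1, rule.grapheme, span))
    yield from mismatches


def parse_graphemes(
    entry: LexiconEntry,
    rules: Sequence[GPCRule],
    *,
    strict: bool = False,
    allow_mismatch: bool = False,
) -> GraphemeParse:
    """Segment a word into (grapheme, phonemes) pairs under a rule table.

    The parse is phonology-constrained: a rule applies at a position only if
    its phonemes match the next unconsumed phonemes of the attested
    pronunciation (silent graphemes consume none).  Among rules applicable
    at a position, precedence is context-sensitive before context-free at
    equal grapheme length, longer grapheme before shorter, file order last.

    With ``allow_mismatch=True``, a rule's grapheme may pair with a non-rule
    phoneme span at cost 1 and the parse minimizing total mismatches is
    returned — this is how attested-but-irregular words (*pint* under
    i → /ɪ/) get a segmentation.  With ``strict=True`` an exact parse must
    be unique, else :class:`AmbiguousParseError`.

    Raises
    ------
    NoParseError
        If no rule sequence covers the word.
    """
    if not rules:
        raise NoParseError("empty rule set")
    orth, phon = entry.orthography, entry.phonology
    sorted_rules = sort_rules(rules)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> Optional[tuple[int, tuple]]:
        if i == len(orth):
            return (0, ()) if j == len(phon) else None
        result: Optional[tuple[int, tuple]] = None
        for cost, g, span in _candidates(orth, phon, i, j, sorted_rules, allow_mismatch):
            sub = best(i + len(g), j + len(span))
            if sub is None:
                continue
            total = cost + sub[0]
            if result is None or total < result[0]:
                result = (total, ((g, span),) + sub[1])
                if total == 0:
                    break  # earliest-precedence exact continuation wins
        return result

    if strict:
        parses = _exact_parses(orth, phon, sorted_rules)
        first = next(parses, None)
        if first is None:
            raise NoParseError(f"no rule parse for {entry.orthography!r}")
        for other in parses:
            if other != first:
                raise AmbiguousParseError(
                    f"multiple rule parses for {entry.orthography!r}: {first} / {other}"
                )
        return GraphemeParse(first).check(entry)

    res = best(0, 0)
    if res is None:
        raise NoParseError(f"no rule parse for {entry.orthography!r}")
    return GraphemeParse(res[1], n_mismatches=res[0]).check(entry)


def _exact_parses(
    orth: str, phon: tuple[str, ...], sorted_rules: Sequence[GPCRule]
) -> Iterator[tuple]:
    """All exact (zero-mismatch) parses, in precedence order."""

    def rec(i: int, j: int) -> Iterator[tuple]:
        if i == len(orth):
            if j == len(phon):
                yield ()
            return
        for cost, g, span in _candidates(orth, phon, i, j, sorted_rules, False):
            for rest in rec(i + len(g), j + len(span)):
                yield ((g, span),) + rest

    return rec(0, 0)


# --------------------------------------------------------------------------
# syllable parsing
# --------------------------------------------------------------------------


def parse_syllable(entry: LexiconEntry, config: LanguageConfig) -> SyllableParse:
    """Split a monosyllable into onset / vowel / coda on both sides.

    The orthographic vowel grapheme is the first maximal run of vowel
    letters; the nucleus is the first maximal run of nucleus phonemes.
    """
    orth, phon = entry.orthography, entry.phonology
    v0 = next((i for i, ch in enumerate(orth) if ch in config.vowel_letters), None)
    if v0 is None:
        raise MeasureError(f"no vowel letter in {orth!r}")
    v1 = v0
    while v1 < len(orth) and orth[v1] in config.vowel_letters:
        v1 += 1
    nuclei = config.nucleus_phonemes
    p0 = next((i for i, t in enumerate(phon) if t in nuclei), None)
    if p0 is None:
        raise MeasureError(f"no nucleus phoneme in {orth!r} {phon}")
    p1 = p0
    while p1 < len(phon) and phon[p1] in nuclei:
        p1 += 1
    return SyllableParse(
        onset_letters=orth[:v0],
        vowel_grapheme=orth[v0:v1],
        coda_letters=orth[v1:],
        onset_phonemes=phon[:p0],
        nucleus_phonemes=phon[p0:p1],
        coda_phonemes=phon[p1:],
    )


# --------------------------------------------------------------------------
# positional alignment
# --------------------------------------------------------------------------


def align_positional(
    entry: LexiconEntry,
    level: str = "letters",
    *,
    windows: str = "overlapping",
) -> AlignedUnits:
    """Pair the i-th letter with the i-th phoneme, left to right.

    Trailing unmatched letters (*e* in *bite* [b aɪ t]) — or, symmetrically,
    trailing unmatched phonemes — are discarded.  At the ``bigrams`` level,
    adjacent pairs of the already-aligned letter and phoneme sequences are
    paired (``windows="overlapping"`` slides by one, ``"disjoint"`` by two).
    """
    if level not in ("letters", "bigrams"):
        raise ValueError(f"unsupported alignment level {level!r}")
    m = min(len(entry.orthography), len(entry.phonology))
    letters = entry.orthography[:m]
    phons = entry.phonology[:m]
    if level == "letters":
        pairs = tuple(zip(letters, phons))
        return AlignedUnits("letters", pairs)
    step = 1 if windows == "overlapping" else 2
    pairs = tuple(
        (letters[i : i + 2], " ".join(phons[i : i + 2])) for i in range(0, m - 1, step)
    )
    return AlignedUnits("bigrams", pairs)
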