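"""Statistical depth measures: consistency and entropy.

Consistency of a word is the proportion of words sharing its orthographic
unit (vowel grapheme or body) that also share that unit's pronunciation —
friends over friends-plus-enemies, the word itself included.  Entropy
refines consistency by distinguishing scenarios that consistency conflates:
a body pronounced P1 once and P2 three times has
H = −(0.25·log2 0.25 + 0.75·log2 0.75) = 0.81 bits, while four distinct
pronunciations give 2 bits.

Two lexicon-level entropy families are provided: *onset entropy* (the
letter-probability-weighted entropy of first-phoneme distributions per
initial letter) and *vowel entropy* in three variants — context-independent,
onset-conditional, and coda-conditional — each a count-weighted average of
per-unit entropies over nucleus pronunciations.

All probabilities are type-based by default (each word counts once); pass
``weighted=True`` to weight by token frequency.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import EmptyLexiconError, MeasureError
from .lexicon import Lexicon, LexiconEntry
from .segmentation import SyllableParse, parse_syllable

__all__ = [
    "ProbDist",
    "ConsistencyScores",
    "EntropySummary",
    "entropy",
    "entropy_summary",
    "unit_consistency",
    "onset_entropy",
    "vowel_entropy",
]


@dataclass(frozen=True)
class ProbDist:
    """A discrete probability distribution over outcome tokens."""

    outcomes: tuple[tuple[str, float], ...]

    def __post_init__(self):
        probs = np.array([p for _, p in self.outcomes], dtype=float)
        if len(probs) == 0 or np.any(probs <= 0):
            raise MeasureError("probabilities must be positive")
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise MeasureError(f"probabilities sum to {probs.sum()}, not 1")

    @classmethod
    def from_counts(cls, counts: dict) -> "ProbDist":
        total = sum(counts.values())
        if total <= 0:
            raise MeasureError("no observations")
        return cls(
            tuple(
                (str(k), v / total)
                for k, v in sorted(counts.items(), key=lambda kv: str(kv[0]))
                if v > 0
            )
        )

    @property
    def probs(self) -> np.ndarray:
        return np.array([p for _, p in self.outcomes], dtype=float)


def entropy(dist) -> float:
    """Shannon entropy in bits, H(X) = −Σ p(x_i) log2 p(x_i).

    Accepts a :class:`ProbDist`, a mapping of counts, or a probability
    array.  A single-outcome distribution has entropy 0.
    """
    if isinstance(dist, ProbDist):
        p = dist.probs
    elif isinstance(dist, dict):
        p = ProbDist.from_counts(dist).probs
    else:
        p = np.asarray(list(dist), dtype=float)
        if p.size == 0 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise MeasureError("invalid probability vector")
        p = p[p > 0]
    return float(stats.entropy(p, base=2))


def _weight(entry: LexiconEntry, weighted: bool) -> float:
    if not weighted:
        return 1.0
    return entry.frequency if entry.frequency is not None else 1.0


def _syllable_parses(lexicon: Lexicon) -> list[tuple[LexiconEntry, SyllableParse]]:
    if len(lexicon) == 0:
        raise EmptyLexiconError("measure needs a nonempty lexicon")
    return [(e, parse_syllable(e, lexicon.config)) for e in lexicon]


@dataclass(frozen=True)
class ConsistencyScores:
    """Per-word consistency values (aligned with the lexicon) and their mean."""

    unit: str
    values: tuple[float, ...]
    mean: float
    n_unique_units: int  # words whose unit occurs nowhere else (score 1 by self)


def unit_consistency(
    lexicon: Lexicon, unit: str = "body", *, weighted: bool = False
) -> ConsistencyScores:
    """Spelling-to-sound consistency at the vowel-grapheme or body level.

    For each word, the share of words carrying the same orthographic unit
    (itself included) that realize it with the same pronunciation: the
    nucleus phonemes for ``unit="vowel"``, the rime for ``unit="body"``.
    *mill/hill/fill* all rhyme, so each scores 1; in a one-P1-vs-three-P2
    body family the minority word scores 0.25 and the majority words 0.75.
    """
    if unit not in ("vowel", "body"):
        raise ValueError(f"unknown consistency unit {unit!r}")
    pairs = _syllable_parses(lexicon)
    unit_of = (
        (lambda s: (s.vowel_grapheme, s.nucleus_phonemes))
        if unit == "vowel"
        else (lambda s: (s.body, s.rime_phonemes))
    )
    denom: Counter = Counter()
    numer: Counter = Counter()
    for e, s in pairs:
        o, p = unit_of(s)
        w = _weight(e, weighted)
        denom[o] += w
        numer[(o, p)] += w
    values = []
    weights = []
    n_unique = 0
    for e, s in pairs:
        o, p = unit_of(s)
        values.append(numer[(o, p)] / denom[o])
        weights.append(_weight(e, weighted))
        if denom[o] == _weight(e, weighted):
            n_unique += 1
    mean = float(np.average(values, weights=weights))
    return ConsistencyScores(unit, tuple(values), mean, n_unique)


@dataclass(frozen=True)
class EntropySummary:
    """The four lexicon-level entropy measures, in bits."""

    onset_entropy: float
    vowel_entropy_ci: float
    vowel_entropy_onset_cond: float
    vowel_entropy_coda_cond: float


def onset_entropy(lexicon: Lexicon, *, weighted: bool = False) -> float:
    """Initial-letter-weighted entropy of initial-phoneme distributions.

    For each initial letter, the entropy of the distribution of initial
    phonemes among words starting with that letter; summed over letters
    weighted by the probability that a word begins with the letter.
    Predictable complexity still counts: *seat*/*sheet* both start with
    *s* but with /s/ vs /ʃ/, contributing a full bit.
    """
    if len(lexicon) == 0:
        raise EmptyLexiconError("onset_entropy needs a nonempty lexicon")
    by_letter: dict[str, Counter] = defaultdict(Counter)
    letter_w: Counter = Counter()
    for e in lexicon:
        w = _weight(e, weighted)
        by_letter[e.orthography[0]][e.phonology[0]] += w
        letter_w[e.orthography[0]] += w
    total = sum(letter_w.values())
    return float(
        sum(letter_w[l] / total * entropy(dict(c)) for l, c in by_letter.items())
    )


_VOWEL_MODES = ("context_independent", "onset_conditional", "coda_conditional")


def vowel_entropy(
    lexicon: Lexicon, mode: str = "context_independent", *, weighted: bool = False
) -> float:
    """Average entropy of vowel-grapheme pronunciations, optionally in context.

    Context-independent: per vowel grapheme, the distribution of its nucleus
    pronunciations across all words.  Conditional variants additionally
    condition on the full orthographic onset (or coda) string — words with
    an empty onset form their own context.  Per-unit entropies are averaged
    weighted by unit (or unit-in-context) occurrence counts, so the law of
    total entropy guarantees that conditioning never increases the value.
    """
    if mode not in _VOWEL_MODES:
        raise ValueError(f"unknown vowel-entropy mode {mode!r}")
    pairs = _syllable_parses(lexicon)
    groups: dict[tuple, Counter] = defaultdict(Counter)
    for e, s in pairs:
        if mode == "context_independent":
            key = (s.vowel_grapheme,)
        elif mode == "onset_conditional":
            key = (s.vowel_grapheme, s.onset_letters)
        else:
            key = (s.vowel_grapheme, s.coda_letters)
        groups[key][s.nucleus_phonemes] += _weight(e, weighted)
    total = sum(sum(c.values()) for c in groups.values())
    return float(
        sum(sum(c.values()) / total * entropy(dict(c)) for c in groups.values())
    )


def entropy_summary(lexicon: Lexicon, *, weighted: bool = False) -> EntropySummary:
    return EntropySummary(
        onset_entropy=onset_entropy(lexicon, weighted=weighted),
        vowel_entropy_ci=vowel_entropy(lexicon, "context_independent", weighted=weighted),
        vowel_entropy_onset_cond=vowel_entropy(lexicon, "onset_conditional", weighted=weighted),
        vowel_entropy_coda_cond=vowel_entropy(lexicon, "coda_conditional", weighted=weighted),
    )
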