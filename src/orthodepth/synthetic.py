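"""Artificial orthographies with known complexity and unpredictability.

The generator builds a rule system around a bijective letter↔phoneme core
and then turns two families of knobs:

* **complexity knobs** — multiletter (digraph) graphemes, context-sensitive
  rules, and silent final letters — enlarge the units needed to read and
  break the one-letter-one-phoneme equality without making any word
  irregular;
* the **unpredictability knob** — the exception rate ε — perturbs one
  unit's mapping per affected word (the nucleus vowel, one token for one
  token) into a non-rule alternative, creating labeled irregular words
  while leaving word lengths untouched.

Because the attested phonology of every non-exception word is *defined* as
the rule-derived pronunciation, ground truth is exact: the share of
irregular words equals the share of exception labels, digraph counts equal
the generator's ledger, and silent-final twins are guaranteed homophone
neighbor pairs.  Words are CVC-skeleton monosyllables so syllable parsing
always succeeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import LanguageConfig
from .errors import InfeasibleSpecError, NoRuleError
from .lexicon import Lexicon, LexiconEntry, write_lexicon
from .rules import GPCRule, sort_rules, write_rules

__all__ = [
    "GeneratorSpec",
    "WordTruth",
    "GroundTruth",
    "generate_orthography",
    "generate_lexicon",
    "write_fixture",
]

_VOWEL_POOL = "aeiouyæøœ"
_CONSONANT_POOL = "bcdfghjklmnpqrstvwxzßðþćčďğ"


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one artificial orthography + lexicon.

    ``n_phonemes`` is normally left ``None`` and derived from the rule
    system; a value inconsistent with the derived inventory raises
    :class:`InfeasibleSpecError`.
    """

    n_letters: int = 20
    n_phonemes: Optional[int] = None
    n_multiletter_graphemes: int = 0
    n_context_rules: int = 0
    silent_final_rate: float = 0.0
    exception_rate: float = 0.0
    word_length_range: tuple[int, int] = (3, 5)
    n_words: int = 500
    seed: int = 0

    def __post_init__(self):
        for name in ("silent_final_rate", "exception_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpecError(f"{name} must be in [0, 1], got {v}")
        if self.n_words <= 0:
            raise InfeasibleSpecError("n_words must be positive")
        lo, hi = self.word_length_range
        if not (1 <= lo <= hi):
            raise InfeasibleSpecError(f"bad word_length_range {self.word_length_range}")


@dataclass(frozen=True)
class WordTruth:
    """Ground-truth record for one generated word."""

    orthography: str
    phonology: tuple[str, ...]
    is_exception: bool
    has_silent_final: bool
    segmentation: tuple[tuple[str, tuple[str, ...]], ...]


@dataclass(frozen=True)
class GroundTruth:
    """The generator's own ledger: rule composition and per-word labels."""

    n_single: int
    n_multi: int
    n_context: int
    silent_letter: Optional[str]
    words: tuple[WordTruth, ...] = field(repr=False)

    @property
    def n_exceptions(self) -> int:
        return sum(w.is_exception for w in self.words)

    def to_dict(self) -> dict:
        return {
            "n_single": self.n_single,
            "n_multi": self.n_multi,
            "n_context": self.n_context,
            "silent_letter": self.silent_letter,
            "words": [
                {
                    "orthography": w.orthography,
                    "phonology": list(w.phonology),
                    "is_exception": w.is_exception,
                    "has_silent_final": w.has_silent_final,
                    "segmentation": [[g, list(p)] for g, p in w.segmentation],
                }
                for w in self.words
            ],
        }


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_orthography(spec: GeneratorSpec) -> tuple[list[GPCRule], LanguageConfig]:
    """Build a seeded rule system and its language configuration.

    The core is the identity mapping letter → letter-named phoneme.  On top
    of it: ``n_multiletter_graphemes`` consonant digraphs mapping to new
    single phonemes (written as the uppercased digraph), ``n_context_rules``
    context-sensitive consonant readings conditioned on the following vowel
    letter, and — when ``silent_final_rate > 0`` — one reserved consonant
    letter used only as a silent word-final grapheme.
    """
    rng, _ = _rngs(spec.seed)
    n_vowels = max(2, round(spec.n_letters * 0.2))
    n_consonants = spec.n_letters - n_vowels
    use_silent = spec.silent_final_rate > 0
    if n_vowels > len(_VOWEL_POOL) or n_consonants > len(_CONSONANT_POOL):
        raise InfeasibleSpecError(f"n_letters={spec.n_letters} exceeds the symbol pools")
    if n_consonants < 1 + int(use_silent):
        raise InfeasibleSpecError("too few consonant letters for the requested features")
    vowels = list(_VOWEL_POOL[:n_vowels])
    consonants = list(_CONSONANT_POOL[:n_consonants])
    silent_letter = consonants.pop() if use_silent else None
    sounding = consonants  # consonants with an identity reading

    if spec.n_multiletter_graphemes > len(sounding) * (len(sounding) - 1):
        raise InfeasibleSpecError("not enough consonant pairs for the digraphs requested")
    if spec.n_context_rules > len(sounding) * len(vowels):
        raise InfeasibleSpecError("not enough consonant-vowel pairs for the context rules")

    rules: list[GPCRule] = []
    # context-sensitive readings: c before vowel v sounds as C1 (a new phoneme)
    cv_pairs = [(c, v) for c in sounding for v in vowels]
    for k in rng.choice(len(cv_pairs), size=spec.n_context_rules, replace=False):
        c, v = cv_pairs[int(k)]
        rules.append(GPCRule(grapheme=c, phonemes=(c.upper() + "1",), post_context=v))
    # multiletter graphemes: digraph c1c2 sounds as the single phoneme C1C2
    digraphs = [c1 + c2 for c1 in sounding for c2 in sounding if c1 != c2]
    for k in rng.choice(len(digraphs), size=spec.n_multiletter_graphemes, replace=False):
        g = digraphs[int(k)]
        rules.append(GPCRule(grapheme=g, phonemes=(g.upper(),)))
    if silent_letter is not None:
        rules.append(GPCRule(grapheme=silent_letter, phonemes=(), position="final"))
    for letter in vowels + sounding:
        rules.append(GPCRule(grapheme=letter, phonemes=(letter,)))

    phonemes = {p for r in rules for p in r.phonemes}
    if spec.n_phonemes is not None and spec.n_phonemes != len(phonemes):
        raise InfeasibleSpecError(
            f"spec.n_phonemes={spec.n_phonemes} but the rule system yields {len(phonemes)}"
        )
    config = LanguageConfig(
        letters=frozenset(vowels + sounding + ([silent_letter] if silent_letter else [])),
        phonemes=frozenset(phonemes),
        vowel_letters=frozenset(vowels),
        vowel_phonemes=frozenset(vowels),
    )
    return rules, config


def _derive(word: str, ordered: list[GPCRule]) -> list[tuple[str, tuple[str, ...]]]:
    """Rule-derived segmentation of a word (precedence application)."""
    pairs = []
    i = 0
    while i < len(word):
        for rule in ordered:
            if rule.matches(word, i):
                pairs.append((rule.grapheme, rule.phonemes))
                i += len(rule.grapheme)
                break
        else:  # pragma: no cover - generator words are covered by construction
            raise NoRuleError(word, i)
    return pairs


def generate_lexicon(
    rules: list[GPCRule],
    config: LanguageConfig,
    spec: GeneratorSpec,
    *,
    language_tag: str = "synthetic",
) -> tuple[Lexicon, GroundTruth]:
    """Sample ``n_words`` distinct CVC-skeleton words and their pronunciations.

    Each word's phonology is the rule-derived reading, perturbed with
    probability ``exception_rate`` into a labeled exception (nucleus vowel
    phoneme replaced by a different vowel phoneme).  With probability
    ``silent_final_rate`` a word is paired with a silent-final twin carrying
    the identical pronunciation, which guarantees homophone neighbor pairs.
    """
    _, rng = _rngs(spec.seed)
    ordered = sort_rules(rules)
    vowels = sorted(config.vowel_letters)
    silent_rules = [r for r in rules if not r.phonemes]
    silent_letter = silent_rules[0].grapheme if silent_rules else None
    cons_units = sorted(
        r.grapheme
        for r in rules
        if r.phonemes and not r.has_context and r.grapheme not in config.vowel_letters
    )
    singles = [u for u in cons_units if len(u) == 1]
    lo, hi = spec.word_length_range

    entries: list[LexiconEntry] = []
    truths: list[WordTruth] = []
    seen: set[str] = set()
    stale = 0  # consecutive draws that yielded no new word
    while len(entries) < spec.n_words:
        stale += 1
        if stale > 20_000:
            raise InfeasibleSpecError(
                f"could not reach n_words={spec.n_words} "
                f"(space too small under word_length_range={spec.word_length_range})"
            )
        target = int(rng.integers(lo, hi + 1))
        word = str(rng.choice(cons_units)) + str(rng.choice(vowels))
        word += str(rng.choice(cons_units))
        while len(word) < target and singles:
            word += str(rng.choice(singles))
        if not lo <= len(word) <= hi or word in seen:
            continue
        segmentation = _derive(word, ordered)
        phon = tuple(t for _, p in segmentation for t in p)
        is_exception = bool(rng.random() < spec.exception_rate)
        if is_exception:
            nucleus = next(i for i, t in enumerate(phon) if t in config.vowel_phonemes)
            alternatives = [v for v in vowels if v != phon[nucleus]]
            new_v = str(rng.choice(alternatives))
            phon = phon[:nucleus] + (new_v,) + phon[nucleus + 1 :]
            segmentation = [
                (g, (new_v,) if any(t in config.vowel_phonemes for t in p) else p)
                for g, p in segmentation
            ]
        seen.add(word)
        stale = 0
        entries.append(LexiconEntry(word, phon))
        truths.append(WordTruth(word, phon, is_exception, False, tuple(segmentation)))
        if (
            silent_letter is not None
            and len(entries) < spec.n_words
            and rng.random() < spec.silent_final_rate
        ):
            twin = word + silent_letter
            if twin not in seen:
                seen.add(twin)
                entries.append(LexiconEntry(twin, phon))
                truths.append(
                    WordTruth(
                        twin,
                        phon,
                        is_exception,
                        True,
                        tuple(segmentation) + ((silent_letter, ()),),
                    )
                )
    summary = GroundTruth(
        n_single=sum(r.rule_class == "single-letter" for r in rules),
        n_multi=sum(r.rule_class == "multiletter" for r in rules),
        n_context=sum(r.rule_class == "context-sensitive" for r in rules),
        silent_letter=silent_letter,
        words=tuple(truths),
    )
    return Lexicon(tuple(entries), config, language_tag), summary


def write_fixture(
    out_dir: str | Path,
    spec: GeneratorSpec,
    *,
    language_tag: str = "synthetic",
) -> dict[str, Path]:
    """Generate and write a complete fixture: lexicon TSV, config YAML,
    rule TSV, ground-truth JSON, and the spec itself."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules, config = generate_orthography(spec)
    lexicon, truth = generate_lexicon(rules, config, spec, language_tag=language_tag)
    paths = {
        "lexicon": out / "lexicon.tsv",
        "config": out / "config.yaml",
        "rules": out / "rules.tsv",
        "truth": out / "ground_truth.json",
        "spec": out / "spec.json",
    }
    write_lexicon(lexicon, paths["lexicon"])
    config.to_file(paths["config"])
    write_rules(rules, paths["rules"])
    paths["truth"].write_text(
        json.dumps(truth.to_dict(), ensure_ascii=False, indent=1), encoding="utf-8"
    )
    spec_d = asdict(spec)
    spec_d["word_length_range"] = list(spec.word_length_range)
    paths["spec"].write_text(json.dumps(spec_d, indent=1), encoding="utf-8")
    return paths
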