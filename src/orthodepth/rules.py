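"""Grapheme–phoneme correspondence (GPC) rules.

A GPC rule maps a grapheme — one or more letters — onto a phoneme sequence
(usually one phoneme; empty for silent letters; two for cases like x → /ks/).
Its pronunciation may be restricted to a word position or conditioned on
surrounding letters, e.g. c → /k/ but c[i] → /s/.  Rules are classed as
single-letter, multiletter, or context-sensitive; the class is fully
determined by the rule's shape.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import LexiconFormatError

__all__ = [
    "GPCRule",
    "SINGLE_LETTER",
    "MULTILETTER",
    "CONTEXT_SENSITIVE",
    "precedence_key",
    "sort_rules",
    "read_rules",
    "write_rules",
]

SINGLE_LETTER = "single-letter"
MULTILETTER = "multiletter"
CONTEXT_SENSITIVE = "context-sensitive"

_POSITIONS = ("any", "initial", "medial", "final")


@dataclass(frozen=True)
class GPCRule:
    """One grapheme→phoneme correspondence with optional constraints.

    ``pre_context`` / ``post_context`` are letter patterns that must
    immediately precede / follow the grapheme; alternatives are separated
    by ``|`` (so ``post_context="i|e|y"`` fires before any of *i e y*).
    """

    grapheme: str
    phonemes: tuple[str, ...]
    position: str = "any"
    pre_context: Optional[str] = None
    post_context: Optional[str] = None

    def __post_init__(self):
        if not self.grapheme:
            raise LexiconFormatError("rule grapheme must be nonempty")
        if self.position not in _POSITIONS:
            raise LexiconFormatError(f"bad rule position {self.position!r}")
        object.__setattr__(
            self, "grapheme", unicodedata.normalize("NFC", self.grapheme)
        )
        object.__setattr__(
            self,
            "phonemes",
            tuple(unicodedata.normalize("NFC", p) for p in self.phonemes),
        )

    @property
    def has_context(self) -> bool:
        return bool(self.pre_context) or bool(self.post_context)

    @property
    def rule_class(self) -> str:
        if self.has_context:
            return CONTEXT_SENSITIVE
        if len(self.grapheme) > 1:
            return MULTILETTER
        return SINGLE_LETTER

    # ------------------------------------------------------------ matching
    def matches(self, orthography: str, pos: int) -> bool:
        """Does this rule's orthographic side apply at ``pos`` of the word?"""
        g = self.grapheme
        end = pos + len(g)
        if orthography[pos:end] != g:
            return False
        if self.position == "initial" and pos != 0:
            return False
        if self.position == "final" and end != len(orthography):
            return False
        if self.position == "medial" and (pos == 0 or end == len(orthography)):
            return False
        if self.pre_context is not None:
            before = orthography[:pos]
            if not any(before.endswith(alt) for alt in self.pre_context.split("|")):
                return False
        if self.post_context is not None:
            after = orthography[end:]
            if not any(after.startswith(alt) for alt in self.post_context.split("|")):
                return False
        return True


def precedence_key(rules: Sequence[GPCRule]):
    """Build a rule-ordering key: specific before general.

    Context-sensitive rules outrank context-free ones at equal grapheme
    length; longer graphemes outrank shorter; remaining ties fall back to
    file order.
    """
    order = {id(r): i for i, r in enumerate(rules)}

    def key(rule: GPCRule):
        return (
            -len(rule.grapheme),
            0 if rule.has_context else 1,
            order[id(rule)],
        )

    return key


def sort_rules(rules: Sequence[GPCRule]) -> list[GPCRule]:
    """Rules sorted by application precedence (stable w.r.t. file order)."""
    return sorted(rules, key=precedence_key(rules))


def read_rules(path: str | Path, *, sep: str = "\t") -> list[GPCRule]:
    """Read a delimited GPC rule file.

    Expected columns: ``grapheme``, ``phonemes`` (space-separated tokens;
    empty for a silent grapheme), and optional ``position``, ``pre_context``,
    ``post_context``.  A ``rule_class`` column, if present, is checked
    against the class implied by the rule's shape.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as e:
        raise LexiconFormatError(f"cannot parse rule file {path}: {e}") from e
    if "grapheme" not in df.columns or "phonemes" not in df.columns:
        raise LexiconFormatError(f"rule file {path} needs 'grapheme' and 'phonemes' columns")
    rules: list[GPCRule] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        phon = tuple(t for t in getattr(row, "phonemes").split() if t)
        rule = GPCRule(
            grapheme=getattr(row, "grapheme"),
            phonemes=phon,
            position=(getattr(row, "position", "") or "any").strip() or "any",
            pre_context=(getattr(row, "pre_context", "") or None),
            post_context=(getattr(row, "post_context", "") or None),
        )
        declared = getattr(row, "rule_class", "")
        if declared and declared != rule.rule_class:
            raise LexiconFormatError(
                f"{path}, row {row_no}: declared class {declared!r} "
                f"contradicts rule shape ({rule.rule_class})"
            )
        rules.append(rule)
    return rules


def write_rules(rules: Sequence[GPCRule], path: str | Path, *, sep: str = "\t") -> None:
    rows = [
        {
            "grapheme": r.grapheme,
            "phonemes": " ".join(r.phonemes),
            "position": r.position,
            "pre_context": r.pre_context or "",
            "post_context": r.post_context or "",
            "rule_class": r.rule_class,
        }
        for r in rules
    ]
    pd.DataFrame(
        rows,
        columns=["grapheme", "phonemes", "position", "pre_context", "post_context", "rule_class"],
    ).to_csv(path, sep=sep, index=False, encoding="utf-8")
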