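"""Rule-based depth measures: basic proxies, rule inventories, irregularity.

The *basic* proxies need no theory: the share of words with as many letters
as phonemes (100% in a perfectly shallow orthography) and the number of
distinct grapheme–phoneme pairings (one for *t*, but two for *c*: /k/ in
*cat*, /s/ in *ceiling*).  The *rule-derived* measures follow the dual-route
tradition: complexity is indexed by the counts of multiletter and
context-sensitive rules, unpredictability by the percentage of words whose
rule-derived pronunciation differs from the attested one (irregular words).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import EmptyLexiconError, NoRuleError
from .lexicon import Lexicon
from .rules import (
    CONTEXT_SENSITIVE,
    MULTILETTER,
    SINGLE_LETTER,
    GPCRule,
    sort_rules,
)
from .segmentation import GraphemeParse

__all__ = [
    "BasicSummary",
    "RuleSystemSummary",
    "pct_equal_length",
    "count_unique_gp_mappings",
    "basic_summary",
    "classify_rules",
    "apply_rules",
    "pct_irregular",
    "irregularity_detail",
    "induce_modal_rules",
]


@dataclass(frozen=True)
class BasicSummary:
    """Inventory sizes and theory-free depth proxies for one lexicon."""

    n_letters: int
    n_graphemes: Optional[int]
    n_phonemes: int
    pct_equal_length: float
    n_unique_gp_mappings: Optional[int]


@dataclass(frozen=True)
class RuleSystemSummary:
    """Rule-class composition of a GPC table plus the irregularity rate."""

    n_single: int
    n_multi: int
    n_context: int
    pct_irregular: Optional[float] = None
    n_no_rule: int = 0

    @property
    def n_total(self) -> int:
        return self.n_single + self.n_multi + self.n_context

    @property
    def pct_each(self) -> dict[str, float]:
        total = self.n_total
        return {
            SINGLE_LETTER: 100.0 * self.n_single / total,
            MULTILETTER: 100.0 * self.n_multi / total,
            CONTEXT_SENSITIVE: 100.0 * self.n_context / total,
        }


def pct_equal_length(lexicon: Lexicon) -> float:
    """Percentage of words with the same number of letters as phonemes."""
    if len(lexicon) == 0:
        raise EmptyLexiconError("pct_equal_length needs a nonempty lexicon")
    n_eq = sum(1 for e in lexicon if len(e.orthography) == len(e.phonology))
    return 100.0 * n_eq / len(lexicon)


def count_unique_gp_mappings(parses: Sequence[GraphemeParse]) -> int:
    """Number of distinct (grapheme, phoneme-sequence) pairings across parses."""
    return len({(g, p) for parse in parses for g, p in parse.pairs})


def basic_summary(
    lexicon: Lexicon, parses: Optional[Sequence[GraphemeParse]] = None
) -> BasicSummary:
    """Table-1-style descriptives; grapheme counts need parses."""
    n_graphemes = None
    n_mappings = None
    if parses is not None:
        n_graphemes = len({g for parse in parses for g, _ in parse.pairs})
        n_mappings = count_unique_gp_mappings(parses)
    return BasicSummary(
        n_letters=len(lexicon.config.letters),
        n_graphemes=n_graphemes,
        n_phonemes=len(lexicon.config.phonemes),
        pct_equal_length=pct_equal_length(lexicon),
        n_unique_gp_mappings=n_mappings,
    )


def classify_rules(rules: Sequence[GPCRule]) -> RuleSystemSummary:
    """Count rules per class (single-letter / multiletter / context-sensitive)."""
    counts = Counter(r.rule_class for r in rules)
    return RuleSystemSummary(
        n_single=counts.get(SINGLE_LETTER, 0),
        n_multi=counts.get(MULTILETTER, 0),
        n_context=counts.get(CONTEXT_SENSITIVE, 0),
    )


def apply_rules(
    orthography: str, rules: Sequence[GPCRule], *, _sorted: bool = False
) -> tuple[str, ...]:
    """Rule-derived pronunciation: deterministic left-to-right application.

    At each position the highest-precedence applicable rule fires and the
    scan advances past its grapheme.  With only g → /g/, *gift* reads
    /gɪft/ (regular) while *gist* is mispredicted; adding g[i] → /dʒ/ flips
    which of the two is irregular.
    """
    ordered = rules if _sorted else sort_rules(rules)
    out: list[str] = []
    i = 0
    while i < len(orthography):
        for rule in ordered:
            if rule.matches(orthography, i):
                out.extend(rule.phonemes)
                i += len(rule.grapheme)
                break
        else:
            raise NoRuleError(orthography, i)
    return tuple(out)


def irregularity_detail(
    lexicon: Lexicon, rules: Sequence[GPCRule]
) -> tuple[float, int, int]:
    """(pct_irregular, n_irregular, n_no_rule) for a lexicon under a rule set.

    A word is irregular when the rule-derived pronunciation differs from the
    attested one; words the rule set cannot read at all (no rule applies at
    some position) are counted irregular but tallied separately so coverage
    gaps can be told apart from genuine exceptions.
    """
    if len(lexicon) == 0:
        raise EmptyLexiconError("pct_irregular needs a nonempty lexicon")
    ordered = sort_rules(rules)
    n_irr = 0
    n_no_rule = 0
    for e in lexicon:
        try:
            predicted = apply_rules(e.orthography, ordered, _sorted=True)
        except NoRuleError:
            n_no_rule += 1
            n_irr += 1
            continue
        if predicted != e.phonology:
            n_irr += 1
    return 100.0 * n_irr / len(lexicon), n_irr, n_no_rule


def pct_irregular(lexicon: Lexicon, rules: Sequence[GPCRule]) -> float:
    """Percentage of words whose rule-derived pronunciation is wrong."""
    return irregularity_detail(lexicon, rules)[0]


def induce_modal_rules(
    parses: Sequence[GraphemeParse], grain: str = "grapheme"
) -> list[GPCRule]:
    """Derive a single-mapping rule table: each grapheme's modal phonemes.

    For every grapheme observed in the parses, emit the most frequent
    phoneme mapping by type count (the rule-based stance that only the most
    frequent correspondence is stored).  ``grain="grapheme+context"``
    conditions on the following letter, emitting context-sensitive rules.
    Ties break lexicographically on the joined phoneme string.
    """
    if grain not in ("grapheme", "grapheme+context"):
        raise ValueError(f"unknown grain {grain!r}")
    counts: Counter = Counter()
    for parse in parses:
        pairs = parse.pairs
        for idx, (g, p) in enumerate(pairs):
            if grain == "grapheme":
                key = (g, None)
            else:
                following = pairs[idx + 1][0][:1] if idx + 1 < len(pairs) else None
                key = (g, following)
            counts[(key, p)] += 1
    by_key: dict = {}
    for ((g, ctx), p), n in counts.items():
        by_key.setdefault((g, ctx), []).append((p, n))
    rules = []
    for (g, ctx), options in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
        best = min(options, key=lambda pn: (-pn[1], " ".join(pn[0])))
        rules.append(GPCRule(grapheme=g, phonemes=best[0], post_context=ctx))
    return rules
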