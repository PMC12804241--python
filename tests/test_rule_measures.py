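"""Basic proxies and rule-derived complexity/unpredictability measures."""

import itertools

import pytest

from orthodepth.errors import EmptyLexiconError, NoRuleError
from orthodepth.lexicon import LexiconEntry, tokenize_phonemes
from orthodepth.rule_measures import (
    apply_rules,
    basic_summary,
    classify_rules,
    count_unique_gp_mappings,
    induce_modal_rules,
    pct_equal_length,
    pct_irregular,
)
from orthodepth.rules import GPCRule
from orthodepth.segmentation import GraphemeParse, parse_graphemes
from orthodepth.synthetic import GeneratorSpec, generate_lexicon, generate_orthography

from conftest import build_lexicon


def R(g, p, **kw):
    return GPCRule(grapheme=g, phonemes=tuple(p.split()) if p else (), **kw)


GIFT_GIST_RULES = [
    R("g", "g"), R("i", "ɪ"), R("f", "f"), R("t", "t"), R("s", "s"),
]


class TestPctEqualLength:
    def test_half(self, en_config):
        lex = build_lexicon({"cat": "kæt", "that": "θæt"}, en_config)
        assert pct_equal_length(lex) == 50.0

    def test_shallow_is_100(self):
        spec = GeneratorSpec(n_letters=12, n_words=200, seed=2)
        rules, config = generate_orthography(spec)
        lex, _ = generate_lexicon(rules, config, spec)
        assert pct_equal_length(lex) == 100.0

    def test_single_unequal_word(self, en_config):
        lex = build_lexicon({"that": "θæt"}, en_config)
        assert pct_equal_length(lex) == 0.0

    def test_empty_errors(self, en_config):
        lex = build_lexicon({}, en_config)
        with pytest.raises(EmptyLexiconError):
            pct_equal_length(lex)


class TestUniqueMappings:
    def test_one_for_t_two_for_c(self):
        parses = [
            GraphemeParse((("c", ("k",)), ("a", ("æ",)), ("t", ("t",)))),
            GraphemeParse((("c", ("s",)), ("t", ("t",)))),
        ]
        mappings = {(g, p) for parse in parses for g, p in parse.pairs}
        assert count_unique_gp_mappings(parses) == len(mappings) == 4
        assert sum(1 for g, _ in mappings if g == "c") == 2
        assert sum(1 for g, _ in mappings if g == "t") == 1

    def test_identity_lexicon_counts_letters(self):
        spec = GeneratorSpec(n_letters=10, n_words=150, seed=4)
        rules, config = generate_orthography(spec)
        lex, _ = generate_lexicon(rules, config, spec)
        parses = [parse_graphemes(e, rules) for e in lex]
        observed_letters = {ch for e in lex for ch in e.orthography}
        assert count_unique_gp_mappings(parses) == len(observed_letters)

    def test_empty(self):
        assert count_unique_gp_mappings([]) == 0


class TestClassifyRules:
    def test_one_of_each(self):
        rules = [R("t", "t"), R("th", "θ"), R("c", "s", post_context="i")]
        s = classify_rules(rules)
        assert (s.n_single, s.n_multi, s.n_context) == (1, 1, 1)
        assert all(abs(p - 100 / 3) < 0.5 for p in s.pct_each.values())
        assert abs(sum(s.pct_each.values()) - 100) < 0.5

    def test_all_single(self):
        rules = [R(ch, ch) for ch in "abcdefghijklmnopqrstuvwxyz"]
        s = classify_rules(rules)
        assert (s.n_single, s.n_multi, s.n_context) == (26, 0, 0)

    def test_recovers_generator_composition(self):
        spec = GeneratorSpec(
            n_letters=16, n_multiletter_graphemes=5, n_context_rules=3,
            silent_final_rate=0.1, n_words=50, seed=9,
        )
        rules, config = generate_orthography(spec)
        lex, truth = generate_lexicon(rules, config, spec)
        s = classify_rules(rules)
        assert s.n_multi == truth.n_multi == 5
        assert s.n_context == truth.n_context == 3
        assert s.n_single == truth.n_single


class TestApplyRulesAndIrregularity:
    def test_gift_regular_gist_irregular(self, en_config):
        assert apply_rules("gift", GIFT_GIST_RULES) == ("g", "ɪ", "f", "t")
        lex = build_lexicon({"gift": "gɪft", "gist": "dʒɪst"}, en_config)
        assert pct_irregular(lex, GIFT_GIST_RULES) == 50.0

    def test_context_rule_flips_which_word_is_irregular(self, en_config):
        with_context = GIFT_GIST_RULES + [R("g", "dʒ", post_context="i")]
        assert apply_rules("gist", with_context) == ("dʒ", "ɪ", "s", "t")
        assert apply_rules("gift", with_context) == ("dʒ", "ɪ", "f", "t")  # now wrong
        lex = build_lexicon({"gift": "gɪft", "gist": "dʒɪst"}, en_config)
        assert pct_irregular(lex, with_context) == 50.0
        gift_only = build_lexicon({"gift": "gɪft"}, en_config)
        assert pct_irregular(gift_only, GIFT_GIST_RULES) == 0.0
        assert pct_irregular(gift_only, with_context) == 100.0

    def test_no_rule_position_reported(self):
        with pytest.raises(NoRuleError) as exc:
            apply_rules("gax", [R("g", "g"), R("a", "a")])
        assert exc.value.position == 2

    def test_identity_system_has_zero_irregularity(self):
        spec = GeneratorSpec(n_letters=12, n_words=150, seed=6)
        rules, config = generate_orthography(spec)
        lex, _ = generate_lexicon(rules, config, spec)
        assert pct_irregular(lex, rules) == 0.0

    def test_injected_exception_rate_recovered(self):
        spec = GeneratorSpec(n_letters=14, n_words=2000, exception_rate=0.2, seed=12)
        rules, config = generate_orthography(spec)
        lex, truth = generate_lexicon(rules, config, spec)
        assert pct_irregular(lex, rules) == 100.0 * truth.n_exceptions / len(lex)


class TestInduceModalRules:
    def test_majority_wins(self, en_config):
        words = {f"ca{c}": f"kæ{c}" for c in "tnmp"} | {"cit": "sɪt"}
        lex = build_lexicon(words, en_config)
        rules = [R(ch, ch) for ch in "tnmp"] + [
            R("a", "æ"), R("i", "ɪ"), R("c", "k"), R("c", "s"),
        ]
        parses = [parse_graphemes(e, rules) for e in lex]
        induced = {r.grapheme: r.phonemes for r in induce_modal_rules(parses)}
        assert induced["c"] == ("k",)  # 4 of 5 words

    def test_tie_breaks_lexicographically(self):
        parses = [
            GraphemeParse((("c", ("s",)),)),
            GraphemeParse((("c", ("k",)),)),
        ]
        induced = induce_modal_rules(parses)
        assert induced[0].phonemes == ("k",)  # "k" < "s"

    def test_identity_recovered(self):
        spec = GeneratorSpec(n_letters=10, n_words=120, seed=8)
        rules, config = generate_orthography(spec)
        lex, _ = generate_lexicon(rules, config, spec)
        parses = [parse_graphemes(e, rules) for e in lex]
        for r in induce_modal_rules(parses):
            assert r.phonemes == (r.grapheme,)

    def test_modal_choice_minimizes_irregularity(self, en_config):
        # brute force: over all single-mapping-per-grapheme assignments, the
        # modal assignment leaves the fewest words with a mismatched pairing
        words = {
            "cat": "kæt", "can": "kæn", "cap": "kæp", "cit": "sɪt",
            "tat": "tæt", "tin": "tɪn",
        }
        lex = build_lexicon(words, en_config)
        base = [R(ch, ch) for ch in "tnmp"] + [
            R("a", "æ"), R("i", "ɪ"), R("c", "k"), R("c", "s"),
        ]
        parses = [parse_graphemes(e, base) for e in lex]
        options = {}
        for parse in parses:
            for g, p in parse.pairs:
                options.setdefault(g, set()).add(p)

        def n_regular(assignment):
            return sum(
                all(assignment[g] == p for g, p in parse.pairs) for parse in parses
            )

        graphemes = sorted(options)
        best = max(
            n_regular(dict(zip(graphemes, combo)))
            for combo in itertools.product(*(sorted(options[g]) for g in graphemes))
        )
        modal = {r.grapheme: r.phonemes for r in induce_modal_rules(parses)}
        assert n_regular(modal) == best


def test_basic_summary_fields(en_config):
    lex = build_lexicon({"cat": "kæt", "that": "θæt"}, en_config)
    rules = [R("th", "θ"), R("c", "k"), R("a", "æ"), R("t", "t")]
    parses = [parse_graphemes(e, rules) for e in lex]
    s = basic_summary(lex, parses)
    assert s.n_letters == len(en_config.letters)
    assert s.n_phonemes == len(en_config.phonemes)
    assert s.n_graphemes == 4
    assert s.n_unique_gp_mappings == 4
    assert s.pct_equal_length == 50.0
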