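"""Exception hierarchy for orthodepth.

Input-contract violations (bad files, symbols outside the declared
inventories) are distinguished from measure-level failures so the CLI can
map them onto different exit codes.
"""


class OrthodepthError(Exception):
    """Base class for all orthodepth errors."""


class ConfigError(OrthodepthError):
    """A language configuration violates its invariants."""


class LexiconFormatError(OrthodepthError):
    """A lexicon or rule file could not be parsed."""


class UnknownSymbolError(LexiconFormatError):
    """A symbol in an input form is not in the declared inventory."""

    def __init__(self, symbol: str, position: int, context: str = ""):
        self.symbol = symbol
        self.position = position
        msg = f"unknown symbol {symbol!r} at position {position}"
        if context:
            msg += f" in {context!r}"
        super().__init__(msg)


class EmptyLexiconError(OrthodepthError):
    """An operation that needs at least one entry got an empty lexicon."""


class NoParseError(OrthodepthError):
    """No rule sequence covers a word's orthography/phonology."""


class AmbiguousParseError(OrthodepthError):
    """Strict parsing found more than one rule segmentation."""


class NoRuleError(OrthodepthError):
    """Rule application got stuck: no rule applies at a position."""

    def __init__(self, orthography: str, position: int):
        self.orthography = orthography
        self.position = position
        super().__init__(
            f"no rule applies at position {position} of {orthography!r}"
        )


class InfeasibleSpecError(OrthodepthError):
    """A synthetic-generator spec cannot be realized."""


class MeasureError(OrthodepthError):
    """A measure could not be computed for this lexicon."""
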