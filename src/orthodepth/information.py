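"""Mutual information and efficiency of the print-to-speech mapping.

For position-aligned orthographic/phonological unit pairs pooled over a
lexicon, the mutual information I(O;P) = H(P) − H(P|O) measures how much
knowing the written unit reduces uncertainty about the spoken one, and
*efficiency* = I(O;P) / H(P) normalizes it: 1 for a perfectly transparent
system (H(P|O) = 0), 0 when print and speech are statistically unrelated.
Profiles are computed at three grain sizes: letters/phonemes,
bigrams/biphones, and graphemes/phonemes (the last needs a rule table for
grapheme parsing).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyLexiconError, MeasureError
from .lexicon import Lexicon
from .rules import GPCRule
from .segmentation import SILENT, align_positional, parse_graphemes

log = logging.getLogger(__name__)

__all__ = [
    "EfficiencyProfile",
    "joint_counts",
    "mutual_information",
    "efficiency_profile_all",
    "LEVELS",
]

LEVELS = ("letters", "bigrams", "graphemes")


@dataclass(frozen=True)
class EfficiencyProfile:
    """H(P), H(P|O), I(O;P) and efficiency at one unit grain size."""

    level: str
    h_p: float
    h_p_given_o: float
    mi: float
    efficiency: float
    n_observations: int


def joint_counts(
    lexicon: Lexicon,
    level: str = "letters",
    *,
    rules: Optional[Sequence[GPCRule]] = None,
    windows: str = "overlapping",
    allow_mismatch: bool = True,
) -> Counter:
    """Pooled co-occurrence counts of (orthographic unit, phonological unit).

    Every aligned pair in every word is one observation — the two *d*'s of
    *dad* count separately.  At the grapheme level the phonological unit is
    the grapheme's full phoneme sequence as one token, with silent graphemes
    pairing with an explicit null token.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    counts: Counter = Counter()
    if level == "graphemes":
        if rules is None:
            raise MeasureError("grapheme-level counts need a GPC rule table")
        for e in lexicon:
            parse = parse_graphemes(e, rules, allow_mismatch=allow_mismatch)
            for g, p in parse.pairs:
                counts[(g, " ".join(p) if p else SILENT)] += 1
    else:
        for e in lexicon:
            for o, p in align_positional(e, level, windows=windows).pairs:
                counts[(o, p)] += 1
    return counts


def mutual_information(counts: Counter, level: str = "") -> EfficiencyProfile:
    """Efficiency profile from a joint count table (maximum likelihood).

    H(P) comes from the marginal phonological-unit distribution,
    H(P|O) = Σ_o P(o) H(P|O=o), and I(O;P) = H(P) − H(P|O); the equivalent
    joint-sum form Σ p(o,p) log2[p(o,p)/(p(o)p(p))] is computed as a
    cross-check on every call.
    """
    if not counts:
        raise EmptyLexiconError("empty co-occurrence table")
    o_labels = sorted({o for o, _ in counts})
    p_labels = sorted({p for _, p in counts})
    o_idx = {o: i for i, o in enumerate(o_labels)}
    p_idx = {p: i for i, p in enumerate(p_labels)}
    table = np.zeros((len(o_labels), len(p_labels)))
    for (o, p), n in counts.items():
        table[o_idx[o], p_idx[p]] = n
    joint = table / table.sum()
    p_o = joint.sum(axis=1)
    p_p = joint.sum(axis=0)

    def _h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    h_p = _h(p_p)
    h_p_given_o = float(
        sum(p_o[i] * _h(joint[i] / p_o[i]) for i in range(len(o_labels)) if p_o[i] > 0)
    )
    mi = h_p - h_p_given_o
    # joint double-sum formulation, kept as a per-call numerical cross-check
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / np.outer(p_o, p_p)
        terms = np.where(joint > 0, joint * np.log2(np.where(joint > 0, ratio, 1.0)), 0.0)
    mi_direct = float(terms.sum())
    if abs(mi - mi_direct) > 1e-9:  # pragma: no cover - numerical guard
        raise MeasureError(
            f"MI decomposition mismatch: {mi} vs joint-sum {mi_direct}"
        )
    if h_p == 0.0:
        warnings.warn("H(P) = 0: efficiency undefined, reporting 1", stacklevel=2)
        efficiency = 1.0
    else:
        efficiency = mi / h_p
    return EfficiencyProfile(
        level=level,
        h_p=h_p,
        h_p_given_o=max(h_p_given_o, 0.0),
        mi=mi,
        efficiency=efficiency,
        n_observations=int(table.sum()),
    )


def efficiency_profile_all(
    lexicon: Lexicon,
    rules: Optional[Sequence[GPCRule]] = None,
    *,
    windows: str = "overlapping",
    allow_mismatch: bool = True,
) -> dict[str, EfficiencyProfile]:
    """Efficiency profiles at all three grain sizes (graphemes need rules)."""
    profiles = {}
    for level in LEVELS:
        if level == "graphemes" and rules is None:
            log.info("skipping grapheme-level profile: no rule table")
            continue
        counts = joint_counts(
            lexicon, level, rules=rules, windows=windows, allow_mismatch=allow_mismatch
        )
        profiles[level] = mutual_information(counts, level)
    return profiles
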