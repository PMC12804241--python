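"""Distance-based depth: orthography–phonology consistency (OPC).

OPC asks how phonologically similar a word is to the words spelled most
like it.  Orthographic neighbors are words at letter-level Levenshtein
distance exactly 1 (substitution, insertion, or deletion — *mints* is a
neighbor of *mint*); a word's OPC is the mean phoneme-token Levenshtein
distance from its pronunciation to its neighbors' pronunciations.  In the
classic toy lexicon, *mint* /mɪnt/ with neighbors *mints, tint, mist, hint,
pint* scores (1+1+1+1+2)/5 = 1.2, /pɑɪnt/ being the distance-2 outlier.
Silent-letter homophone pairs (French *chat*/*chats*, both /ʃa/) contribute
distance 0 and can pull the lexicon mean below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyLexiconError, MeasureError
from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "OPCResult",
    "levenshtein",
    "orthographic_neighbors",
    "opc_word",
    "mean_opc",
]


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance between two symbol sequences.

    Works on letter strings and on phoneme-token tuples alike; tokens are
    compared whole, so /ɑɪ/ as one token differs from /ɑ/ /ɪ/ as two.
    """
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, sa in enumerate(a, start=1):
        cur = [i]
        for j, sb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # deletion
                    cur[j - 1] + 1,  # insertion
                    prev[j - 1] + (sa != sb),  # substitution / match
                )
            )
        prev = cur
    return prev[-1]


class _NeighborIndex:
    """Distance-1 neighbor lookup via single-edit candidate generation.

    All words one substitution, insertion, or deletion away are enumerated
    over the letter inventory and matched against an orthography index —
    linear in word length times alphabet size rather than in lexicon size.
    """

    def __init__(self, lexicon: Lexicon):
        self.by_orth: dict[str, list[int]] = {}
        for i, e in enumerate(lexicon):
            self.by_orth.setdefault(e.orthography, []).append(i)
        self.alphabet = sorted(lexicon.config.letters)
        self.lexicon = lexicon

    def neighbors(self, entry: LexiconEntry) -> list[LexiconEntry]:
        w = entry.orthography
        cand: set[str] = set()
        for i in range(len(w)):
            cand.add(w[:i] + w[i + 1 :])  # deletion
            for ch in self.alphabet:
                cand.add(w[:i] + ch + w[i + 1 :])  # substitution
        for i in range(len(w) + 1):
            for ch in self.alphabet:
                cand.add(w[:i] + ch + w[i:])  # insertion
        cand.discard(w)
        out = []
        for c in sorted(cand):
            for idx in self.by_orth.get(c, ()):
                out.append(self.lexicon[idx])
        # homographs of the word itself are neighbors at distance 0, not 1;
        # same-spelling entries are excluded wholesale by cand.discard(w)
        return out


def orthographic_neighbors(entry: LexiconEntry, lexicon: Lexicon) -> list[LexiconEntry]:
    """All other entries at orthographic Levenshtein distance exactly 1."""
    return _NeighborIndex(lexicon).neighbors(entry)


def opc_word(
    entry: LexiconEntry,
    lexicon: Lexicon,
    *,
    _index: Optional[_NeighborIndex] = None,
) -> float:
    """Mean phonological Levenshtein distance to the word's orthographic neighbors.

    Raises
    ------
    MeasureError
        If the word has no distance-1 neighbor (callers exclude such words).
    """
    index = _index if _index is not None else _NeighborIndex(lexicon)
    nbrs = index.neighbors(entry)
    if not nbrs:
        raise MeasureError(f"{entry.orthography!r} has no orthographic neighbors")
    return float(
        np.mean([levenshtein(entry.phonology, n.phonology) for n in nbrs])
    )


@dataclass(frozen=True)
class OPCResult:
    """Per-word OPC values for a sample and their mean."""

    per_word: dict[int, float]  # lexicon index -> mean neighbor distance
    mean_opc: float
    n_sampled: int
    n_excluded: int  # sampled words with no orthographic neighbor
    seed: Optional[int]


def mean_opc(
    lexicon: Lexicon,
    sample_size: int = 1000,
    seed: Optional[int] = None,
) -> OPCResult:
    """Lexicon-level OPC from a uniform random sample of words.

    ``min(sample_size, |lexicon|)`` entries are drawn without replacement
    under ``seed``; sampled words without any orthographic neighbor are
    excluded from the mean and reported in ``n_excluded``.
    """
    if len(lexicon) == 0:
        raise EmptyLexiconError("mean_opc needs a nonempty lexicon")
    rng = np.random.default_rng(seed)
    n = min(sample_size, len(lexicon))
    idx = sorted(rng.choice(len(lexicon), size=n, replace=False).tolist())
    index = _NeighborIndex(lexicon)
    per_word: dict[int, float] = {}
    n_excluded = 0
    for i in idx:
        try:
            per_word[i] = opc_word(lexicon[i], lexicon, _index=index)
        except MeasureError:
            n_excluded += 1
    if not per_word:
        raise MeasureError("every sampled word is neighbor-less")
    return OPCResult(
        per_word=per_word,
        mean_opc=float(np.mean(list(per_word.values()))),
        n_sampled=n,
        n_excluded=n_excluded,
        seed=seed,
    )
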