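# Methods

This note records the conventions, parameter choices, and known limits of
each measure. Everything here is implemented and exercised by the test
suite; nothing is reported that the code does not compute.

## Input model

A lexicon is a set of (orthography, phonology, optional frequency) entries
under a language configuration that declares the letter inventory
(diacritic letters such as *ř* are atomic, never decomposed), the phoneme
inventory (tokens may be multi-character: /ɑɪ/, /tʃ/), the vowel subsets on
both sides, optional syllabic consonants (Czech /r̩/ in *krk*), and
suprasegmental marks to strip on load (stress, stød, length marks if the
analyst so decides). Input is UTF-8, NFC-normalized; orthography is
case-folded to lower case (transcriptions are left as-is, since case can
be distinctive in transcription schemes). Exact duplicate rows merge with
frequencies summed; homophones and homographs stay distinct.

**Phoneme tokenization** is greedy longest-match against the inventory.
No tokenizer convention is universal; longest-match is deterministic,
auditable, and exact whenever no inventory token is a proper prefix of
another (the property-test regime). Configs must therefore list diphthongs
and affricates as explicit tokens.

**Monosyllable filter**: a word is monosyllabic iff its transcription
contains exactly one maximal run of nucleus phonemes (vowel phonemes ∪
syllabic consonants). All measures are defined on monosyllables;
`compute_all` applies the filter and reports how much was dropped.
Per-language cleaning steps (loanword or abbreviation exclusion) are left
to the user's preprocessing — the toolkit deliberately hard-codes none.

## Segmentation conventions

**Grapheme parsing** is phonology-constrained: rules consume both the
spelling and the attested pronunciation, because the measures need the
attested pairing, not a prediction. Rule precedence is specific-before-
general: longer grapheme first; at equal length context-sensitive before
context-free; remaining ties by file order. Silent letters are graphemes
mapping to the empty phoneme sequence; split graphemes (*a_e*) are *not*
modeled as discontinuous units — *a_e* words parse as vowel letter plus
silent *e*, a known open issue in the field. Strict mode raises on parses
that remain ambiguous after precedence; lenient mode takes the
highest-precedence parse.

Irregular words have, by definition, no exact rule parse. The
`allow_mismatch` mode (used by the lexicon-level measures) finds the
segmentation minimizing the number of non-rule pairings, letting a rule's
grapheme pair with a phoneme span of length 0..|rule phonemes|+1 at cost 1.
This reconstructs, reproducibly, what per-word manual coding does in
practice, and is what lets *pint* contribute its (i, /ɑɪ/) pairing to the
unique-mapping count and the grapheme-level information measures.

**Syllable parsing**: orthographic onset = letters before the first vowel
letter; vowel grapheme = first maximal vowel-letter run; body = vowel
grapheme + remaining letters; the phonological split is analogous over
nucleus phonemes. Vowel-initial words have an empty onset, which acts as
its own conditioning context.

**Positional alignment** pairs the i-th letter with the i-th phoneme;
trailing unmatched letters are discarded (*e* in *bite*), and trailing
unmatched phonemes symmetrically when |P| > |O|. Bigrams/biphones are
overlapping windows over the already-aligned sequences by default
(`windows="disjoint"` is available); no boundary padding is added. The
windowing choice is genuinely open in the literature, which is why it is a
switch rather than a constant.

## Measure conventions

* All probabilities are **type-based** by default (each word counts once);
  `weighted=True` switches to token-frequency weighting. Lexicon-level
  averages over words are unweighted means of per-word values.
* **Consistency** counts the word itself among its friends: value =
  (sharers of the unit with the same pronunciation, incl. self) / (all
  sharers, incl. self). This is what makes the canonical 1-vs-3 body
  family give 0.25 for the minority word. Words whose unit is unique score
  1 (self only) and are tallied.
* **Entropy** is log base 2; p = 0 terms contribute 0. Onset entropy
  weights each initial letter's first-phoneme entropy by the probability
  that a word starts with that letter. Vowel entropy averages per-unit
  (or per-unit-in-context) entropies weighted by occurrence counts;
  conditioning is on the **full** onset or coda letter string. With count
  weighting the law of total entropy guarantees conditional ≤ context-
  independent, a property the suite checks on randomized lexicons.
* **Mutual information** pools all positions into one joint count table
  (one number per lexicon requires pooling; repeated letters are separate
  observations). Probabilities are maximum likelihood, no smoothing, so
  the transparency identities (H(P|O) = 0, efficiency = 1) are exact. The
  H(P) − H(P|O) decomposition is cross-checked against the joint double
  sum Σ p(o,p) log₂[p(o,p)/(p(o)p(p))] on every call (tolerance 1e-9).
  If H(P) = 0 the efficiency ratio is undefined; it is reported as 1 with
  a warning. Grapheme-grain phonological units are each grapheme's full
  phoneme sequence as one token, with an explicit null token for silent
  graphemes. A speech-to-print direction is a trivially symmetric variant
  (swap the table axes) and is not separately validated.
* **OPC**: orthographic neighbors are entries at letter-level Levenshtein
  distance exactly 1 (substitutions, insertions, and deletions — *mints*
  neighbors *mint*), excluding same-spelling entries; homograph neighbors
  contribute one token each. Phonological distance is unit-cost
  Levenshtein over phoneme **tokens**, so /ɑɪ/ counts as one symbol.
  The lexicon mean is computed over a uniform sample without replacement
  (default 1000 words) under a mandatory seed; sampled words with no
  neighbor are excluded from the mean and their count reported. Neighbor
  lookup enumerates single-edit candidates over the letter inventory
  against a hash index, so 1000-word samples over 5000-word lexicons run
  in seconds.
* **Irregularity**: a word is irregular when deterministic left-to-right
  rule application (highest-precedence applicable rule at each position)
  disagrees with the attested phonology, compared after suprasegmental
  stripping. Words the rule set cannot read at all count as irregular but
  are tallied separately, so coverage gaps are distinguishable from
  genuine exceptions. Rule counts are type counts. Because curated rule
  tables are unavoidably analyst choices, the toolkit accepts user tables
  as ground truth and offers `induce_modal_rules` (modal mapping per
  grapheme, ties broken lexicographically) as a reproducible default.

## The synthetic generator

The generator's job is to realize the two depth dimensions independently,
with exact ground truth.

* Core: a bijective letter ↔ phoneme identity mapping; words are
  CVC-skeleton monosyllables (onset consonant unit, one vowel letter, coda
  consonant units) with letter lengths in `word_length_range` (default
  3–5, the typical monosyllable range; silent-final twins may exceed the
  upper bound by one). About 20% of letters are vowels (≥ 2, so exceptions
  have an alternative nucleus available).
* **Complexity knobs**: `n_multiletter_graphemes` consonant digraphs each
  mapping to one new phoneme; `n_context_rules` consonant readings
  conditioned on the following vowel letter; `silent_final_rate`, which
  pairs words with silent-final twins pronounced identically (guaranteed
  homophone neighbor pairs — the mechanism that pushes mean OPC below 1,
  as silent-letter-rich orthographies show). None of these create
  irregular words: every word's attested phonology is *defined* as the
  rule-derived reading.
* **Unpredictability knob**: with probability `exception_rate` a word's
  nucleus vowel phoneme is replaced by a different vowel phoneme — one
  unit, one token for one token, so word lengths and the equal-length
  proxy are untouched and the exception count is exactly Binomial(n, ε).
* All randomness flows from the single spec seed through two named
  generator streams (rule construction, word sampling); identical specs
  give byte-identical fixtures.

What the generator does **not** emulate: real phonotactics, frequency
distributions, morphology, loanword strata, or split graphemes. Passing
recovery tests therefore shows the measures are computed correctly and
respond to the right structural causes — not that any real language's
published value would be reproduced, which additionally depends on corpus
composition and rule-table curation.

## Reports and comparison

`compute_all` restricts to monosyllables, parses, runs every measure, and
serializes deterministically (sorted keys; fixed seeds recorded in the
provenance block together with config/rule hashes and the toolkit
version). Individual measure failures downgrade to skipped-with-reason.

`correlate_and_project` takes ≥ 3 reports, standardizes the measure matrix
(zero mean, unit variance), computes Pearson correlations, and runs a PCA
on the correlation matrix — appropriate for the mixed scales (percentages,
bits, ratios). Constant or missing columns are dropped with a warning.
Component signs are fixed by forcing each component's largest-magnitude
loading positive, since biplot signs are otherwise arbitrary. With few
languages the CLI prints a "descriptive only" caveat (threshold 30); no
inferential statistics are attached, deliberately.

## Problem sizes and numerics

The validation suite uses 5000-word lexicons for exact transparency
ceilings and binomial recovery (99% CI at ε ∈ {0, .05, .1, .2, .4} × 3
seeds), 1200–1500-word lexicons for monotonicity and dissociation checks,
and 100 small randomized lexicons for the entropy-conditioning inequality
— sizes at which every check is stable and the whole suite runs in well
under a minute. Exact-equality assertions (efficiency = 1, OPC = 1,
H(P|O) = 0) rely on maximum-likelihood counting with no smoothing;
inequality checks carry 1e-9/1e-12 float guards. Levenshtein is verified
against exhaustive edit-script recursion (all pairs, length ≤ 3) and an
independent C implementation (all pairs, length ≤ 5).

## Known limitations

* Monosyllables only; no polysyllabic aggregation is offered.
* Split graphemes are not discontinuous units (see above).
* Greedy tokenization can fail on inventories with adversarial prefix
  overlap; such rows raise a clear error rather than guessing.
* The bigram/biphone windowing convention and the OPC sampling protocol
  are analyst choices; both are explicit parameters with logged defaults.
* Rule-based measures inherit the arbitrariness of the rule table; the
  modal-induction helper makes that arbitrariness reproducible, not
  absent.
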