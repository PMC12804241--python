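# orthodepth

Quantitative measures of **orthographic depth** — how closely an alphabetic
writing system's spellings track its pronunciations — computed from a
pronunciation lexicon (one row per word: spelling, phonemic transcription,
optional frequency).

Cross-linguistic reading research needs depth quantified objectively, and
depth is not one number: it splits into **complexity** (how large the
orthographic units must be before pronunciation becomes predictable —
multiletter graphemes like *th*, context-sensitive readings like *c[i]* →
/s/, silent letters) and **unpredictability** (the inconsistency that
remains even once unit size is accounted for — *mint* /mɪnt/ vs *pint*
/pɑɪnt/). This package implements the full battery of measures used to map
those two dimensions, for researchers in psycholinguistics and the
cognitive science of reading:

| family | measures |
| --- | --- |
| basic proxies | % words with equal letter and phoneme counts; number of unique grapheme–phoneme pairings |
| rule-based | rule-class counts (single-letter / multiletter / context-sensitive); % irregular words under a GPC rule table; modal-rule induction |
| statistical | vowel and body consistency (friends / (friends + enemies)); Shannon entropy H(X) = −Σ pᵢ log₂ pᵢ of unit pronunciations: onset entropy, and context-independent / onset-conditional / coda-conditional vowel entropy |
| information-theoretic | mutual information I(O;P) = H(P) − H(P∣O) and efficiency I(O;P)/H(P) at letter/phoneme, bigram/biphone, and grapheme/phoneme grain |
| distance-based | OPC: mean phoneme-level Levenshtein distance from a word to its orthographic distance-1 neighbors |

All measures operate on monosyllabic words. A synthetic-orthography
generator with independent complexity and unpredictability knobs provides
ground truth for every measure, so the whole battery is testable without
licensed corpora (CELEX-style resources cannot be redistributed).

## Worked example

Generate an artificial orthography that is moderately complex (4 digraph
graphemes) and moderately unpredictable (15% exception words), then run
every measure:

```python
from orthodepth import GeneratorSpec, compute_all, generate_lexicon, generate_orthography

spec = GeneratorSpec(
    n_letters=16, n_words=2000, n_multiletter_graphemes=4,
    exception_rate=0.15, seed=42,
)
rules, config = generate_orthography(spec)
lexicon, truth = generate_lexicon(rules, config, spec)
report = compute_all(lexicon, rules, seed=42, sample_size=1000)
vec = report.measure_vector()
for k in ("pct_equal_length", "pct_irregular", "vowel_consistency",
          "entropy_ci", "efficiency_letters", "efficiency_graphemes", "mean_opc"):
    print(f"{k:22s} {vec[k]:.3f}")
```

prints

```
pct_equal_length       66.450
pct_irregular          12.650
vowel_consistency      0.771
entropy_ci             0.673
efficiency_letters     0.696
efficiency_graphemes   0.959
mean_opc               1.304
```

Reading the numbers: the digraphs drag the equal-length proxy and
letter-level efficiency down (complexity), while the injected exceptions
show up as ~13% irregular words, vowel consistency below 1, positive vowel
entropy, grapheme-level efficiency below 1, and a mean OPC above 1
(unpredictability). A perfectly transparent orthography scores 100 / 0 /
1 / 0 / 1 / 1 / 1 on the same columns.

## Command line

```bash
orthodepth simulate --spec spec.yaml --out-dir fixture/       # synthetic lexicon + config + rules + ground truth
orthodepth compute  --lexicon lex.tsv --config lang.yaml \
                    --rules rules.tsv --seed 1 --out report.json
orthodepth compare  --reports reports/ --out summary.json --plot biplot.svg
```

`compute` writes one JSON depth report per lexicon; `compare` builds the
languages × measures matrix, its correlation matrix, and a 2-component PCA
(the analysis that separates the unpredictability measures from the
complexity measures). Exit codes: 2 for input errors, 3 if a measure
failed unexpectedly (it is skipped with a reason in the report).

Input formats: TSV/CSV lexicons with a header row (UTF-8, IPA-like
transcriptions tokenized by greedy longest match against the declared
phoneme inventory), a YAML/JSON language configuration declaring letter and
phoneme inventories, and an optional GPC rule table
(grapheme / phonemes / position / contexts).

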