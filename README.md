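# rwov — Relevant Word Order Vectorization for clinical free text

Pathology reports and similar electronic-health-record fields carry decisive
facts — "is this tumor estrogen-receptor positive?" — in short, semi-structured
free text: "ER+", "positive staining for ER", "ER: Positive (85%)",
"tumor cells are positive for CK7 and MOC31, negative for CK5/6, TTF-1, CK20,
ER and PR". Bag-of-words features discard exactly the information that
disambiguates such text: *where* a polarity word sits relative to the marker
being asked about. `rwov` implements a positional vectorization designed for
this setting, together with the baselines and the statistical machinery needed
to evaluate classifiers on it under class imbalance.

## The vectorization

Fix a **term of interest** (TOI), e.g. the token `er`, matched in text along
with its aliases ("estrogen receptor", ...). From the corpus, take the k = 30
**relevant words** — the tokens co-occurring most frequently with the TOI.
Each text block *i* becomes a row over those words; the cell for word *j* is

    T(i, j) = 0                     if word j does not occur in block i
    T(i, j) = ±1/(d + 1)            otherwise,

where *d* is the number of relevant-word occurrences strictly between word
*j*'s closest occurrence and the TOI anchor, and the sign records whether the
word lies before (−) or after (+) the TOI. Values decay nonlinearly from ±1
(adjacent to the TOI) toward 0 (absent), so a classifier sees not just *which*
cue words occur but their ordering relative to the marker of interest.

Around the core the package provides:

- **`rwov.normalize`** — sentence/word-symbol tokenization, stop-word removal
  (`the, are, of, as, is, and, or, report, pathology`), symbol substitution
  (`"," → comm`, `"/" → slash`, `"+" → plu`), polarity-qualified percentage
  collapsing (`Positive (85%)` → `pospct`), Porter stemming.
- **`rwov.vocab`** — TOI alias matching (longest match wins) and relevant-word
  selection with per-observation mean frequencies.
- **`rwov.core`** — the signed reciprocal-distance matrix.
- **`rwov.baselines`** — IDF-weighted n-gram counts and mean-pooled skip-gram
  document embeddings, for comparison on identical preprocessing.
- **`rwov.evaluate`** — per-class F1 and Mann–Whitney AUC, stratified
  percentile-bootstrap CIs, stratified 3-fold cross-validation with shared
  splits across methods, and the DeLong test for correlated AUC differences
  (cross-checked against R's `pROC`).
- **`rwov.synth`** — a seeded generator of labelled pathology-report-like text
  (real corpora of this kind are protected health information), with a
  rule-based extractor proving every generated report is label-consistent.

## Worked example

```bash
python examples/02_rwov_features.py
```

```
top 10 relevant words (mean occurrences per observation):
  .        4.29
  for      2.34
  posit    1.56
  neg      1.55
  comm     1.39
  ...

report: CK7-. HER2: Negative (0%). Progesterone receptor positive.
Positive staining for TTF-1. Positive for CK5/6. ER+. Ki-67 is reported 7%.
nonzero features (signed 1/(d+1) relative to the first 'er' mention):
  {'.': -1.0, 'for': -0.2, 'posit': -0.167, 'neg': -0.056, ..., 'plu': 1.0, ...}
```

The `plu` (“+”) column is +1.0: a “+” immediately follows `er` with no
relevant word between them — the report says "ER+". The `neg` column is
−0.056: the nearest "negative" lies 17 relevant words *before* the ER
mention (it belongs to HER2, not ER), so it contributes almost nothing.
A bag-of-words row for this report would contain both `posit` and `neg`
counts with no way to tell which receptor they describe.

`examples/03_evaluate_and_compare.py` trains the package's 50/50/100 ReLU
network on RWOV features and on IDF-weighted unigram+bigram counts over
identical folds (ER task, 400 synthetic reports):

```
RWOV        ER=NEG: F1 0.912 [0.870, 0.951]  AUC 0.973 [0.926, 0.991]
RWOV        ER=POS: F1 0.981 [0.972, 0.991]  AUC 0.980 [0.949, 0.996]
ngram(1,2)  ER=NEG: F1 0.346 [0.254, 0.447]  AUC 0.679 [0.601, 0.732]
ngram(1,2)  ER=POS: F1 0.814 [0.786, 0.844]  AUC 0.652 [0.573, 0.707]
DeLong RWOV vs ngram(1,2) (ER=NEG): p = 5.45e-17
```

and `examples/04_interleaving_mechanism.py` shows the mechanism: raising the
generator's interleaving level (more biomarkers between a receptor and its
polarity cue) costs the unigram bag 0.12 macro-F1 while RWOV is unaffected.

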