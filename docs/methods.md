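# Methods

This note records the scientific and numerical choices behind the package:
the vectorization and its conventions, the evaluation statistics, what the
synthetic-report generator does and does not emulate, and known limitations.

## Normalization

A block (one report) is split into sentences by a rule — terminal
punctuation followed by whitespace and an uppercase letter, digit or opening
parenthesis — then into word/symbol tokens: alphanumeric runs with internal
hyphens survive intact (`ki-67`, `her-2`), every other non-space character
is its own token. Blocks are processed as **one token stream**: sentence
boundaries do not reset positions, because the vectorization below is
defined over the whole block.

Stop words (`the, are, of, as, is, and, or, report, pathology`) are removed
by the **raw lowercased** token. Stemming happens afterwards, so a stem may
coincide with a stop word (`reported → report`); this is intended — the
root carries signal even when its exact surface form was excluded.

Symbol substitutions map `","→comm`, `"/"→slash`, `"+"→plu` before
stemming, first matching pattern wins. A percentage within three tokens
after a polarity word in the same sentence collapses to `pospct`/`negpct`
("Positive (85%)" → `posit ( pospct )`); an unqualified percentage stays as
its number and `%` tokens. These identifier conventions are stated rules of
this package, not reconstructions of any particular institution's pipeline.

The stemmer is the classic Porter iterated suffix-stripper, implemented in
`rwov._porter` and selectable per config (`stemmer="porter"|"none"`). Any
fixed suffix-stripping scheme works for the method; what matters is that
the corpus and the TOI aliases are normalized with the same config (alias
phrases are compiled through the full pipeline before matching).

## TOI matching and relevant words

A TOI is a canonical token plus alias token-tuples; built-ins are
`er` (aliases "estrogen", "estrogen receptor"), `pr` ("progesterone
receptor") and `her2` ("her-2", "her/" — which tokenizes to
`("her", "slash")` and therefore also anchors "HER/neu" spellings).
Matching scans left to right, longest pattern first, non-overlapping.

The k = 30 relevant words are the most frequent tokens inside TOI-containing
blocks. Counting conventions, fixed and deterministic:

- positions covered by TOI matches are excluded, except that every match
  after the first in a block counts as one occurrence of the canonical
  token — repeated TOI mentions are informative, the anchor itself is not;
- the mean frequency divides by the total number of observations m (not by
  TOI-containing blocks);
- ties at the cut rank break lexicographically.

## The signed reciprocal-distance matrix

Cell (i, j) is 0 if word j is absent from block i, else ±1/(d+1) with d the
number of relevant-word **occurrences** (types are not deduplicated)
strictly between j's occurrence and the anchor. Conventions where the
formula is silent, all fixed and documented:

- **anchor** = first TOI occurrence in the block;
- **sign**: before the anchor → negative, after → positive;
- **multiple occurrences of j**: the occurrence minimizing d wins (largest
  magnitude, "as close as possible"); an exact tie between a before- and an
  after-occurrence resolves to after;
- endpoints are excluded from d (strict betweenness); other TOI mentions
  between j and the anchor count toward d exactly when the canonical token
  is itself in the relevant list;
- a block lacking the TOI, or an empty normalized block, yields a zero row.

The implementation is O(L·k) per block via a prefix count of relevant
occurrences; tests check exact agreement with a brute-force enumerator on
10,000 random blocks and on all 4-symbol blocks of length ≤ 6.

## Baselines

N-gram counts (ranges (1,2), (2,2), (1,3), (2,3), (3,3)) are produced by
scikit-learn's `CountVectorizer` over the already-normalized token streams;
IDF weighting is the smoothed dialect ln((1+N)/(1+df)) + 1 with no length
normalization, so a term present everywhere gets the floor weight 1.

Skip-gram document features come from a compact in-package SGNS trainer
(numpy SGD, unigram^0.75 noise distribution, seeded, single-threaded):
word vectors of dimension 100, window 6, 5 negative samples, 5 epochs,
min-count 1 — small-corpus settings. A document is the unweighted mean of
its in-vocabulary token vectors; a document with none gets a zero vector.
Mean pooling is a stated convention: nothing in the method itself dictates
how word vectors become document features.

## Classifiers and evaluation

One binary model is trained **per class** (positive-vs-rest for each
receptor state), because under imbalance users may care about either class.
The neural network is a multilayer perceptron with three ReLU hidden layers
of 50, 50 and 100 units and a logistic output; it is trained with the
full-batch lbfgs solver, L2 penalty λ = 0.01, up to 2000 iterations and a
fixed seed. Solver and λ were fixed once by a small grid on independently
generated tuning corpora and then frozen — the recommended defaults, in the
same spirit as fixing hyperparameters on held-out data before the study
proper. The SVM baseline is an RBF-kernel SVC with inverse-class-frequency
weighting; its ranking scores are decision-function values.

Metrics:

- **F1** from confusion counts, 0 when tp = 0 (including tp=fp=fn=0). The
  classification threshold is 0.5 on the probability scale and 0 on the SVM
  decision scale — F1 is threshold-dependent and the threshold is a stated
  convention.
- **AUC** is the Mann–Whitney probability estimate with ties at 1/2,
  computed from ranks; it equals pair enumeration exactly.
- **Cross-validation** is stratified 3-fold with shuffling fixed by seed;
  fold assignments are exposed and reused so every method is scored on
  identical train/test splits. Reported F1/AUC are per-fold averages.
- **Bootstrap CIs** are stratified percentile intervals (positives and
  negatives resampled separately, so every resample retains both classes),
  B = 2000 by default, computed on pooled out-of-fold scores.
- **DeLong test**: placement-value covariance estimate of the paired AUC
  difference, z against the standard normal, two-sided. Degenerate variance
  returns p = 1 with a warning. The implementation agrees with R `pROC`'s
  `roc.test(..., method="delong", paired=TRUE)` to ~1e-10 on fixed data,
  and with an exact 2^n sign-flip permutation oracle at n = 12 to within
  the normal approximation's accuracy (|Δp| ≲ 0.1 at moderate p; at such
  sample sizes the approximation, not Monte-Carlo error, dominates).

## Synthetic report generator

Real hormone-receptor corpora are PHI and not distributable, so the
generator is a first-class module: it emulates the phrasing families seen
in breast-cancer pathology reports — `ER+` / `ER-`, "estrogen receptor
positive", "positive (staining) for ER", bare percentages ("ER: 30%",
0% for negative), colon-qualified forms ("ER: Positive (85%)",
"ER: Negative (0%)"), grouped polarity lists over receptors and distractor
markers (CK7, MOC31, CK5/6, TTF-1, CK20, plus Ki-67 percentages), and the
HER2 equivocal-then-FISH follow-up ("HER2: Equivocal (2+). FISH analysis
for HER2/neu was performed and was reportedly negative.").

Defaults, chosen once as the study conditions:

- n = 600 reports; per-receptor positive prevalences ER 0.781, PR 0.661,
  HER2 0.183 (drawn independently; an institution's real statuses are
  correlated — a deliberate simplification);
- 3–10 biomarkers per report, binomially shifted by the interleaving level;
- `interleaving = 0.5`: the probability that polar mentions are grouped
  into shared positive/negative lists, and the difficulty knob for the
  mechanism study (0.1 vs 0.9 there);
- HER2 equivocal+FISH rate 0.1;
- style weights colon 0.45, plus 0.20, spelled 0.10, for 0.10, staining
  0.10, percent 0.05 — a stereotyped-institution profile anchored to the
  per-observation token-frequency fingerprints real report collections
  show (qualified-percent identifiers and commas near one per report,
  "+" around a third, bare numbers rare). A uniform style draw is
  unrealistic for a single institution and starves rare templates of
  training examples at these sample sizes;
- noise off: every report is internally consistent, verified by a
  rule-based reference extractor whose exact agreement with stored labels
  is asserted on every test corpus (the closure property).

What the generator does **not** emulate: section headers and longitudinal
structure, typos and OCR noise, receptor-status correlation, vocabulary
drift between institutions. Passing recovery tests therefore demonstrate
that the pipeline extracts positional structure the templates contain; they
do not certify performance on any real institution's text.

## Problem sizes and determinism

Test and example workloads are sized for a single CPU: recovery runs use
n = 600 with 3-fold CV; the mechanism comparison pairs 10 seeds at n = 300;
bootstrap coverage uses 500 datasets of n = 200 with B = 500 resamples;
DeLong calibration uses 1000 null simulations at n = 200. Every stochastic
component (generator, folds, bootstrap, embeddings, network init) is
seeded, and fixed seeds reproduce results bit-for-bit on one thread.

## Known limitations

- **Nearest-occurrence masking.** Each column keeps only the occurrence of
  its word closest (in relevant-word count) to the anchor. A distant but
  decisive cue can therefore be invisible: in "ER: Positive … HER2:
  Equivocal (2+) … FISH … reportedly positive", the ER "positive" lies
  closer to the HER2 anchor than the FISH verdict, so the `posit` column
  reflects the wrong mention. Equivocal-then-FISH-**negative** reports
  remain recognizable (the late "negative" is usually the nearest one and
  sits after the anchor), and the package classifies them reliably; the
  FISH-positive counterpart surrounded by positive IHC lines is a genuine
  blind spot of the representation.
- A single anchor (first TOI mention) per block; multi-TOI joint features
  are out of scope.
- Raw co-occurrence frequency selects the vocabulary; no statistical
  relevance weighting.
- The skip-gram baseline is known to be weak at these corpus sizes; it is
  included for comparison-harness parity, not as a tuned competitor.
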