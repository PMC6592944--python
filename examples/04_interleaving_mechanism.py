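"""Why positional features help: robustness to biomarker interleaving.

Generates two corpora that differ only in how strongly biomarker mentions
are interleaved (grouped "positive for A, B and C, negative for D and E"
lists with many biomarkers vs mostly standalone mentions), then compares how
much a unigram bag-of-words and RWOV lose when interleaving rises. Bag
counts cannot tell WHICH receptor sits in which polarity list; signed
distances can.
"""

import numpy as np

from rwov import (
    ClassifierConfig,
    NGramConfig,
    SyntheticConfig,
    cross_validate,
    generate_corpus,
    ngram_features,
    normalize_corpus,
    rwov_features,
)


def macro_f1(level, featurizer):
    reports = generate_corpus(SyntheticConfig(n=300, seed=1000, interleaving=level))
    sequences = normalize_corpus(reports)
    labels = np.array([r.labels["er"] for r in reports])
    rep = cross_validate(
        featurizer(sequences), labels, ClassifierConfig(kind="nn", seed=7),
        seed=7, ci_bootstrap=100,
    )
    return np.mean([m.f1 for m in rep.per_class.values()])


rwov_f = lambda seqs: rwov_features(seqs, "er", k=30)[0].values
uni_f = lambda seqs: ngram_features(seqs, NGramConfig(range=(1, 1), idf=True))[0]

for name, feat in (("RWOV", rwov_f), ("unigram", uni_f)):
    lo, hi = macro_f1(0.1, feat), macro_f1(0.9, feat)
    print(f"{name:8s} macro-F1: interleaving 0.1 -> {lo:.3f}, 0.9 -> {hi:.3f} "
          f"(drop {lo - hi:+.3f})")
print("\nThe unigram bag degrades sharply under interleaving; the positional")
print("features barely move - the mechanism the vectorization is built for.")
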