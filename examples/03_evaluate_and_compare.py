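"""Cross-validated comparison of RWOV against an n-gram baseline.

Trains the 50/50/100 ReLU network on RWOV features and on IDF-weighted
unigram+bigram counts, using identical stratified 3-fold splits, then
reports per-class F1/AUC with 95% bootstrap confidence intervals and the
DeLong p-value for the paired AUC difference on pooled out-of-fold scores.
"""

import numpy as np

from rwov import (
    ClassifierConfig,
    NGramConfig,
    SyntheticConfig,
    compare_methods,
    generate_corpus,
    ngram_features,
    normalize_corpus,
    rwov_features,
)

reports = generate_corpus(SyntheticConfig(n=400, seed=42))
sequences = normalize_corpus(reports)
labels = np.array([r.labels["er"] for r in reports])

matrix, _ = rwov_features(sequences, "er", k=30)
ngrams, _ = ngram_features(sequences, NGramConfig(range=(1, 2), idf=True))

reports_by_method, comparisons = compare_methods(
    {"RWOV": matrix.values, "ngram(1,2)": ngrams},
    labels,
    ClassifierConfig(kind="nn", seed=0),
    seed=0,
    ci_bootstrap=500,
)

for name, rep in reports_by_method.items():
    for cls, m in rep.per_class.items():
        print(
            f"{name:11s} ER={cls}: F1 {m.f1:.3f} "
            f"[{m.f1_ci[0]:.3f}, {m.f1_ci[1]:.3f}]  "
            f"AUC {m.auc:.3f} [{m.auc_ci[0]:.3f}, {m.auc_ci[1]:.3f}]"
        )
for (a, b, cls), p in comparisons.items():
    print(f"DeLong {a} vs {b} (ER={cls}): p = {p:.3g}")
print("\nSmall p-values mean the paired out-of-fold AUCs differ beyond what")
print("their shared-sample correlation explains.")
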