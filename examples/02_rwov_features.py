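"""Compute signed reciprocal-distance features for one term of interest.

Normalizes a small corpus, selects the 30 words that co-occur most often
with the estrogen-receptor TOI, and vectorizes every report: each cell is
+-1/(d+1) where d counts relevant words between the column's word and the
nearest "er" mention (negative = before, positive = after, 0 = absent).
"""

from rwov import SyntheticConfig, generate_corpus, normalize_corpus, rwov_features

reports = generate_corpus(SyntheticConfig(n=200, seed=42))
sequences = normalize_corpus(reports)
matrix, index = rwov_features(sequences, "er", k=30)

print("top 10 relevant words (mean occurrences per observation):")
for token, freq in index.words[:10]:
    print(f"  {token:8s} {freq:.2f}")

print(f"\nRWOV matrix shape: {matrix.values.shape}")
report = reports[0]
print(f"\nreport: {report.text}")
row = dict(zip(matrix.columns, matrix.values[0]))
nonzero = {t: round(float(v), 3) for t, v in row.items() if v != 0}
print(f"nonzero features (signed 1/(d+1) relative to the first 'er' mention):")
print(f"  {nonzero}")
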