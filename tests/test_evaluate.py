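"""Metrics, DeLong comparison, bootstrap CIs and cross-validation."""

import itertools
import subprocess
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pytest

from rwov import (
    ClassifierConfig,
    auc,
    bootstrap_ci,
    cross_validate,
    delong_compare,
    f1_score,
    make_folds,
)


def brute_force_auc(scores, labels):
    """Pair-enumeration probability with ties at 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(10, 0, 0, 1.0), (0, 5, 3, 0.0), (0, 0, 0, 0.0), (8, 2, 4, 8 / 11)],
    )
    def test_examples(self, tp, fp, fn, expected):
        assert f1_score(tp, fp, fn) == pytest.approx(expected)

    def test_matches_harmonic_mean_form(self, rng):
        for _ in range(300):
            tp, fp, fn = (int(v) for v in rng.integers(0, 50, size=3))
            got = f1_score(tp, fp, fn)
            if tp == 0:
                assert got == 0.0
            else:
                p, r = tp / (tp + fp), tp / (tp + fn)
                assert got == pytest.approx(2 * p * r / (p + r))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f1_score(-1, 0, 0)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_printed_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_enumeration(self, rng):
        """Exact agreement with the brute-force oracle on n <= 12 inputs."""
        for _ in range(300):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # force ties
            assert auc(s, y) == pytest.approx(brute_force_auc(s, y))


def permutation_p(scores_a, scores_b, labels):
    """Exact sign-flip permutation distribution of the AUC difference."""
    n = len(labels)
    observed = abs(auc(scores_a, labels) - auc(scores_b, labels))
    count = 0
    total = 2**n
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    for mask in range(total):
        bits = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        sa = np.where(bits, b, a)
        sb = np.where(bits, a, b)
        if abs(auc(sa, labels) - auc(sb, labels)) >= observed - 1e-12:
            count += 1
    return count / total


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.2, 0.8, 0.3, 0.9, 0.7, 0.1]
        with pytest.warns(UserWarning, match="degenerate"):
            assert delong_compare(s, s, y) == 1.0

    def test_matches_r_proc_reference(self, tmp_path):
        """Same p-value as the pROC DeLong implementation on a fixed dataset."""
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = rng.normal(size=40) + 0.8 * y
        b = rng.normal(size=40) + 0.3 * y
        ours = delong_compare(a, b, y)
        data = tmp_path / "scores.csv"
        np.savetxt(data, np.column_stack([y, a, b]), delimiter=",",
                   header="y,a,b", comments="")
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"d <- read.csv('{data}')\n"
            "t <- roc.test(roc(d$y, d$a, quiet=TRUE), roc(d$y, d$b, quiet=TRUE),"
            " method='delong', paired=TRUE)\n"
            "cat(sprintf('%.12f', t$p.value))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        assert ours == pytest.approx(float(out.stdout), abs=1e-9)

    def test_small_n_agrees_with_permutation_oracle(self):
        """Normal-approximation p close to the exact sign-flip permutation p."""
        rng = np.random.default_rng(21)
        diffs = []
        for _ in range(4):
            n = 12
            y = np.array([0, 1] * 6)
            a = rng.normal(size=n) + 0.9 * y
            b = rng.normal(size=n) + 0.4 * y
            p_d = delong_compare(a, b, y)
            p_p = permutation_p(a, b, y)
            diffs.append(abs(p_d - p_p))
        assert np.median(diffs) < 0.1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([0.1, 0.2], [0.1], [0, 1])


class TestBootstrapCI:
    def test_perfect_classifier_degenerate_interval(self):
        y = [0, 0, 1, 1, 0, 1]
        s = [0.1, 0.2, 0.9, 0.8, 0.15, 0.95]
        assert bootstrap_ci("auc", s, y, B=200, seed=0) == (1.0, 1.0)

    def test_same_seed_same_interval(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.normal(size=60) + y
        one = bootstrap_ci("auc", s, y, B=300, seed=9)
        two = bootstrap_ci("auc", s, y, B=300, seed=9)
        assert one == two

    def test_interval_contains_point_estimate(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100) + 0.8 * y
        lo, hi = bootstrap_ci("auc", s, y, B=500, seed=2)
        assert lo <= auc(s, y) <= hi
        lo, hi = bootstrap_ci("f1", s, y, B=500, seed=2)
        assert lo <= hi

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci("auc", [0.1, 0.9], [0, 1], B=10)


class TestCrossValidate:
    def features(self, rng, n=60):
        y = np.array(["POS"] * (n // 2) + ["NEG"] * (n - n // 2))
        X = rng.normal(size=(n, 4)) + (y == "POS")[:, None] * 1.5
        return X, y

    def test_fold_sizes_balanced(self):
        y = np.array([0, 1] * 5)
        folds = make_folds(y, 3, seed=0)
        sizes = sorted(np.bincount(folds).tolist())
        assert sizes == [3, 3, 4]

    def test_folds_stratified(self, rng):
        y = np.array([1] * 30 + [0] * 60)
        folds = make_folds(y, 3, seed=4)
        for f in range(3):
            assert abs(y[folds == f].sum() - 10) <= 1

    def test_shared_splits_across_methods(self, rng):
        X, y = self.features(rng)
        cfg = ClassifierConfig(kind="svm", seed=0)
        r1 = cross_validate(X, y, cfg, seed=5, ci_bootstrap=100)
        r2 = cross_validate(X**2, y, cfg, seed=5, ci_bootstrap=100)
        assert np.array_equal(r1.folds, r2.folds)

    def test_full_determinism(self, rng):
        X, y = self.features(rng)
        cfg = ClassifierConfig(kind="nn", seed=1, max_iter=200)
        a = cross_validate(X, y, cfg, seed=5, ci_bootstrap=100)
        b = cross_validate(X, y, cfg, seed=5, ci_bootstrap=100)
        for c in a.per_class:
            assert a.per_class[c].f1 == b.per_class[c].f1
            assert a.per_class[c].auc_ci == b.per_class[c].auc_ci

    def test_separable_problem_scores_high(self, rng):
        X, y = self.features(rng, n=90)
        rep = cross_validate(X, y, ClassifierConfig(kind="svm"), seed=3,
                             ci_bootstrap=100)
        for c in ("POS", "NEG"):
            assert rep.per_class[c].auc > 0.9

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        with pytest.raises(ValueError):
            cross_validate(X, np.zeros(12), ClassifierConfig(), seed=0)
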