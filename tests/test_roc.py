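import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from presig.roc import (
    auc_ci,
    auc_mannwhitney,
    filter_candidates,
    operating_point,
    screen_variables,
    wilcoxon_group_test,
)


def brute_force_auc(scores, labels):
    """O(n1*n2) pair-count oracle: wins + half-ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def scan_operating_point(scores, labels, fpr):
    """Exhaustive threshold-scan oracle: max TPR over all cutoffs with
    empirical FPR <= fpr (predict positive when score > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    best = -1.0
    best_t = None
    for t in np.unique(np.concatenate([scores, [scores.min() - 1]])):
        f = np.mean(neg > t)
        if f <= fpr + 1e-12:
            tpr = np.mean(pos > t)
            if tpr > best:
                best, best_t = tpr, t
    return best, best_t


class TestAUC:
    def test_hand_example(self):
        scores = [1, 2, 3, 3, 4, 5]
        labels = [0, 0, 0, 1, 1, 1]
        auc, _ = auc_mannwhitney(scores, labels)
        assert auc == 8.5 / 9

    def test_all_ties(self):
        auc, p = auc_mannwhitney([2.0] * 10, [0, 1] * 5)
        assert auc == 0.5
        assert p == 0.5

    def test_label_swap_symmetry(self, rng):
        s = rng.normal(size=30)
        lab = rng.random(30) > 0.6
        a1, _ = auc_mannwhitney(s, lab)
        a2, _ = auc_mannwhitney(s, ~lab)
        assert a1 == pytest.approx(1 - a2)

    def test_exact_vs_pair_count_random_draws(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            auc, _ = auc_mannwhitney(scores, labels)
            assert auc == brute_force_auc(scores, labels)  # exact

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=6, max_size=25))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, vals):
        # coarse grid so float rounding in exp() cannot merge distinct values
        vals = np.round(np.asarray(vals), 3)
        labels = np.arange(len(vals)) % 2 == 0
        a1, _ = auc_mannwhitney(vals, labels)
        a2, _ = auc_mannwhitney(np.exp(vals / 2.0), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_sided_p_matches_scipy(self, rng):
        s = rng.normal(size=40) + np.repeat([0.0, 0.8], 20)
        lab = np.repeat([False, True], 20)
        _, p = auc_mannwhitney(s, lab)
        want = stats.mannwhitneyu(
            s[lab], s[~lab], alternative="greater", method="asymptotic"
        ).pvalue
        assert p == pytest.approx(want, rel=1e-9)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            auc_mannwhitney([1.0, 2.0], [1, 1])

    def test_ci_contains_auc(self, rng):
        s = rng.normal(size=49) + np.r_[np.full(10, 1.0), np.zeros(39)]
        lab = np.r_[np.ones(10), np.zeros(39)].astype(bool)
        auc, lo, hi = auc_ci(s, lab)
        assert 0 <= lo <= auc <= hi <= 1


class TestOperatingPoint:
    def test_spec_example(self):
        """NP = 1..10, PE = {4.5, 9.5, 10.5}: FPR = 0.1, sensitivity = 2/3."""
        scores = list(range(1, 11)) + [4.5, 9.5, 10.5]
        labels = [0] * 10 + [1] * 3
        op = operating_point(scores, labels, fpr=0.10, n_boot=100, seed=0)
        assert op.threshold == 9.0
        assert op.sensitivity == pytest.approx(2 / 3)
        assert op.specificity == pytest.approx(0.9)

    def test_perfect_separation(self):
        scores = [0.0] * 8 + [5.0] * 4
        labels = [0] * 8 + [1] * 4
        op = operating_point(scores, labels, n_boot=100, seed=0)
        assert op.sensitivity == 1.0
        assert op.specificity == 1.0
        assert op.accuracy == 1.0

    def test_exact_vs_threshold_scan(self, rng):
        """Sensitivity equals the exhaustive threshold-scan maximum."""
        for _ in range(300):
            n0 = int(rng.integers(5, 40))
            n1 = int(rng.integers(2, 15))
            scores = np.concatenate(
                [rng.integers(0, 12, n0), rng.integers(0, 12, n1)]
            ).astype(float)
            labels = np.r_[np.zeros(n0), np.ones(n1)].astype(bool)
            op = operating_point(scores, labels, fpr=0.10, n_boot=10, seed=0)
            want, _ = scan_operating_point(scores, labels, 0.10)
            assert op.sensitivity == want  # exact

    def test_specificity_invariant(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            scores = r.normal(size=49)
            labels = np.r_[np.ones(10), np.zeros(39)].astype(bool)
            op = operating_point(scores, labels, fpr=0.10, n_boot=10, seed=0)
            assert op.specificity >= 0.9

    def test_accuracy_consistent(self, rng):
        scores = rng.normal(size=49)
        labels = np.r_[np.ones(10), np.zeros(39)].astype(bool)
        op = operating_point(scores, labels, n_boot=50, seed=0)
        want = (op.sensitivity * 10 + op.specificity * 39) / 49
        assert op.accuracy == pytest.approx(want)

    def test_ci_bounds_valid(self, rng):
        scores = rng.normal(size=49) + np.r_[np.full(10, 1.2), np.zeros(39)]
        labels = np.r_[np.ones(10), np.zeros(39)].astype(bool)
        op = operating_point(scores, labels, n_boot=500, seed=1)
        lo, hi = op.sensitivity_ci
        assert 0 <= lo <= hi <= 1

    def test_bad_fpr(self):
        with pytest.raises(ValueError):
            operating_point([1, 2], [0, 1], fpr=0.0)


@pytest.fixture(scope="module")
def screen_result():
    rng = np.random.default_rng(12)
    n = 49
    labels = np.r_[np.ones(10), np.zeros(39)].astype(bool)
    X = rng.normal(size=(120, n))
    X[0] = labels.astype(float)  # perfect marker
    X[1] = -(labels.astype(float)) + rng.normal(0, 0.3, n)  # anti-correlated
    vars_ = pd.DataFrame(X, index=[f"V{i}" for i in range(120)])
    return vars_, labels, screen_variables(vars_, labels, n_boot=200, seed=0)


class TestScreen:
    def test_one_row_per_variable(self, screen_result):
        vars_, _, res = screen_result
        assert len(res) == len(vars_)

    def test_perfect_marker(self, screen_result):
        _, _, res = screen_result
        assert res.loc["V0", "auc"] == 1.0
        assert res.loc["V0", "sensitivity"] == 1.0

    def test_anticorrelated_oriented_above_half(self, screen_result):
        _, _, res = screen_result
        assert res.loc["V1", "auc"] > 0.5
        assert res.loc["V1", "orientation"] == -1.0

    def test_auc_matches_scalar_path(self, screen_result):
        vars_, labels, res = screen_result
        for v in ["V5", "V17"]:
            x = vars_.loc[v].to_numpy()
            x = x if res.loc[v, "orientation"] > 0 else -x
            auc, p = auc_mannwhitney(x, labels)
            assert res.loc[v, "auc"] == pytest.approx(auc)
            assert res.loc[v, "auc_p"] == pytest.approx(p, rel=1e-9)

    def test_operating_point_matches_scalar_path(self, screen_result):
        vars_, labels, res = screen_result
        for v in ["V3", "V11"]:
            x = vars_.loc[v].to_numpy()
            x = x if res.loc[v, "orientation"] > 0 else -x
            op = operating_point(x, labels, fpr=0.10, n_boot=10, seed=0)
            assert res.loc[v, "sensitivity"] == op.sensitivity
            assert res.loc[v, "specificity"] == op.specificity

    def test_labels_single_class_rejected(self, screen_result):
        vars_, _, _ = screen_result
        with pytest.raises(ValueError):
            screen_variables(vars_, np.ones(49, dtype=bool))


class TestFilterCandidates:
    def _df(self, sens, aucs):
        return pd.DataFrame({"sensitivity": sens, "auc": aucs},
                            index=[f"V{i}" for i in range(len(sens))])

    def test_strict_inequality_boundary(self):
        res = filter_candidates(self._df([0.65, 0.7], [0.9, 0.8]))
        assert list(res.index) == ["V1"]

    def test_sorted_by_auc_desc(self):
        res = filter_candidates(self._df([0.7, 0.8, 0.9], [0.75, 0.95, 0.85]))
        assert list(res["auc"]) == [0.95, 0.85, 0.75]

    def test_empty_input(self):
        res = filter_candidates(self._df([], []))
        assert len(res) == 0


def test_planted_marker_ranks_top_percent():
    """Biomarkers planted at binormal delta = 1.6 (expected AUC ~ 0.87) rank
    in the top 1% of a 5,000-variable null screen."""
    hits = 0
    for seed in range(4):
        r = np.random.default_rng(seed)
        n = 49
        labels = np.r_[np.ones(10), np.zeros(39)].astype(bool)
        X = r.normal(size=(5000, n))
        X[0] = r.normal(size=n) + 1.6 * labels  # unit-sd variable, delta=1.6
        vars_ = pd.DataFrame(X, index=[f"V{i}" for i in range(5000)])
        res = screen_variables(vars_, labels, n_boot=10, seed=seed)
        rank = int((res["auc"] > res.loc["V0", "auc"]).sum())
        hits += rank < 50  # top 1%
    assert hits >= 3


class TestWilcoxon:
    def test_disjoint_supports_tiny_p(self):
        x = np.arange(10) + 100.0
        y = np.arange(39) * 1.0
        p = wilcoxon_group_test(np.r_[x, y], np.r_[np.ones(10), np.zeros(39)] > 0)
        assert p < 1e-6

    def test_identical_values_p_one(self):
        p = wilcoxon_group_test([3.0] * 12, [0, 1] * 6)
        assert p == 1.0

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=30)
        labels = rng.random(30) > 0.5
        perm = rng.permutation(30)
        assert wilcoxon_group_test(vals, labels) == wilcoxon_group_test(
            vals[perm], labels[perm]
        )

    def test_calibration_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            vals = r.normal(size=40)
            labels = np.r_[np.ones(15), np.zeros(25)].astype(bool)
            ps.append(wilcoxon_group_test(vals, labels))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
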