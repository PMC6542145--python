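"""ROC/AUC/Youden/DeLong/Hanley-McNeil and t-test behaviour.

Brute-force pair enumeration and scikit-learn serve as independent
oracles for the hand-rolled ROC machinery.
"""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from liverdki.stats import (
    MarkerSeries,
    ROCResult,
    auc,
    delong_test,
    evaluate_marker,
    hanley_mcneil_ci,
    infer_polarity,
    paired_t_test,
    roc_curve,
    two_sample_t_test,
    youden_optimal,
)


def brute_force_auc(values, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = values[labels]
    neg = values[~labels]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_series(rng, n_max=30):
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    values = rng.choice([0.0, 0.5, 1.0, 1.5, 2.0, 3.0], size=n)  # force ties
    return MarkerSeries(values, labels, "greater")


class TestROCCurve:
    def test_perfect_separation_reaches_corner(self):
        s = MarkerSeries(np.array([3.0, 4.0, 1.0, 2.0]),
                         np.array([True, True, False, False]))
        roc = roc_curve(s)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in roc.points)
        assert auc(roc) == 1.0

    def test_trivial_extremes_present(self):
        s = MarkerSeries(np.array([2.0, 4.0, 1.0, 3.0]),
                         np.array([True, True, False, False]))
        roc = roc_curve(s)
        assert (roc.points[0].sensitivity, roc.points[0].specificity) == (0.0, 1.0)
        assert (roc.points[-1].sensitivity, roc.points[-1].specificity) == (1.0, 0.0)

    def test_interleaved_scores_three_quarters_concordant(self):
        s = MarkerSeries(np.array([2.0, 4.0, 1.0, 3.0]),
                         np.array([True, True, False, False]))
        assert auc(s) == pytest.approx(0.75)

    def test_polarity_flip_reflects_concordance(self):
        values = np.array([3.0, 4.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        assert auc(MarkerSeries(values, labels, "greater")) == 1.0
        assert auc(MarkerSeries(values, labels, "smaller")) == 0.0

    def test_smaller_polarity_cutoff_scale(self):
        """Cutoffs are reported on the original marker scale: for a
        smaller-is-positive marker the rule is value <= cutoff."""
        values = np.array([1.0, 1.2, 1.8, 2.0])
        labels = np.array([True, True, False, False])
        roc = roc_curve(MarkerSeries(values, labels, "smaller"))
        best = youden_optimal(roc)
        assert best.j == 1.0
        assert 1.2 <= best.cutoff < 1.8
        assert np.mean(values[labels] <= best.cutoff) == best.sensitivity

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_curve(MarkerSeries(np.array([1.0, 2.0]), np.array([True, True])))

    def test_auc_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(100)
        for _ in range(60):
            s = random_series(rng)
            ours = auc(s)
            assert ours == pytest.approx(brute_force_auc(s.values, s.labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(s.labels, s.values), abs=1e-12)

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(17)
        aucs = []
        for _ in range(300):
            values = rng.normal(size=30)
            labels = np.zeros(30, bool)
            labels[:12] = True
            rng.shuffle(labels)
            aucs.append(auc(MarkerSeries(values, labels)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestYouden:
    def test_perfect_marker(self):
        s = MarkerSeries(np.array([3.0, 4.0, 1.0, 2.0]),
                         np.array([True, True, False, False]))
        assert youden_optimal(roc_curve(s)).j == pytest.approx(1.0)

    def test_optimum_beats_every_cutoff_exhaustively(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            s = random_series(rng, n_max=20)
            roc = roc_curve(s)
            best = youden_optimal(roc)
            assert best.j == pytest.approx(max(p.youden_j for p in roc.points))

    def test_ties_break_toward_higher_specificity(self):
        # two operating points share J = 0.5; the high-specificity one wins
        roc = ROCResult.from_operating_points(
            [(1.0, 0.9, 0.6), (2.0, 0.6, 0.9)]
        )
        best = youden_optimal(roc)
        assert best.specificity == 0.9 and best.sensitivity == 0.6


class TestHanleyMcNeil:
    def test_closed_form_at_half(self):
        n = 25
        se, lo, hi = hanley_mcneil_ci(0.5, n, n)
        a, q1, q2 = 0.5, 0.5 / 1.5, 2 * 0.25 / 1.5
        expected = np.sqrt(
            (a * (1 - a) + (n - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (n * n)
        )
        assert se == pytest.approx(expected, rel=1e-12)
        assert lo <= 0.5 <= hi

    def test_se_vanishes_with_sample_size(self):
        se_small = hanley_mcneil_ci(0.8, 20, 20)[0]
        se_large = hanley_mcneil_ci(0.8, 20000, 20000)[0]
        assert se_large < se_small / 10
        assert se_large < 0.005

    def test_ci_clipped_to_unit_interval(self):
        _, lo, hi = hanley_mcneil_ci(0.99, 5, 5)
        assert 0.0 <= lo and hi <= 1.0

    def test_evaluate_marker_assembles_all_fields(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 20)])
        labels = np.concatenate([np.ones(30, bool), np.zeros(20, bool)])
        res = evaluate_marker(MarkerSeries(values, labels))
        assert 0 <= res.auc <= 1 and res.se > 0
        assert res.ci[0] <= res.auc <= res.ci[1]
        assert res.youden.j == pytest.approx(
            res.youden.sensitivity + res.youden.specificity - 1
        )


class TestDeLong:
    def _series_pair(self, seed=0, n_pos=40, n_neg=25, shift=0.6):
        rng = np.random.default_rng(seed)
        base = np.concatenate([rng.normal(shift, 1, n_pos), rng.normal(0, 1, n_neg)])
        other = base + rng.normal(0, 0.8, n_pos + n_neg)
        labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
        return MarkerSeries(base, labels), MarkerSeries(other, labels)

    def test_identical_series_give_null_result(self):
        a, _ = self._series_pair()
        res = delong_test(a, a)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self):
        a, b = self._series_pair(seed=2)
        fwd, rev = delong_test(a, b), delong_test(b, a)
        assert fwd.z == pytest.approx(-rev.z, rel=1e-12)
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)

    def test_mismatched_labels_rejected(self):
        a, b = self._series_pair()
        flipped = MarkerSeries(b.values, ~b.labels)
        with pytest.raises(ValueError, match="identical patients"):
            delong_test(a, flipped)

    def test_auc_agrees_with_trapezoid(self):
        a, b = self._series_pair(seed=9)
        res = delong_test(a, b)
        assert res.auc_a == pytest.approx(auc(a), abs=1e-12)
        assert res.auc_b == pytest.approx(auc(b), abs=1e-12)

    def test_clearly_better_marker_detected(self):
        rng = np.random.default_rng(8)
        labels = np.concatenate([np.ones(60, bool), np.zeros(40, bool)])
        strong = np.concatenate([rng.normal(2.5, 1, 60), rng.normal(0, 1, 40)])
        weak = rng.normal(0, 1, 100)
        res = delong_test(MarkerSeries(strong, labels), MarkerSeries(weak, labels))
        assert res.auc_a > res.auc_b and res.p < 0.01


class TestTTests:
    def test_paired_identical_series(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_paired_hand_computed(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        res = paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert res.df == 2

    def test_paired_sign_flip_negates_t_preserves_p(self):
        pre, post = [0.0, 0.0, 0.0], [1.0, 2.0, 3.0]
        fwd, rev = paired_t_test(pre, post), paired_t_test(post, pre)
        assert fwd.t == pytest.approx(-rev.t) and fwd.p == pytest.approx(rev.p)

    def test_paired_zero_variance_nonzero_mean(self):
        res = paired_t_test([0.0, 0.0], [1.0, 1.0])
        assert np.isinf(res.t) and res.p == 0.0

    def test_welch_identical_groups(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_welch_separated_groups(self):
        rng = np.random.default_rng(1)
        b = 1.0 + rng.normal(0, 1e-9, 4)
        res = two_sample_t_test([0.0, 0.0, 0.0, 0.0], b)
        assert res.p < 1e-6

    def test_welch_agrees_with_permutation_oracle(self):
        """Exhaustive label-permutation p-value on 6+6 draws."""
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 6)
        res = two_sample_t_test(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        combos = list(itertools.combinations(range(12), 6))
        for idx in combos:
            sel = np.zeros(12, bool)
            sel[list(idx)] = True
            diff = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += diff >= observed - 1e-12
        perm_p = count / len(combos)
        assert res.p == pytest.approx(perm_p, abs=0.02)


class TestPolarity:
    def test_inference_from_group_means(self):
        labels = np.array([True, True, False, False])
        assert infer_polarity(np.array([3.0, 4.0, 1.0, 2.0]), labels) == "greater"
        assert infer_polarity(np.array([1.0, 2.0, 3.0, 4.0]), labels) == "smaller"
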