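import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpskin as dk


def brute_force_auc(scores, labels):
    """All-pairs concordance count with half credit for ties (oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_example_concordance(self):
        scores = np.array([0.9, 0.2, 0.8, 0.1])
        labels = np.array([1, 1, 0, 0])
        r = dk.roc_auc(scores, labels, compute_ci=False)
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = dk.roc_auc([3, 4, 5, 1, 2], [1, 1, 1, 0, 0], compute_ci=False)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_all_ties_give_half(self):
        r = dk.roc_auc(np.ones(10), [1] * 5 + [0] * 5, compute_ci=False)
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            dk.roc_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=60, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=20),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=20),
    )
    def test_matches_brute_force_concordance(self, pos, neg):
        # integer scores force plenty of ties
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        r = dk.roc_auc(scores, labels, compute_ci=False)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        r1 = dk.roc_auc(scores, labels, compute_ci=False)
        r2 = dk.roc_auc(np.exp(scores), labels, compute_ci=False)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert r1.sensitivity == pytest.approx(r2.sensitivity)
        assert r1.specificity == pytest.approx(r2.specificity)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        r = dk.roc_auc(scores, labels, n_boot=500, seed=0)
        assert r.ci95[0] <= r.auc <= r.ci95[1]


class TestYoudenCutoff:
    def test_single_positive_above_all(self):
        scores = np.array([4.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 0, 0, 0])
        cut, sens, spec = dk.youden_cutoff(scores, labels)
        assert sens == 1.0 and spec == 1.0
        assert 3.0 < cut <= 4.0

    def test_orientation_flip_preserves_j(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, s1, p1 = dk.youden_cutoff(scores, labels, positive_high=True)
        _, s2, p2 = dk.youden_cutoff(-scores, labels, positive_high=False)
        assert s1 + p1 == pytest.approx(s2 + p2)

    def test_tie_break_deterministic(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 1, 1])
        cut1 = dk.youden_cutoff(scores, labels)[0]
        cut2 = dk.youden_cutoff(scores, labels)[0]
        assert cut1 == cut2


class TestBootstrapAucTest:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=60)
        y = np.array([1] * 30 + [0] * 30)
        assert dk.bootstrap_auc_test(s, s, y, n_boot=200, seed=1) == 1.0

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 100 + [0] * 100)
        perfect = y + rng.uniform(0, 0.5, 200)
        random = rng.normal(size=200)
        p = dk.bootstrap_auc_test(perfect, random, y, n_boot=500, seed=2)
        assert p < 0.01

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(12)
        y = np.array([1] * 50 + [0] * 50)
        a = y + rng.normal(0, 1.2, 100)
        b = y + rng.normal(0, 2.0, 100)
        p_ab = dk.bootstrap_auc_test(a, b, y, n_boot=2000, seed=3)
        p_ba = dk.bootstrap_auc_test(b, a, y, n_boot=2000, seed=4)
        assert p_ab == pytest.approx(p_ba, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            dk.bootstrap_auc_test([1, 2], [1, 2, 3], [0, 1])


class TestSmote:
    def test_cohort_balancing_counts(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(166, 2))
        y = np.array([1] * 105 + [0] * 61)
        Xb, yb = dk.smote(X, y, seed=0)
        assert len(yb) == 210
        assert (yb == 1).sum() == 105 and (yb == 0).sum() == 105

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = dk.smote(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 2))
        y = np.array([1] * 30 + [0] * 10)
        Xb, yb = dk.smote(X, y, k=3, seed=0)
        X_min = X[y == 0]
        for p in Xb[40:]:
            # p = a + u*(b-a) for some minority pair (a, b): collinear and between
            ok = False
            for i in range(len(X_min)):
                for j in range(len(X_min)):
                    if i == j:
                        continue
                    a, b = X_min[i], X_min[j]
                    d = b - a
                    u = np.dot(p - a, d) / np.dot(d, d)
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(a + u * d, p, atol=1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(50, 2))
        y = np.array([1] * 35 + [0] * 15)
        X1, y1 = dk.smote(X, y, seed=7)
        X2, y2 = dk.smote(X, y, seed=7)
        np.testing.assert_array_equal(X1, X2)

    def test_large_k_reduced_with_warning(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(13, 2))
        y = np.array([1] * 10 + [0] * 3)
        with pytest.warns(UserWarning, match="reducing k"):
            Xb, yb = dk.smote(X, y, k=5, seed=0)
        assert (yb == 0).sum() == 10


class TestDiagnosticOddsRatio:
    def test_plain_arithmetic(self):
        assert dk.diagnostic_odds_ratio(9, 1, 1, 9) == pytest.approx(81.0)

    def test_zero_cell_correction(self):
        # add 0.5 to every cell: (10.5 * 8.5) / (0.5 * 2.5) = 71.4
        assert dk.diagnostic_odds_ratio(10, 0, 2, 8) == pytest.approx(71.4)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(18)
    X = np.vstack(
        [rng.normal([0, 0], 0.1, size=(105, 2)), rng.normal([5, 5], 0.1, size=(105, 2))]
    )
    y = np.array([0] * 105 + [1] * 105)
    return X, y


class TestRepeatedSvmEvaluation:
    def test_test_partition_size(self, separable):
        X, y = separable
        ev = dk.repeated_svm_evaluation(X, y, "linear", n_runs=3, seed=0)
        counts = ev.runs[["tp", "fp", "fn", "tn"]].sum(axis=1)
        assert (counts == 63).all()  # 30% of the 210-sample balanced cohort

    def test_separable_clusters_perfect(self, separable):
        X, y = separable
        ev = dk.repeated_svm_evaluation(X, y, "linear", n_runs=5, seed=0)
        assert ev.mean_auc == 1.0
        assert (ev.runs["fp"] == 0).all() and (ev.runs["fn"] == 0).all()

    def test_random_classifier_dor_near_one(self):
        # uninformative features, fresh dataset per replicate: mean log-DOR
        # must be near zero (resplitting one fixed null dataset is biased by
        # train-noise anti-generalisation, so datasets are redrawn)
        logs = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(120, 2))
            y = np.array([0] * 60 + [1] * 60)
            ev = dk.repeated_svm_evaluation(X, y, "linear", n_runs=10, seed=s)
            logs.append(np.log(ev.runs["dor"]).mean())
        assert abs(np.mean(logs)) < 0.35

    def test_rbf_kernel_runs(self, separable):
        X, y = separable
        ev = dk.repeated_svm_evaluation(X, y, "rbf", n_runs=2, seed=0)
        assert ev.kernel == "rbf"
        assert ev.mean_auc > 0.99


class TestDunnett:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(20)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1, 25)
        from scipy import stats

        p_dunnett = dk.dunnett_comparison([a, b], reference_index=0, seed=0)[0]
        p_t = stats.ttest_ind(b, a).pvalue
        assert p_dunnett == pytest.approx(p_t, abs=5e-3)

    def test_reference_excluded_from_output(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(size=10) for _ in range(4)]
        p = dk.dunnett_comparison(groups, reference_index=1, seed=0)
        assert p.shape == (3,)

    def test_null_familywise_error_controlled(self):
        rng = np.random.default_rng(22)
        rejections = 0
        n_rep = 150
        for _ in range(n_rep):
            groups = [rng.normal(size=15) for _ in range(3)]
            p = dk.dunnett_comparison(groups, reference_index=0, seed=0)
            rejections += int((p < 0.05).any())
        rate = rejections / n_rep
        assert 0.005 < rate < 0.12  # family-wise ~5%

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dk.dunnett_comparison([np.ones(5), np.ones(5)], 0)
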