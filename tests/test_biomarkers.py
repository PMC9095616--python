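"""Rank-sum tests, ROC/Youden operating points, logistic marker panels."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from mimoprofile.biomarkers import (
    BiomarkerError,
    auc,
    best_subset,
    fit_logistic,
    rank_markers,
    roc_points,
    wilcoxon_rank_sum,
    youden_optimal,
)

from oracles import confusion_point, pairwise_auc, sweep_youden


class TestWilcoxonRankSum:
    def test_tiny_case_close_to_exact_permutation(self):
        # exact two-sided p by full enumeration of C(4,2)=6 group splits
        x, y = [1.0, 2.0], [3.0, 4.0]
        pooled = x + y
        w_obs = sum(sorted(pooled).index(v) + 1 for v in x)
        count = 0
        total = 0
        for comb in itertools.combinations(range(4), 2):
            w = sum(sorted(pooled).index(pooled[i]) + 1 for i in comb)
            total += 1
            if abs(w - 5.0) >= abs(w_obs - 5.0):  # 5 = E[W]
                count += 1
        exact = count / total
        assert exact == pytest.approx(1 / 3)
        _, p = wilcoxon_rank_sum(x, y)
        assert abs(p - exact) < 0.15

    def test_identical_groups_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_all_constant_p_is_one(self):
        _, p = wilcoxon_rank_sum([5.0] * 4, [5.0] * 3)
        assert p == 1.0

    def test_statistic_is_midrank_sum(self):
        w, _ = wilcoxon_rank_sum([1.0, 3.0, 3.0], [2.0, 3.0])
        # pooled ranks: 1->1, 2->2, 3s -> midrank 4
        assert w == pytest.approx(1 + 4 + 4)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestRocPoints:
    def test_separable_case(self):
        pts = {t: (s, sp) for t, s, sp in roc_points(
            [5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])}
        assert pts[5] == (1.0, 1.0)

    def test_infinite_threshold_boundary(self):
        pts = roc_points([5, 1], [1, 0])
        t, sens, spec = pts[-1]
        assert math.isinf(t) and sens == 0.0 and spec == 1.0

    def test_each_point_matches_counting_oracle(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        for t, sens, spec in roc_points(scores, labels):
            o_sens, o_spec = confusion_point(scores, labels, t)
            assert (sens, spec) == (o_sens, o_spec)

    def test_single_class_errors(self):
        with pytest.raises(BiomarkerError):
            roc_points([1, 2], [1, 1])


class TestYoudenOptimal:
    def test_separable_selects_lowest_separating_cutpoint(self):
        perf = youden_optimal([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert perf.youden == pytest.approx(1.0)
        assert perf.threshold == 5  # lowest evaluated separating cutpoint

    def test_hand_worked_interleaved_case(self):
        perf = youden_optimal([1, 5, 6, 2, 3, 4], [1, 1, 1, 0, 0, 0])
        assert perf.youden == pytest.approx(2 / 3)
        assert perf.threshold == 5
        assert perf.sensitivity == pytest.approx(2 / 3)
        assert perf.specificity == pytest.approx(1.0)

    def test_equals_brute_force_sweep(self, rng):
        for _ in range(30):
            scores = np.round(rng.normal(size=40), 1)
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                labels[0] = 1 - labels[0]
            perf = youden_optimal(scores, labels)
            j_star, t, sens, spec = sweep_youden(list(scores), list(labels))
            assert perf.youden == pytest.approx(j_star)
            assert perf.threshold == t
            assert (perf.sensitivity, perf.specificity) == (sens, spec)

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(5)
        high = 0
        reps = 500
        for _ in range(reps):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            if labels.sum() in (0, 200):
                labels[0] = 1 - labels[0]
            if youden_optimal(scores, labels).youden > 0.25:
                high += 1
        assert high / reps <= 0.05


class TestAuc:
    def test_hand_enumerated_pairs(self):
        assert auc([0.9, 0.4, 0.1, 0.5], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert auc([3.0] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_label_flip_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = np.array([1] * 10 + [0] * 20)
        assert auc(scores, labels) == pytest.approx(
            1.0 - auc(scores, 1 - labels), rel=1e-12
        )

    def test_equals_pair_enumeration_and_sklearn(self, rng):
        for n in (20, 100, 200):
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            got = auc(scores, labels)
            assert got == pytest.approx(pairwise_auc(scores, labels), rel=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), rel=1e-9)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        transformed = np.exp(scores / 2.0)
        assert auc(scores, labels) == pytest.approx(
            auc(transformed, labels), rel=1e-12
        )
        assert youden_optimal(scores, labels).youden == pytest.approx(
            youden_optimal(transformed, labels).youden, rel=1e-12
        )


class TestRankMarkers:
    def _matrix(self, rows: dict, samples: list[str]) -> pd.DataFrame:
        return pd.DataFrame(rows, index=samples).T

    def test_perfect_marker_ranks_first(self):
        samples = [f"s{i}" for i in range(8)]
        labels = {s: int(i < 4) for i, s in enumerate(samples)}
        m = pd.DataFrame(
            {
                "WHKD": [9, 8, 9, 7, 1, 2, 1, 0],
                "GQ.HD": [5, 1, 4, 2, 5, 1, 4, 2],
            },
            index=samples,
        ).T
        ranked = rank_markers(m, labels, min_sens=0.5, min_spec=0.5, k=15)
        assert ranked[0].pattern.symbols == "WHKD"
        assert ranked[0].youden == pytest.approx(1.0)

    def test_uninformative_matrix_empty(self):
        samples = ["a", "b", "c", "d"]
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        m = pd.DataFrame({"WHKD": [3.0, 3.0, 3.0, 3.0]}, index=samples).T
        assert rank_markers(m, labels) == []

    def test_returned_markers_satisfy_floors(self, rng):
        samples = [f"s{i}" for i in range(30)]
        labels = {s: int(i < 10) for i, s in enumerate(samples)}
        res = "ACDEFGHIKLMNPQRSTVWY"
        rows = {f"P{res[j]}TK": rng.normal(size=30) + (j % 3 == 0) * 1.5 *
                np.array([1] * 10 + [0] * 20) for j in range(20)}
        m = pd.DataFrame(rows, index=samples).T
        for perf in rank_markers(m, labels, min_sens=0.6, min_spec=0.6, k=15):
            assert perf.sensitivity > 0.6 and perf.specificity > 0.6
            assert perf.youden == pytest.approx(
                perf.sensitivity + perf.specificity - 1.0
            )

    def test_planted_discriminative_markers_recovered(self):
        # 3 informative epitopes among 100 nulls, 20 seeded repetitions
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            samples = [f"s{i}" for i in range(40)]
            y = np.array([1] * 12 + [0] * 28)
            labels = {s: int(v) for s, v in zip(samples, y)}
            rows = {}
            planted = ["AAAA", "CCCC", "DDDD"]
            res = "ACDEFGHIKLMNPQRSTVWY"
            for j in range(100):
                rows[f"N{res[j // 20]}{res[j % 20]}W"] = rng.lognormal(3, 1, size=40)
            for pat in planted:
                rows[pat] = rng.lognormal(3, 1, size=40) * (1 + 9 * y)
            m = pd.DataFrame(rows, index=samples).T
            ranked = rank_markers(m, labels, min_sens=0.5, min_spec=0.5, k=5)
            top5 = {p.pattern.symbols for p in ranked}
            if all(p in top5 for p in planted):
                hits += 1
        assert hits >= 18


class TestFitLogistic:
    def test_separable_flags_nonconvergence_with_auc_one(self):
        x = np.array([[0.0], [0.1], [0.2], [2.0], [2.1], [2.2]])
        y = [0, 0, 0, 1, 1, 1]
        model = fit_logistic(x, y)
        assert model.auc == pytest.approx(1.0)
        assert not model.converged

    def test_parameter_recovery_known_coefficients(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.normal(size=n)
        beta_true = np.array([0.0, 2.0])
        p = 1.0 / (1.0 + np.exp(-(beta_true[0] + beta_true[1] * x)))
        y = rng.binomial(1, p)
        model = fit_logistic(x[:, None], y)
        assert model.converged
        # standard errors from the observed Fisher information
        design = np.column_stack([np.ones(n), x])
        mu = 1.0 / (1.0 + np.exp(-design @ model.coefficients))
        cov = np.linalg.inv(design.T @ (design * (mu * (1 - mu))[:, None]))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(model.coefficients - beta_true) < 3 * se)

    def test_agrees_with_sklearn_unpenalized(self):
        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(size=(n, 2))
        p = 1.0 / (1.0 + np.exp(-(0.5 + X @ [1.0, -0.7])))
        y = rng.binomial(1, p)
        model = fit_logistic(X, y)
        sk = LogisticRegression(C=np.inf, max_iter=500).fit(X, y)
        assert model.coefficients[0] == pytest.approx(sk.intercept_[0], abs=1e-4)
        assert model.coefficients[1:] == pytest.approx(sk.coef_[0], abs=1e-4)

    def test_duplicate_column_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = (x + rng.normal(scale=0.5, size=50) > 0).astype(int)
        X = pd.DataFrame({"m1": x, "m2": x, "m3": np.ones(50)})
        with pytest.warns(UserWarning):
            model = fit_logistic(X, y)
        assert model.markers == ["m1"]

    def test_auc_revalidates_from_scores(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 2))
        y = rng.integers(0, 2, size=80)
        if y.sum() in (0, 80):
            y[0] = 1 - y[0]
        model = fit_logistic(X, y)
        design = np.column_stack([np.ones(80), X])
        scores = design @ model.coefficients
        assert model.auc == pytest.approx(auc(scores, y), abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(BiomarkerError):
            fit_logistic(np.zeros((4, 1)) + np.arange(4)[:, None], [1, 1, 1, 1])


class TestBestSubset:
    def _setup(self, rng):
        samples = [f"s{i}" for i in range(24)]
        y = np.array([1] * 8 + [0] * 16)
        labels = {s: int(v) for s, v in zip(samples, y)}
        return samples, y, labels

    def test_perfect_singleton_wins(self, rng):
        samples, y, labels = self._setup(rng)
        rows = {
            "AAAA": 10.0 ** (y * 3 + 1),  # separates perfectly
            "CCCC": rng.lognormal(2, 1, size=24),
            "DDDD": rng.lognormal(2, 1, size=24),
        }
        m = pd.DataFrame(rows, index=samples).T
        model = best_subset(m, labels, list(rows), max_size=3)
        assert model.auc == pytest.approx(1.0)
        assert model.markers == ["AAAA"]

    def test_complementary_pair_beats_singletons(self):
        # two weak markers whose sum separates the groups
        samples = [f"s{i}" for i in range(8)]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        labels = dict(zip(samples, y))
        a = np.array([9.0, 0.0, 9.0, 0.0, 0.0, 2.0, 0.0, 2.0])
        b = np.array([0.0, 9.0, 0.0, 9.0, 2.0, 0.0, 2.0, 0.0])
        m = pd.DataFrame({"AAAA": a, "CCCC": b}, index=samples).T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pair = best_subset(m, labels, ["AAAA", "CCCC"], max_size=2)
        feats_a = np.log10(a + 1)
        feats_b = np.log10(b + 1)
        assert pair.auc > max(auc(feats_a, y), auc(feats_b, y))
        assert sorted(pair.markers) == ["AAAA", "CCCC"]

    def test_max_size_one_reduces_to_best_single_auc(self, rng):
        samples, y, labels = self._setup(rng)
        rows = {f"M{j}AA": rng.lognormal(2, 1, size=24) * (1 + j * y)
                for j in range(4)}
        m = pd.DataFrame(rows, index=samples).T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = best_subset(m, labels, list(rows), max_size=1)
            singles = {
                name: fit_logistic(
                    np.log10(m.loc[[name]].T.to_numpy() + 1), y).auc
                for name in rows
            }
        assert len(model.markers) == 1
        assert model.auc == pytest.approx(max(singles.values()))
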