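import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.utils.estimator_checks import check_estimator

import wmdecode as wd
from wmdecode.coding import (
    CodingDimensionClassifier,
    InsufficientDataError,
    loo_decode_naive,
)


def two_class_problem(n=80, p=6, sep=1.5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.where(rng.random(n) < 0.5, "A", "B")
    X[y == "B", 0] += sep
    return X, y


class TestFitCd:
    def test_closed_form_identity_covariance(self):
        # two cells, unit covariance, mean difference along the first axis:
        # w is proportional to (1/(1+gamma), 0)
        rng = np.random.default_rng(0)
        n = 100_000
        X = rng.normal(size=(n, 2))
        y = np.array(["A", "B"] * (n // 2))
        X[y == "B", 0] += 1.0
        clf = wd.fit_cd(X, y, gamma=1e-4)
        w = clf.weights_
        assert abs(w[1] / w[0]) < 0.02
        # direction (1, 0); magnitude ~ diff/(var + gamma) with var ~ 1 + sep^2/4
        assert w[0] > 0

    def test_ridge_limit_is_mean_difference(self):
        X, y = two_class_problem(seed=1)
        clf = wd.fit_cd(X, y, gamma=1e6)
        mu = X[y == "B"].mean(0) - X[y == "A"].mean(0)
        cos = (clf.weights_ @ mu) / np.linalg.norm(clf.weights_) / np.linalg.norm(mu)
        assert cos == pytest.approx(1.0, abs=1e-3)

    def test_matches_dense_inverse_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(2, 6))
            X = rng.normal(size=(n, p))
            y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            gamma = 10.0 ** rng.uniform(-5, 0)
            clf = wd.fit_cd(X, y, gamma=gamma)
            cov = np.cov(X, rowvar=False, ddof=1)
            mu = X[y == "B"].mean(0) - X[y == "A"].mean(0)
            w = np.linalg.inv(cov + gamma * np.eye(p)) @ mu
            np.testing.assert_allclose(clf.weights_, w, atol=1e-8, rtol=1e-6)

    def test_positive_class_convention(self):
        X, y = two_class_problem(seed=3)
        clf = wd.fit_cd(X, y)
        # lexicographically larger class (B / WM) projects positive
        assert clf.classes_[-1] == "B"
        assert clf.class_means_projected_["B"] > clf.class_means_projected_["A"]

    def test_single_class_and_bad_gamma_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            wd.fit_cd(X, np.array(["A"] * 10))
        with pytest.raises(ValueError):
            wd.fit_cd(X, np.array(["A", "B"] * 5), gamma=0.0)

    def test_sklearn_estimator_contract(self):
        check_estimator(
            CodingDimensionClassifier(),
            expected_failed_checks={
                "check_classifiers_one_label": "binary contrast requires two classes",
                "check_classifiers_classes": "binary-only classifier",
                "check_classifiers_multilabel_representation_invariance":
                    "binary-only classifier",
            },
            on_fail=None,
        )


class TestLooDecode:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.full((20, 3), -1.0), np.full((20, 3), 1.0)])
        X += rng.normal(0, 1e-6, X.shape)
        y = np.array(["A"] * 20 + ["B"] * 20)
        assert wd.loo_decode(X, y).accuracy == 1.0

    def test_fast_equals_naive(self):
        X, y = two_class_problem(n=60, seed=4)
        f, nv = wd.loo_decode(X, y), loo_decode_naive(X, y)
        assert (f.predicted == nv.predicted).all()
        np.testing.assert_allclose(f.scores, nv.scores, atol=1e-10)
        assert f.accuracy == nv.accuracy

    def test_shuffled_labels_give_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 8))
        accs = [wd.loo_decode(X, rng.permutation(
            np.array(["A", "B"] * 100))).accuracy for _ in range(60)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_train_accuracy_reported(self):
        X, y = two_class_problem(seed=6)
        res = wd.loo_decode(X, y)
        assert res.train_accuracy >= res.accuracy - 0.05

    def test_agrees_with_logistic_regression_on_separable_data(self):
        # an independent linear classifier reaches the same accuracy regime
        X, y = two_class_problem(n=200, sep=2.0, seed=7)
        cd_acc = wd.loo_decode(X, y).accuracy
        lr = LogisticRegression(max_iter=1000).fit(X[:150], y[:150])
        lr_acc = lr.score(X[150:], y[150:])
        assert abs(cd_acc - lr_acc) < 0.1


class TestDelayFeature:
    def _tensor(self, n_frames_per_trial, seed=0):
        from test_selection import make_tensor
        rng = np.random.default_rng(seed)
        return make_tensor([rng.random((4, k)) for k in n_frames_per_trial],
                           window_ms=(0.0, 3200.0))

    def test_span_of_five_frames(self):
        # five frames at 4.68 Hz cover 1068 ms of data
        assert 5 / 4.68 * 1000 == pytest.approx(1068, abs=1.0)

    def test_constant_trace_gives_constant(self):
        from test_selection import make_tensor
        ten = make_tensor([np.full((2, 8), 3.0)])
        X, ok = wd.delay_feature(ten, k=5, rng=np.random.default_rng(0))
        assert ok[0]
        np.testing.assert_allclose(X[0], 3.0)

    def test_short_trials_excluded(self):
        ten = self._tensor([3, 8, 10])
        X, ok = wd.delay_feature(ten, k=5, rng=np.random.default_rng(0))
        assert list(ok) == [False, True, True]

    def test_expectation_equals_full_mean(self):
        ten = self._tensor([9])
        full = ten.windows[0].mean(axis=1)
        rng = np.random.default_rng(1)
        est = np.mean([wd.delay_feature(ten, 5, rng)[0][0]
                       for _ in range(10_000)], axis=0)
        np.testing.assert_allclose(est, full, atol=5e-3)


class TestSweeps:
    @pytest.fixture(scope="class")
    def problem(self):
        return two_class_problem(n=120, p=12, sep=1.2, seed=8)

    def test_full_sample_equals_full_population(self, problem):
        X, y = problem
        full = wd.loo_decode(X, y).accuracy
        out = wd.sweep_cells(X, y, ns=[12], repeats=2,
                             rng=np.random.default_rng(0))
        assert out["accuracy"][0] == pytest.approx(full, abs=1e-12)
        assert out["variance_fraction"][0] == pytest.approx(1.0)

    def test_single_null_cell_is_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 10))
        y = np.array(["A", "B"] * 75)
        out = wd.sweep_cells(X, y, ns=[1], repeats=25, rng=rng)
        assert out["accuracy"][0] == pytest.approx(0.5, abs=0.06)

    def test_accuracy_grows_with_cells_on_planted_code(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 30))
        y = np.array(["A", "B"] * 75)
        X[y == "B"] += 0.25  # distributed code across every cell
        out = wd.sweep_cells(X, y, ns=[2, 8, 30], repeats=10, rng=rng)
        acc = out["accuracy"]
        assert acc[0] < acc[1] < acc[2]

    def test_pc_sweep_k0_and_full_rank_identities(self, problem):
        X, y = problem
        rng = np.random.default_rng(11)
        frames = rng.normal(size=(500, 12))
        full = wd.loo_decode(X - frames.mean(0), y).accuracy
        top = wd.sweep_pcs(frames, X, y, ks=[0, 12], mode="top")
        excl = wd.sweep_pcs(frames, X, y, ks=[0], mode="exclude")
        assert top["accuracy"][0] == pytest.approx(full, abs=1e-12)
        assert top["accuracy"][1] == pytest.approx(full, abs=1e-9)
        assert excl["accuracy"][0] == pytest.approx(full, abs=1e-12)

    def test_exclude_all_pcs_warns_and_is_chance(self, problem):
        X, y = problem
        rng = np.random.default_rng(12)
        frames = rng.normal(size=(500, 12))
        with pytest.warns(UserWarning):
            out = wd.sweep_pcs(frames, X, y, ks=[12], mode="exclude")
        assert out["accuracy"][0] == pytest.approx(0.5, abs=0.15)

    def test_code_orthogonal_to_top_pcs_survives_exclusion(self):
        rng = np.random.default_rng(13)
        n, p = 160, 20
        frames = rng.normal(size=(2000, p))
        frames[:, 0] *= 8.0  # dominant mode carries no label information
        X = rng.normal(size=(n, p)) * 0.3
        X[:, 0] += rng.normal(size=n) * 3.0
        y = np.array(["A", "B"] * (n // 2))
        X[y == "B", 5] += 1.0  # code on a low-variance axis
        out = wd.sweep_pcs(frames, X, y, ks=[0, 1], mode="exclude")
        assert abs(out["accuracy"][1] - out["accuracy"][0]) < 0.05
        assert out["accuracy"][1] > 0.85


class TestStimulusPeriodCd:
    def test_shared_code_transfers_across_tasks(self):
        rng = np.random.default_rng(14)
        Xw, yw = two_class_problem(n=150, sep=2.0, seed=14)
        Xd, yd = two_class_problem(n=150, sep=2.0, seed=15)
        out = wd.stimulus_period_cd(Xw, yw, Xd, yd)
        assert out["cross_task_accuracy"] >= out["within_task"].accuracy - 0.08

    def test_zero_signal_is_chance_both_ways(self):
        rng = np.random.default_rng(16)
        Xw = rng.normal(size=(200, 6))
        yw = np.array(["A", "B"] * 100)
        Xd = rng.normal(size=(200, 6))
        out = wd.stimulus_period_cd(Xw, yw, Xd, yw)
        assert out["within_task"].accuracy == pytest.approx(0.5, abs=0.1)
        assert out["cross_task_accuracy"] == pytest.approx(0.5, abs=0.1)

    def test_orientation_mismatch_rejected(self):
        Xw, yw = two_class_problem(seed=17)
        with pytest.raises(ValueError):
            wd.stimulus_period_cd(Xw, yw, Xw, np.array(["C"] * len(yw)))


class TestPersistence:
    def test_perfectly_persistent_signal(self):
        rng = np.random.default_rng(18)
        a = rng.lognormal(size=400)
        delays = np.full(400, 2500.0)
        res = wd.persistence_stats(a, a, delays)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_independent_halves(self):
        rng = np.random.default_rng(19)
        res = wd.persistence_stats(rng.normal(size=3000), rng.normal(size=3000),
                                   np.full(3000, 2500.0))
        assert res.slope == pytest.approx(0.0, abs=0.05)
        assert res.r_squared < 0.01

    def test_short_delays_excluded(self):
        rng = np.random.default_rng(20)
        delays = np.array([1000.0] * 50 + [2500.0] * 50)
        res = wd.persistence_stats(rng.normal(size=100), rng.normal(size=100),
                                   delays)
        assert res.n_trials == 50

    def test_too_few_trials_raises(self):
        with pytest.raises(InsufficientDataError):
            wd.persistence_stats(np.ones(5), np.ones(5), np.full(5, 2500.0))


class TestOutcomePrediction:
    def test_code_collapse_predicts_false_alarms(self):
        rng = np.random.default_rng(21)
        n, p = 2000, 12
        amp = np.where(rng.random(n) < 0.3, 0.0, 1.0)  # collapsed trials
        y = np.array(["A", "B"] * (n // 2))
        X = rng.normal(size=(n, p)) * 0.4
        X[:, 0] += np.where(y == "B", 1.0, -1.0) * amp
        outcomes = np.where(amp == 0,
                            np.where(rng.random(n) < 0.7, "FA", "CR"),
                            np.where(rng.random(n) < 0.1, "FA", "CR"))
        correct = wd.decode_with_outcome_control(X, y, outcomes == "CR")
        out = wd.outcome_split_accuracy(correct, outcomes)
        assert out["testable"]
        assert out["acc_pre_fa"] < out["acc_pre_cr"]
        assert out["fisher_p"] < 0.05

    def test_outcome_independent_of_code_is_null(self):
        rng = np.random.default_rng(22)
        n = 800
        y = np.array(["A", "B"] * (n // 2))
        X = rng.normal(size=(n, 6))
        X[:, 0] += np.where(y == "B", 0.8, -0.8)
        outcomes = np.where(rng.random(n) < 0.3, "FA", "CR")
        out = wd.outcome_split_accuracy(
            wd.decode_with_outcome_control(X, y, outcomes == "CR"), outcomes)
        assert abs(out["acc_pre_fa"] - out["acc_pre_cr"]) < 0.1

    def test_all_cr_not_testable(self):
        out = wd.outcome_split_accuracy(np.ones(50, bool),
                                        np.array(["CR"] * 50))
        assert not out["testable"]


class TestConditionalCueAccuracy:
    def test_identical_correctness_gives_r_one(self):
        c = np.random.default_rng(23).random(200) < 0.7
        out = wd.conditional_cue_accuracy(c, c)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_independent_codes_give_zero_r(self):
        rng = np.random.default_rng(24)
        out = wd.conditional_cue_accuracy(rng.random(5000) < 0.8,
                                          rng.random(5000) < 0.8)
        assert out["pearson_r"] == pytest.approx(0.0, abs=0.05)

    def test_shared_gain_gives_positive_r(self):
        rng = np.random.default_rng(25)
        gain = rng.random(3000) < 0.5
        task = np.where(gain, rng.random(3000) < 0.95, rng.random(3000) < 0.6)
        cue = np.where(gain, rng.random(3000) < 0.95, rng.random(3000) < 0.6)
        out = wd.conditional_cue_accuracy(task, cue)
        assert out["pearson_r"] > 0.1
        assert out["cue_acc_task_correct"] > out["cue_acc_task_incorrect"]

    def test_degenerate_split(self):
        out = wd.conditional_cue_accuracy(np.ones(20, bool),
                                          np.random.default_rng(0).random(20) < 0.5)
        assert not out["testable"]
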