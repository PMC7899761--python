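"""Feature assembly, scaling, network training, CV and comparison stats."""

import numpy as np
import pytest
from sklearn.metrics import r2_score

from emgfatigue.estimate import (CVSpec, MethodKind, NetworkSpec, ScalerPair,
                                 assemble, blocked_folds, compare,
                                 log_sigmoid, percent_increase, r2, run_cv,
                                 train_net)
from emgfatigue.features import FeatureMatrix


def toy_matrix(n=24, channels=3, with_mfl=True, seed=0):
    rng = np.random.default_rng(seed)
    fm = FeatureMatrix(
        window_times=np.arange(n, dtype=float),
        channel_labels=[f"ch{i}" for i in range(channels)],
        rms=rng.uniform(0.1, 1.0, (n, channels)),
        arv=rng.uniform(0.1, 1.0, (n, channels)),
        mnf=rng.uniform(50, 150, (n, channels)),
        mnf_arv=rng.uniform(100, 500, (n, channels)),
        mean_force=rng.uniform(200, 400, n),
        mfl=np.linspace(0, 1, n) if with_mfl else None,
    )
    return fm


class TestAssemble:
    @pytest.mark.parametrize("method,width",
                             [("TMLM", 3), ("CMLM", 6), ("FMLM", 4)])
    def test_design_matrix_widths(self, method, width):
        X, y = assemble(method, toy_matrix())
        assert X.shape == (24, width)
        assert y.shape == (24,)

    def test_fmlm_requires_assigned_fatigue(self):
        with pytest.raises(ValueError, match="assign MFL"):
            assemble(MethodKind.FMLM, toy_matrix(with_mfl=False))


class TestScaling:
    def test_column_maps_to_unit_interval(self):
        X = np.array([[0.0], [5.0], [10.0]])
        y = np.array([1.0, 2.0, 3.0])
        sc = ScalerPair().fit(X, y)
        Xs, ys = sc.transform(X, y)
        assert np.allclose(Xs.ravel(), [0, 0.5, 1])
        assert np.allclose(ys, [0, 0.5, 1])

    def test_out_of_range_test_values_not_clipped(self):
        sc = ScalerPair().fit(np.array([[0.0], [10.0]]), np.array([0.0, 1.0]))
        assert sc.transform(np.array([[20.0]]))[0, 0] == pytest.approx(2.0)

    def test_zero_range_column_maps_to_zero(self):
        X = np.column_stack([np.full(3, 7.0), [0.0, 1.0, 2.0]])
        sc = ScalerPair().fit(X, np.array([1.0, 2.0, 3.0]))
        assert np.allclose(sc.transform(X)[:, 0], 0.0)

    def test_target_round_trip(self):
        y = np.array([250.0, 300.0, 350.0])
        sc = ScalerPair().fit(np.zeros((3, 1)), y)
        _, ys = sc.transform(np.zeros((3, 1)), y)
        assert np.allclose(sc.inverse_y(ys), y, atol=1e-12)


class TestNetwork:
    def test_transfer_function_midpoint(self):
        assert log_sigmoid(0.0) == 0.5
        assert log_sigmoid(np.array([-np.inf, np.inf])) == pytest.approx([0, 1])

    def test_capacity_on_noiseless_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (200, 1))
        y = 2 * X[:, 0]
        scores = []
        for seed in range(5):
            net = train_net(X, y, NetworkSpec(hidden_nodes=4), seed=seed)
            scores.append(r2(y, net.predict(X)))
        assert np.median(scores) > 0.99

    def test_too_few_rows_guard(self):
        with pytest.raises(ValueError, match="too few"):
            train_net(np.zeros((10, 2)), np.zeros(10),
                      NetworkSpec(hidden_nodes=10))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (60, 2))
        y = X.sum(axis=1)
        a = train_net(X, y, NetworkSpec(4), seed=9).predict(X)
        b = train_net(X, y, NetworkSpec(4), seed=9).predict(X)
        assert np.array_equal(a, b)


class TestR2:
    def test_identities(self):
        a = np.array([1.0, 2.0, 3.0])
        assert r2(a, a) == 1.0
        assert r2(a, np.full(3, a.mean())) == 0.0
        assert r2(a, np.array([1.1, 1.9, 3.2])) == pytest.approx(0.97)

    def test_zero_variance_target_is_undefined(self):
        assert np.isnan(r2(np.full(5, 2.0), np.arange(5.0)))

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.normal(size=20)
            p = rng.normal(size=20)
            assert r2(a, p) == pytest.approx(r2_score(a, p), abs=1e-12)


class TestBlockedFolds:
    def test_contiguous_blocks_stratified_over_groups(self):
        groups = np.repeat([0, 1], 40)
        folds = blocked_folds(80, 4, groups)
        assert sorted(np.concatenate(folds).tolist()) == list(range(80))
        for f in folds:
            # one contiguous block per group
            per_group = [f[f < 40], f[f >= 40]]
            for blk in per_group:
                assert np.array_equal(blk, np.arange(blk[0], blk[-1] + 1))

    def test_permuting_test_rows_leaves_r2_unchanged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        p = a + rng.normal(0, 0.1, 30)
        perm = rng.permutation(30)
        assert r2(a[perm], p[perm]) == pytest.approx(r2(a, p), abs=1e-12)


class TestRunCV:
    @staticmethod
    def linear_problem(n=240, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 1.0, (n, 3))
        y = 100 * X[:, 0] + 50 * X[:, 1] + 200 * X[:, 2]
        return X, y

    def test_retrain_fold_bookkeeping(self):
        X, y = self.linear_problem()
        res = run_cv(X, y, CVSpec(folds=2, retrains=2, seed=0),
                     node_range=[2, 3])
        assert set(res.per_node) == {2, 3}
        for mean, sd, raw in res.per_node.values():
            assert raw.size == 4  # folds x retrains
            assert np.isfinite(sd)
        assert res.best_mean_r2 == max(m for m, _, _ in res.per_node.values())

    def test_noiseless_linear_relation_is_learned(self):
        X, y = self.linear_problem()
        res = run_cv(X, y, CVSpec(folds=4, retrains=1, seed=0),
                     node_range=[2, 3])
        for mean, _, _ in res.per_node.values():
            assert mean > 0.99

    def test_deterministic_under_seed(self):
        X, y = self.linear_problem()
        a = run_cv(X, y, CVSpec(folds=2, retrains=1, seed=5), node_range=[3])
        b = run_cv(X, y, CVSpec(folds=2, retrains=1, seed=5), node_range=[3])
        assert a.per_node[3][2] == pytest.approx(b.per_node[3][2], abs=0)


class TestComparison:
    def test_percent_increase_worked_examples(self):
        assert percent_increase(0.9093, 0.9255) == pytest.approx(1.7816,
                                                                 abs=1e-4)
        assert percent_increase(0.8656, 0.9209) == pytest.approx(6.389,
                                                                 abs=1e-2)
        assert percent_increase(0.5, 0.5) == 0.0
        assert np.isnan(percent_increase(0.0, 0.5))
        assert np.isnan(percent_increase(-0.2, 0.5))

    def test_identical_samples_give_null_ttest(self):
        v = np.array([0.8, 0.85, 0.9])
        rep = compare({"A": v, "B": v.copy()})
        t, p = rep.ttests["A_vs_B"]
        assert t == 0.0 and p == 1.0
        assert not rep.significant["A_vs_B"]
        assert rep.increases["A_vs_B"] == 0.0

    def test_consistent_advantage_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.8, 0.9, 10)
        rep = compare({"TMLM": base, "FMLM": base + 0.05})
        assert rep.significant["TMLM_vs_FMLM"]
        assert rep.increases["TMLM_vs_FMLM"] > 0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            compare({"A": np.ones(3), "B": np.ones(4)})

    def test_supplied_means_reproduce_percent_increase(self):
        rep = compare({"TMLM": np.array([0.8656] * 3),
                       "FMLM": np.array([0.9209] * 3)})
        assert rep.increases["TMLM_vs_FMLM"] == pytest.approx(
            percent_increase(0.8656, 0.9209), abs=1e-12)
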