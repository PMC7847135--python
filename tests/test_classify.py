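"""Stepwise LDA, split protocol, MLP training and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from spotmorph.classify import (
    MLPConfig,
    make_split,
    permutation_importance,
    search_topology,
    stepwise_lda,
    train_mlp,
    wilks_lambda,
)


def _two_group_frame(rng, n=30, sep=10.0):
    labels = np.array(["g1"] * n + ["g2"] * n)
    a = np.concatenate([rng.normal(0, 1, n), rng.normal(sep, 1, n)])
    b = rng.normal(0, 1, 2 * n)
    frame = pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(2 * n)])
    return frame, pd.Series(labels, index=frame.index)


def _three_group_frame(rng, n=25):
    labels = np.repeat(["g1", "g2", "g3"], n)
    x = np.concatenate([rng.normal(m, 1, n) for m in (0, 4, 8)])
    y = np.concatenate([rng.normal(m, 1, n) for m in (0, 3, 0)])
    noise = rng.normal(size=3 * n)
    frame = pd.DataFrame(
        {"x": x, "y": y, "noise": noise}, index=[f"s{i}" for i in range(3 * n)]
    )
    return frame, pd.Series(labels, index=frame.index)


class TestStepwiseLDA:
    def test_informative_variable_selected_noise_excluded(self, rng):
        frame, labels = _two_group_frame(rng)
        model = stepwise_lda(frame, labels)
        assert model.selected_vars == ["A"]
        assert model.accuracy_resub == 100.0

    def test_three_groups_give_two_canonical_axes(self, rng):
        frame, labels = _three_group_frame(rng)
        model = stepwise_lda(frame, labels)
        assert len(model.selected_vars) >= 2
        assert model.canonical_axes.shape[1] == 2

    def test_wilks_lambda_decreases_along_trace(self, rng):
        frame, labels = _three_group_frame(rng)
        model = stepwise_lda(frame, labels)
        enters = model.step_trace[model.step_trace["action"] == "enter"]
        assert (enters["wilks"].diff().dropna() < 0).all()
        assert 0 < model.wilks < 1

    def test_trace_reproducible(self, rng):
        frame, labels = _three_group_frame(rng)
        t1 = stepwise_lda(frame, labels).step_trace
        t2 = stepwise_lda(frame, labels).step_trace
        pd.testing.assert_frame_equal(t1, t2)

    def test_scores_invariant_to_feature_rescaling(self, rng):
        frame, labels = _three_group_frame(rng)
        m1 = stepwise_lda(frame, labels)
        rescaled = frame.copy()
        rescaled["x"] = rescaled["x"] * 37.0 + 5.0
        m2 = stepwise_lda(rescaled, labels)
        assert m1.selected_vars == m2.selected_vars
        for j in range(m1.scores.shape[1]):
            s1, s2 = m1.scores.iloc[:, j], m2.scores.iloc[:, j]
            assert min(np.abs(s1 - s2).max(), np.abs(s1 + s2).max()) < 1e-8

    def test_loo_not_better_than_resubstitution_on_average(self, rng):
        diffs = []
        for rep in range(15):
            frame, labels = _three_group_frame(np.random.default_rng(100 + rep), n=12)
            model = stepwise_lda(frame, labels)
            diffs.append(model.accuracy_resub - model.accuracy_loo)
        assert np.mean(diffs) >= 0

    def test_no_discriminative_variables_raises_unless_allowed(self, rng):
        n = 30
        frame = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        labels = pd.Series(np.repeat(["g1", "g2"], n // 2), index=frame.index)
        with pytest.raises(ValueError, match="no discriminative"):
            stepwise_lda(frame, labels, f_enter=1e6)
        model = stepwise_lda(frame, labels, f_enter=1e6, allow_empty=True)
        assert model.selected_vars == []

    def test_wilks_lambda_matches_anova_for_one_variable(self, rng):
        frame, labels = _two_group_frame(rng, sep=2.0)
        lam = wilks_lambda(frame[["A"]].to_numpy(), labels.to_numpy())
        import scipy.stats as sps

        f = sps.f_oneway(
            frame["A"][labels == "g1"], frame["A"][labels == "g2"]
        ).statistic
        n, g = len(frame), 2
        f_from_lambda = (1 / lam - 1) * (n - g) / (g - 1)
        assert f_from_lambda == pytest.approx(f, rel=1e-10)


class TestMakeSplit:
    def _labels(self):
        ids = (
            [f"h1_{i}" for i in range(39)]
            + [f"h2_{i}" for i in range(23)]
            + [f"h3_{i}" for i in range(39)]
        )
        return pd.Series(["H1"] * 39 + ["H2"] * 23 + ["H3"] * 39, index=ids)

    def test_sixty_percent_per_group_rounding(self):
        split = make_split(self._labels(), seed=1)
        sizes = pd.Series(self._labels()[split.train_ids]).value_counts()
        assert sizes["H1"] == 23 and sizes["H2"] == 14 and sizes["H3"] == 23

    def test_partition_is_disjoint_and_complete(self):
        labels = self._labels()
        split = make_split(labels, seed=2)
        assert set(split.train_ids) | set(split.validation_ids) == set(labels.index)
        assert not set(split.train_ids) & set(split.validation_ids)

    def test_forced_ids_always_validate(self):
        labels = self._labels()
        forced = ["h1_0", "h2_5", "h3_38"]
        for seed in range(100):
            split = make_split(labels, forced_validation_ids=forced, seed=seed)
            assert set(forced) <= set(split.validation_ids)

    def test_same_seed_same_split(self):
        labels = self._labels()
        s1 = make_split(labels, seed=7)
        s2 = make_split(labels, seed=7)
        assert s1.train_ids == s2.train_ids and s1.validation_ids == s2.validation_ids

    def test_unknown_forced_id_rejected(self):
        with pytest.raises(ValueError, match="forced"):
            make_split(self._labels(), forced_validation_ids=["nope"])


class TestTrainMLP:
    def test_separable_data_perfect_training(self, rng):
        frame, labels = _two_group_frame(rng)
        split = make_split(labels, seed=0)
        model = train_mlp(frame, labels, split, MLPConfig(hidden_units=10, seed=0))
        assert model.accuracy_train == 100.0
        assert model.accuracy_validation == 100.0

    def test_permuted_labels_validate_at_chance(self):
        accs = []
        for rep in range(5):
            rng = np.random.default_rng(200 + rep)
            frame, labels = _three_group_frame(rng, n=30)
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            split = make_split(permuted, seed=rep)
            model = train_mlp(frame, permuted, split, MLPConfig(hidden_units=10, seed=rep))
            accs.append(model.accuracy_validation / 100.0)
        n_val = 36  # 40% of 90
        band = 1.96 * np.sqrt((1 / 3) * (2 / 3) / (n_val * len(accs)))
        assert abs(np.mean(accs) - 1 / 3) < 3 * band + 0.05

    def test_deterministic_given_seed(self, rng):
        frame, labels = _three_group_frame(rng)
        split = make_split(labels, seed=3)
        m1 = train_mlp(frame, labels, split, MLPConfig(seed=5))
        m2 = train_mlp(frame, labels, split, MLPConfig(seed=5))
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        pd.testing.assert_frame_equal(m1.confusion_validation, m2.confusion_validation)

    @pytest.mark.parametrize("activation,loss", [("logistic", "cross_entropy"), ("sine", "sum_of_squares"), ("tanh", "sum_of_squares")])
    def test_alternative_activations_and_losses_learn(self, activation, loss):
        rng = np.random.default_rng(42)
        frame, labels = _two_group_frame(rng, sep=6.0)
        split = make_split(labels, seed=0)
        cfg = MLPConfig(hidden_units=8, hidden_activation=activation, loss=loss, seed=1)
        model = train_mlp(frame, labels, split, cfg)
        assert model.accuracy_train >= 95.0

    def test_gradient_matches_finite_differences(self):
        from scipy.optimize import check_grad

        from spotmorph.classify import _mlp_loss_grad

        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        onehot = np.eye(3)[rng.integers(0, 3, 12)]
        for act in ("tanh", "logistic", "sine"):
            for loss in ("cross_entropy", "sum_of_squares"):
                shapes = (3, 4, 3)
                theta = rng.normal(size=3 * 4 + 4 + 4 * 3 + 3) * 0.5
                err = check_grad(
                    lambda t: _mlp_loss_grad(t, x, onehot, shapes, act, loss, 1e-4)[0],
                    lambda t: _mlp_loss_grad(t, x, onehot, shapes, act, loss, 1e-4)[1],
                    theta,
                )
                assert err < 1e-5


class TestSearchTopology:
    def test_tie_break_prefers_fewer_units(self, rng):
        frame, labels = _two_group_frame(rng, sep=8.0)
        split = make_split(labels, seed=0)
        best, board = search_topology(frame, labels, split, hidden_grid=(5, 20), seed=0)
        top = board.iloc[0]
        if (board["accuracy_validation"] == top["accuracy_validation"]).sum() > 1:
            assert best.config.hidden_units == 5

    def test_single_element_grid(self, rng):
        frame, labels = _two_group_frame(rng)
        split = make_split(labels, seed=0)
        best, board = search_topology(frame, labels, split, hidden_grid=(7,), seed=0)
        assert best.config.hidden_units == 7 and len(board) == 1

    def test_leaderboard_deterministic(self, rng):
        frame, labels = _three_group_frame(rng, n=15)
        split = make_split(labels, seed=1)
        _, b1 = search_topology(frame, labels, split, hidden_grid=(5, 10), seed=2)
        _, b2 = search_topology(frame, labels, split, hidden_grid=(5, 10), seed=2)
        pd.testing.assert_frame_equal(b1, b2)


class TestPermutationImportance:
    def test_noise_variable_near_one_informative_greatest(self, rng):
        frame, labels = _two_group_frame(rng, n=50, sep=8.0)
        split = make_split(labels, seed=0)
        model = train_mlp(frame, labels, split, MLPConfig(hidden_units=8, seed=0))
        report = permutation_importance(model, frame, labels, reps=50, seed=1)
        assert 0.8 <= report.importance["B"] <= 1.2
        assert report.importance.idxmax() == "A"
        assert report.importance["A"] > report.importance["B"]

    def test_deterministic_given_seed(self, rng):
        frame, labels = _two_group_frame(rng)
        split = make_split(labels, seed=0)
        model = train_mlp(frame, labels, split, MLPConfig(hidden_units=5, seed=0))
        r1 = permutation_importance(model, frame, labels, reps=10, seed=9)
        r2 = permutation_importance(model, frame, labels, reps=10, seed=9)
        pd.testing.assert_series_equal(r1.importance, r2.importance)
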