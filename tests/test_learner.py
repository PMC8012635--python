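import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprank.features import FEATURE_NAMES
from sprank.learner import (
    backward_elimination,
    compute_target,
    feature_importance,
    inverse_transform,
    rank_moves,
    single_feature_models,
    train,
    transform_target,
)


def synthetic_frame(n_datasets=12, moves_per_dataset=40, noise=0.0, seed=0):
    """A labelled corpus table whose transformed target is a monotone
    function of the path-length feature plus optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_datasets):
        ll_start = -float(rng.uniform(800, 4000))
        X = rng.uniform(0.0, 2.0, size=(moves_per_dataset, len(FEATURE_NAMES)))
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        df["topo_dist"] = rng.integers(1, 12, moves_per_dataset)
        target = 0.002 * df["bl_dist"] + 0.0005 * df["topo_dist"] - 0.0015
        target = target + noise * rng.normal(size=moves_per_dataset)
        df["dataset_id"] = f"d{d:02d}"
        df["move_id"] = np.arange(moves_per_dataset)
        df["ll_start"] = ll_start
        df["target"] = target
        df["ll_neighbor"] = ll_start + target * ll_start
        df["transformed_target"] = transform_target(target)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestTargetAlgebra:
    def test_compute_target_examples(self):
        assert compute_target(-1010.0, -1010.0) == 0.0
        assert compute_target(-1000.0, -1010.0) == pytest.approx(10 / -1010)
        assert compute_target(-1020.0, -1010.0) == pytest.approx(10 / 1010)
        with pytest.raises(ValueError):
            compute_target(-1.0, 0.0)

    def test_improvement_gives_negative_target(self):
        # better neighbor (higher LL) => negative target because ll_start < 0
        assert compute_target(-900.0, -1000.0) < 0
        assert compute_target(-1100.0, -1000.0) > 0

    def test_transform_fixed_points(self):
        assert transform_target(0.0) == 2.0
        assert transform_target(-1.0) == 1.0

    def test_round_trip_identity_on_grid(self):
        grid = np.linspace(-2, 2, 401)
        assert np.max(np.abs(inverse_transform(transform_target(grid)) - grid)) < 1e-12

    def test_transform_is_strictly_monotone(self):
        grid = np.linspace(-3, 3, 100)
        assert np.all(np.diff(transform_target(grid)) > 0)

    def test_inverse_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            inverse_transform(0.0)

    @given(st.floats(min_value=-5.0, max_value=5.0, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_transform_round_trip_property(self, t):
        assert inverse_transform(transform_target(t)) == pytest.approx(t, abs=1e-10)

    @given(
        st.lists(st.floats(min_value=-0.5, max_value=0.5), min_size=2, max_size=30),
        st.floats(min_value=-1e6, max_value=-1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_transform_preserves_ranking_property(self, targets, ll_start):
        # because ll_start < 0 and the transform is increasing, sorting by
        # transformed prediction ascending equals sorting by predicted
        # delta-LL descending
        preds = transform_target(np.array(targets))
        delta = inverse_transform(preds) * ll_start
        assert list(np.argsort(preds, kind="stable")) == list(
            np.argsort(-delta, kind="stable")
        )


class TestTraining:
    def test_deterministic_given_seed(self):
        frame = synthetic_frame()
        X = frame[list(FEATURE_NAMES)].to_numpy()
        y = frame["transformed_target"].to_numpy()
        m1 = train(X, y, seed=5)
        m2 = train(X, y, seed=5)
        probe = X[:50]
        assert np.array_equal(m1.predict_transformed(probe), m2.predict_transformed(probe))

    def test_max_features_is_ceiling_of_one_third(self):
        frame = synthetic_frame(n_datasets=2)
        model = train(
            frame[list(FEATURE_NAMES)].to_numpy(),
            frame["transformed_target"].to_numpy(),
        )
        assert model.forest.max_features == 7  # ceil(19 / 3)
        assert model.forest.n_estimators == 70

    def test_nan_feature_raises_with_location(self):
        X = np.ones((5, 19))
        X[3, 4] = np.nan
        with pytest.raises(ValueError, match="row 3.*topo_dist"):
            train(X, np.ones(5))

    def test_noiseless_signal_learned(self):
        frame = synthetic_frame(n_datasets=16, moves_per_dataset=60)
        test_ids = {"d00", "d01"}
        test = frame[frame.dataset_id.isin(test_ids)]
        tr = frame[~frame.dataset_id.isin(test_ids)]
        model = train(
            tr[list(FEATURE_NAMES)].to_numpy(), tr["transformed_target"].to_numpy(), seed=0
        )
        from scipy.stats import spearmanr

        pred = model.predict_transformed(test[list(FEATURE_NAMES)].to_numpy())
        rho = spearmanr(test["transformed_target"], pred).statistic
        assert rho > 0.95

    def test_save_load_round_trip(self, tmp_path):
        frame = synthetic_frame(n_datasets=2)
        X = frame[list(FEATURE_NAMES)].to_numpy()
        model = train(X, frame["transformed_target"].to_numpy(), seed=1)
        path = tmp_path / "rf.joblib"
        model.save(str(path))
        from sprank.learner import RankModel

        loaded = RankModel.load(str(path))
        assert loaded.feature_names == model.feature_names
        assert np.array_equal(loaded.predict_transformed(X[:10]), model.predict_transformed(X[:10]))


class TestRanking:
    def test_sign_discipline(self):
        class Fixed:
            feature_names = ("f",)

            def predict_transformed(self, X):
                # targets -0.01 (improvement) and +0.01 (worsening)
                return transform_target(np.array([-0.01, 0.01]))

        ranking = rank_moves(Fixed(), np.zeros((2, 1)), ll_start=-1000.0)
        assert list(ranking["move_id"]) == [0, 1]
        assert ranking["predicted_delta_ll"].iloc[0] == pytest.approx(10.0)
        assert ranking["predicted_delta_ll"].iloc[1] == pytest.approx(-10.0)

    def test_tie_break_by_move_id(self):
        class Const:
            feature_names = ("f",)

            def predict_transformed(self, X):
                return np.full(len(X), 2.0)

        ranking = rank_moves(Const(), np.zeros((6, 1)), ll_start=-100.0)
        assert list(ranking["move_id"]) == list(range(6))

    def test_matches_brute_force_resort(self):
        rng = np.random.default_rng(8)
        preds = transform_target(rng.normal(0, 0.01, 50))

        class R:
            feature_names = ("f",)

            def predict_transformed(self, X):
                return preds

        ll_start = -1234.5
        ranking = rank_moves(R(), np.zeros((50, 1)), ll_start)
        expected = np.argsort(inverse_transform(preds) * ll_start, kind="stable")[::-1]
        brute = sorted(range(50), key=lambda i: (-(inverse_transform(preds[i]) * ll_start), i))
        assert list(ranking["move_id"]) == brute

    def test_requires_negative_ll_start(self):
        class R:
            feature_names = ("f",)

            def predict_transformed(self, X):
                return np.ones(len(X))

        with pytest.raises(ValueError):
            rank_moves(R(), np.zeros((3, 1)), ll_start=10.0)


class TestFeatureStudies:
    def test_importances_sum_to_one_and_constant_feature_is_zero(self):
        frame = synthetic_frame(n_datasets=4)
        frame["longest_branch"] = 1.0  # constant column can never split
        model = train(
            frame[list(FEATURE_NAMES)].to_numpy(),
            frame["transformed_target"].to_numpy(),
            seed=3,
        )
        imp = feature_importance(model)
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.set_index("feature").loc["longest_branch", "importance"] == 0.0
        assert np.all(np.diff(imp["importance"].to_numpy()) <= 0)

    def test_single_feature_models_find_the_signal(self):
        frame = synthetic_frame(n_datasets=8, moves_per_dataset=50)
        table = single_feature_models(frame, k=4, seed=0)
        assert set(table["feature"]) == set(FEATURE_NAMES)
        # the two signal-carrying features dominate
        assert table["feature"].iloc[0] in ("bl_dist", "topo_dist")

    def test_backward_elimination_structure(self):
        frame = synthetic_frame(n_datasets=6, moves_per_dataset=30)
        table = backward_elimination(frame, k=3, seed=0)
        assert list(table["n_features"]) == list(range(19, 0, -1))
        sets = [set(s) for s in table["features"]]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller < bigger
            (dropped,) = bigger - smaller
        # each dropped feature is the recorded minimal-importance one
        for row, smaller in zip(table.itertuples(), sets[1:]):
            assert row.next_dropped not in smaller
        # full set does at least as well as the single survivor
        assert table["mean_rho"].iloc[0] >= table["mean_rho"].iloc[-1] - 0.05
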