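"""Cox log-risk network: loss identities, gradients, training contracts."""

import numpy as np
import pandas as pd
import pytest

from dnmbc.network import (
    NetworkConfig,
    SearchSpace,
    _backward,
    _forward,
    encode_features,
    load_model,
    neg_log_partial_likelihood,
    partial_likelihood_grad,
    predict_log_risk,
    random_search,
    save_model,
    train,
)
from dnmbc.survival import concordance, cox_fit


# --------------------------------------------------------------------------
# Encoding
# --------------------------------------------------------------------------

class TestEncoding:
    def test_two_level_factor_gives_one_column(self, small_cohort):
        x, enc = encode_features(
            small_cohort.df, ["marital"], "CW", ("CW", "NS", "SC"),
            scheme=small_cohort.scheme,
        )
        assert enc.columns[:1] == ["marital=Unmarried"]
        assert x.shape[1] == 1 + 2  # factor + two treatment indicators

    def test_three_level_treatment_flags_two_columns(self, small_cohort):
        x, enc = encode_features(
            small_cohort.df, ["grade"], small_cohort.df["arm"],
            ("CW", "NS", "SC"), scheme=small_cohort.scheme,
        )
        assert [enc.columns[i] for i in enc.treatment_cols] == [
            "treatment=NS", "treatment=SC"
        ]

    def test_deterministic(self, small_cohort):
        args = (small_cohort.df, ["grade", "t_stage"], "CW", ("CW", "NS", "SC"))
        x1, _ = encode_features(*args, scheme=small_cohort.scheme)
        x2, _ = encode_features(*args, scheme=small_cohort.scheme)
        assert np.array_equal(x1, x2)

    def test_unseen_level_rejected(self, small_cohort):
        _, enc = encode_features(
            small_cohort.df, ["grade"], "CW", ("CW", "NS", "SC"),
            scheme=small_cohort.scheme,
        )
        bad = small_cohort.df.head(3).copy()
        bad["grade"] = "V"
        with pytest.raises(ValueError, match="unseen"):
            enc.transform(bad, "CW")
        with pytest.raises(ValueError, match="treatment"):
            enc.transform(small_cohort.df.head(3), "XX")


# --------------------------------------------------------------------------
# Loss
# --------------------------------------------------------------------------

class TestLoss:
    def test_single_event_equal_risks_is_log_n(self):
        for n in (2, 5, 17):
            h = np.zeros(n)
            t = np.arange(1, n + 1, dtype=float)
            e = np.zeros(n, dtype=int)
            e[0] = 1
            assert neg_log_partial_likelihood(h, t, e) == pytest.approx(
                np.log(n), abs=1e-12
            )

    def test_shift_invariance(self, rng):
        h = rng.normal(size=40)
        t = rng.integers(1, 30, 40).astype(float)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        base = neg_log_partial_likelihood(h, t, e)
        for c in (-100.0, -3.3, 7.7, 250.0):
            assert neg_log_partial_likelihood(h + c, t, e) == pytest.approx(
                base, abs=1e-9
            )

    def test_matches_cox_partial_likelihood_at_optimum(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([[1.0], [0.0], [1.0], [0.0]])
        fit = cox_fit(x, times, events, ties="breslow")
        loss = neg_log_partial_likelihood(x @ fit.coef, times, events)
        assert loss == pytest.approx(-fit.loglik / events.sum(), abs=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            neg_log_partial_likelihood([0.0, 0.0], [1.0, 2.0], [0, 0])

    def test_gradient_matches_finite_differences(self, rng):
        h = rng.normal(size=25)
        t = rng.integers(1, 10, 25).astype(float)  # heavy ties on purpose
        e = rng.integers(0, 2, 25)
        e[:3] = 1
        grad = partial_likelihood_grad(h, t, e)
        eps = 1e-6
        for k in range(25):
            hp, hm = h.copy(), h.copy()
            hp[k] += eps
            hm[k] -= eps
            fd = (
                neg_log_partial_likelihood(hp, t, e)
                - neg_log_partial_likelihood(hm, t, e)
            ) / (2 * eps)
            assert grad[k] == pytest.approx(fd, abs=1e-7)


def test_backprop_matches_finite_differences(rng):
    """End-to-end parameter-gradient check through BN + ReLU + linear layers."""
    n, p = 30, 4
    x = rng.normal(size=(n, p))
    t = rng.integers(1, 15, n).astype(float)
    e = rng.integers(0, 2, n)
    e[:5] = 1
    config = NetworkConfig(
        n_hidden_layers=2, nodes_per_layer=5, dropout=0.0, batch_norm=True,
        max_epochs=1, seed=0,
    )
    from dnmbc.network import _init_params

    layers = _init_params(p, config, np.random.default_rng(0))

    def loss_at(layers_):
        h, _ = _forward(layers_, x, config, train_mode=True)
        return neg_log_partial_likelihood(h, t, e)

    h, cache = _forward(layers, x, config, train_mode=True)
    grads = _backward(layers, cache, partial_likelihood_grad(h, t, e), config)
    eps = 1e-6
    for li in (0, 2):
        for key in ("W", "b"):
            flat_idx = (0, 0) if grads[li][key].ndim == 2 else (0,)
            import copy

            lp = copy.deepcopy(layers)
            lm = copy.deepcopy(layers)
            lp[li][key][flat_idx] += eps
            lm[li][key][flat_idx] -= eps
            fd = (loss_at(lp) - loss_at(lm)) / (2 * eps)
            assert grads[li][key][flat_idx] == pytest.approx(fd, abs=1e-6)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _training_data(recovery_cohort):
    df = recovery_cohort.df
    x = np.column_stack([
        (df["grade"] == "III/IV").to_numpy(float),
        (df["metastases"] == "Brain").to_numpy(float),
        (df["arm"] == "NS").to_numpy(float),
    ])
    return x, df["time_months"].to_numpy(float), df["event_os"].to_numpy(int)


class TestTraining:
    def test_same_seed_identical_result(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        config = NetworkConfig(
            n_hidden_layers=1, nodes_per_layer=8, dropout=0.2,
            max_epochs=30, early_stop_patience=0, seed=7,
        )
        m1 = train(x, t, e, config)
        m2 = train(x, t, e, config)
        assert m1.history["train_loss"].iloc[-1] == m2.history["train_loss"].iloc[-1]
        assert np.array_equal(m1.predict(x), m2.predict(x))

    def test_linear_model_is_exact_affine_map(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        config = NetworkConfig(
            n_hidden_layers=0, dropout=0.0, batch_norm=False,
            max_epochs=20, early_stop_patience=0, seed=1,
        )
        model = train(x, t, e, config)
        w = model.layers[0]["W"].ravel()
        b = model.layers[0]["b"][0]
        assert model.predict(x) == pytest.approx(x @ w + b, abs=1e-12)

    def test_eval_mode_invariant_to_batch_composition(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        config = NetworkConfig(
            n_hidden_layers=2, nodes_per_layer=8, dropout=0.3,
            max_epochs=25, early_stop_patience=0, seed=3,
        )
        model = train(x, t, e, config)
        whole = model.predict(x[:50])
        parts = np.concatenate([model.predict(x[:17]), model.predict(x[17:50])])
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_permuted_outcomes_give_null_discrimination(self, recovery_cohort, rng):
        x, t, e = _training_data(recovery_cohort)
        perm = rng.permutation(len(t))
        config = NetworkConfig(
            n_hidden_layers=1, nodes_per_layer=8, dropout=0.1,
            max_epochs=60, early_stop_patience=0, seed=5,
        )
        model = train(x, t[perm], e[perm], config)
        c = concordance(t[perm], e[perm], model.predict(x)).c
        assert c == pytest.approx(0.5, abs=0.05)

    def test_divergence_aborts_with_diagnostic(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        config = NetworkConfig(
            n_hidden_layers=1, nodes_per_layer=8, learning_rate=1e4,
            grad_clip_norm=None, max_epochs=50, early_stop_patience=0, seed=0,
        )
        with pytest.raises(RuntimeError, match="diverged"):
            train(x * 1e3, t, e, config)

    def test_too_few_events_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            train(x, np.arange(1.0, 11.0), np.zeros(10, int), NetworkConfig(max_epochs=5))

    def test_epoch_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            NetworkConfig(max_epochs=1001)


class TestRandomSearch:
    def test_single_draw_returns_that_config(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        space = SearchSpace(
            choices={"n_hidden_layers": [1], "nodes_per_layer": [4],
                     "max_epochs": [15], "early_stop_patience": [0]},
            n_draws=1, seed=0,
        )
        config, model, board = random_search(x, t, e, space, seed=0)
        assert config.n_hidden_layers == 1 and config.nodes_per_layer == 4
        assert len(board) == 1

    def test_reproducible_leaderboard(self, recovery_cohort):
        x, t, e = _training_data(recovery_cohort)
        space = SearchSpace(
            choices={"n_hidden_layers": [0, 1], "nodes_per_layer": [4, 8],
                     "max_epochs": [15], "early_stop_patience": [0]},
            n_draws=3, seed=4,
        )
        _, _, b1 = random_search(x, t, e, space, seed=9)
        _, _, b2 = random_search(x, t, e, space, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_informative_model_beats_zero_capacity(self, recovery_cohort):
        # a linear model with real inputs vs an intercept-like all-dropout net
        x, t, e = _training_data(recovery_cohort)
        space = SearchSpace(
            choices={"n_hidden_layers": [0], "dropout": [0.0],
                     "batch_norm": [False], "max_epochs": [60],
                     "early_stop_patience": [0], "learning_rate": [0.05, 1e-7]},
            n_draws=6, seed=1,
        )
        config, _, board = random_search(x, t, e, space, seed=2)
        assert config.learning_rate == 0.05
        assert board["val_c"].max() == board.loc[board["learning_rate"] == 0.05, "val_c"].max()

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SearchSpace(choices={"bogus": [1]}, n_draws=1)


class TestPersistence:
    def test_save_load_round_trip(self, recovery_cohort, tmp_path):
        df = recovery_cohort.df
        x, enc = encode_features(
            df, ["grade", "t_stage"], df["arm"], ("CW", "NS", "SC"),
            scheme=recovery_cohort.scheme,
        )
        config = NetworkConfig(
            n_hidden_layers=1, nodes_per_layer=6, max_epochs=20,
            early_stop_patience=0, seed=2,
        )
        model = train(x, df["time_months"], df["event_os"], config, encoding=enc)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.config == model.config
        assert np.array_equal(
            predict_log_risk(back, df, df["arm"]),
            predict_log_risk(model, df, df["arm"]),
        )
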