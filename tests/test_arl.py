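"""Active-reinforcement loop: entropy selection, state discretization,
Q-learning updates, pseudo-labeling, loop mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arlnet.arl import (ARLConfig, QTable, arl_loop, prediction_entropy,
                        pseudo_label_batch, q_update, reward, select_uncertain,
                        state_key)


class TestEntropy:
    def test_maximum_at_half(self):
        assert prediction_entropy(0.5) == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_at_certainty(self):
        assert prediction_entropy(1.0) == 0.0
        assert prediction_entropy(0.0) == 0.0

    def test_hand_value_at_09(self):
        assert prediction_entropy(0.9) == pytest.approx(0.3251, abs=5e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            prediction_entropy(1.2)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, p):
        h = prediction_entropy(p)
        assert 0.0 <= h <= np.log(2) + 1e-12
        assert h == pytest.approx(prediction_entropy(1 - p), abs=1e-12)


class TestSelectUncertain:
    def test_ranked_truncated_selection(self):
        # entropies ~ (0.693, 0.098, 0.500)
        probs = np.array([0.5, 0.985, 0.80])
        assert list(select_uncertain(probs, k=2, threshold=0.3)) == [0, 2]

    def test_all_below_threshold_empty(self):
        assert len(select_uncertain(np.array([0.99, 0.01]), 2, 0.3)) == 0

    def test_k_larger_than_qualifying(self):
        probs = np.array([0.5, 0.5, 0.99])
        assert len(select_uncertain(probs, k=10, threshold=0.3)) == 2

    def test_ties_keep_batch_order(self):
        selected = select_uncertain(np.array([0.5, 0.5, 0.5]), 2, 0.1)
        assert list(selected) == [0, 1]


class TestStateKey:
    def test_identical_vectors_equal_keys(self):
        v = np.random.default_rng(0).normal(size=20)
        assert state_key(v) == state_key(v.copy())

    def test_within_bin_perturbation_same_key(self):
        v = np.full(10, 0.1)
        assert state_key(v) == state_key(v + 1e-6)

    def test_distinct_bins_rarely_collide(self):
        rng = np.random.default_rng(1)
        keys = set()
        n = 1000
        for _ in range(n):
            keys.add(state_key(rng.integers(0, 4, size=16) - 1.5, bins=4))
        assert len(keys) > n * 0.99

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            state_key(np.array([1.0, np.nan]))


class TestRewardAndQUpdate:
    @pytest.mark.parametrize("action,pred,expected",
                             [(1, 1, 1), (0, 1, -1), (0, 0, 1), (1, 0, -1)])
    def test_reward_is_match_indicator(self, action, pred, expected):
        assert reward(action, pred) == expected

    def test_terminal_update_hand_values(self):
        cfg = ARLConfig()
        q = QTable()
        q_update(q, "s", 0, +1, None, cfg)
        assert q.get("s")[0] == pytest.approx(0.1)
        q_update(q, "s", 0, +1, None, cfg)
        assert q.get("s")[0] == pytest.approx(0.19)

    def test_bootstrap_update_hand_value(self):
        cfg = ARLConfig()
        q = QTable()
        q.set("next", np.array([0.0, 1.0]))
        q_update(q, "s", 0, +1, "next", cfg)
        assert q.get("s")[0] == pytest.approx(0.195)

    def test_only_target_entry_changes(self):
        cfg = ARLConfig()
        q = QTable()
        q.set("other", np.array([0.4, 0.6]))
        q_update(q, "s", 1, -1, None, cfg)
        assert np.array_equal(q.get("other"), [0.4, 0.6])
        assert q.get("s")[0] == 0.0


class TestPseudoLabeling:
    def test_converges_to_model_predictions(self):
        cfg = ARLConfig(episodes_per_batch=50)
        rng = np.random.default_rng(0)
        keys = [f"s{i}" for i in range(10)]
        preds = np.array([0, 1] * 5)
        q = QTable()
        labels = pseudo_label_batch(q, keys, preds, cfg, rng)
        assert np.array_equal(labels, preds)
        for k, pred in zip(keys, preds):
            assert q.get(k)[pred] > q.get(k)[1 - pred]

    def test_zero_episodes_tie_break_to_zero(self):
        cfg = ARLConfig(episodes_per_batch=0)
        labels = pseudo_label_batch(QTable(), ["a", "b"], np.array([1, 1]),
                                    cfg, np.random.default_rng(0))
        assert np.array_equal(labels, [0, 0])

    def test_qtable_growth_bounded_by_selection(self):
        cfg = ARLConfig(episodes_per_batch=3)
        q = QTable()
        keys = [f"k{i}" for i in range(7)]
        pseudo_label_batch(q, keys, np.ones(7, dtype=int), cfg,
                           np.random.default_rng(0))
        assert len(q) <= 7

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            pseudo_label_batch(QTable(), [], np.array([]), ARLConfig(),
                               np.random.default_rng(0))


class _MockModel:
    """Deterministic stand-in classifier: probability is a hash of the
    sample content, kept near 0.5 so every sample is uncertain."""

    def predict_proba(self, X):
        X = np.asarray(X)
        s = X.reshape(len(X), -1).sum(axis=1)
        return 0.45 + 0.1 * ((np.abs(np.sin(s * 1000)) * 997) % 1)

    def pooled_features(self, X):
        X = np.asarray(X)
        return X.reshape(len(X), -1)[:, :4]


class TestLoopMechanics:
    def test_iteration_count_is_ceiling_division(self):
        cfg = ARLConfig(batch_size=200, episodes_per_batch=1,
                        state_mode="probability", seed=0)
        pool = np.random.default_rng(0).random((1000, 2, 2))
        labeled = (np.random.default_rng(1).random((10, 2, 2)),
                   np.array([0, 1] * 5))
        _, _, history = arl_loop(labeled, pool, _MockModel(), cfg)
        assert len(history) == 5

    def test_pool_conservation_and_growth(self):
        cfg = ARLConfig(batch_size=64, episodes_per_batch=1,
                        state_mode="probability", seed=0)
        pool = np.random.default_rng(0).random((256, 2, 2))
        labeled = (np.random.default_rng(1).random((16, 2, 2)),
                   np.ones(16, dtype=int))
        _, _, history = arl_loop(labeled, pool, _MockModel(), cfg)
        frame = history.to_frame()
        assert (frame["labeled_pool"].diff().dropna() >= 0).all()
        total = frame.iloc[-1][["labeled_pool", "remaining_unlabeled", "skipped"]].sum()
        assert total == 16 + 256

    def test_empty_pool_is_noop(self):
        model = _MockModel()
        out, q, history = arl_loop((np.zeros((2, 2, 2)), np.zeros(2, dtype=int)),
                                   np.empty((0, 2, 2)), model, ARLConfig())
        assert len(history) == 0 and len(q) == 0

    def test_max_iterations_respected(self):
        cfg = ARLConfig(batch_size=10, max_iterations=3, episodes_per_batch=1,
                        state_mode="probability", seed=0)
        pool = np.random.default_rng(0).random((200, 2, 2))
        _, _, history = arl_loop((np.zeros((4, 2, 2)), np.zeros(4, dtype=int)),
                                 pool, _MockModel(), cfg)
        assert len(history) == 3


class TestARLConfigValidation:
    @pytest.mark.parametrize("kwargs", [dict(alpha=0.0), dict(alpha=1.5),
                                        dict(gamma=1.0), dict(epsilon=-0.1),
                                        dict(batch_size=0),
                                        dict(state_mode="pixels")])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ARLConfig(**kwargs)


def test_qtable_json_roundtrip(tmp_path):
    q = QTable()
    q.set("a", np.array([0.1, -0.2]))
    path = tmp_path / "q.json"
    q.to_json(path)
    back = QTable.from_json(path)
    assert np.allclose(back.get("a"), [0.1, -0.2])
    assert back.greedy_action("a") == 0
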