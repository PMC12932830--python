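"""Active-reinforcement pseudo-labeling loop.

The unlabeled pool is consumed in batches (200 images by default).  For
each batch the current classifier predicts class probabilities; the
prediction entropy H(p) = -[p ln p + (1-p) ln(1-p)] ranks the samples,
and those above a threshold (top-k) are handed to a tabular Q-learning
agent that assigns the pseudo-labels.  The agent's Markov decision
process is: states are discretized image feature vectors, actions are
the two labels, the transition moves to the next sample in the selected
batch, and the reward is +1 when the chosen label matches the
classifier's own predicted class and -1 otherwise.  Q-values follow the
standard update

    Q(s,a) <- Q(s,a) + alpha * [r + gamma * max_a' Q(s',a') - Q(s,a)]

with alpha = 0.1, gamma = 0.95 and epsilon-greedy exploration at
epsilon = 0.1.  Pseudo-labeled samples are unioned into the labeled pool
and the classifier is retrained; the loop runs until the pool is
exhausted or ``max_iterations`` (120) is reached.

A tabular Q-function over continuous feature vectors needs a discrete
state: each standardized feature is clipped to [-2, 2] and quantized
into ``state_bins`` equal bins, and the bin tuple is hashed to a stable
key.  A coarser alternative (``state_mode='probability'``) bins only the
model's predicted probability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import confusion_matrix, roc_pr_brier, threshold_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARLConfig:
    batch_size: int = 200
    top_k_fraction: float = 0.5          # of the qualifying batch
    entropy_threshold: float = 0.3       # nats
    alpha: float = 0.1
    gamma: float = 0.95
    epsilon: float = 0.1
    max_iterations: int = 120
    episodes_per_batch: int = 10
    retrain_epochs: int = 5
    state_bins: int = 4
    state_mode: str = "features"         # or "probability"
    recycle_unselected: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must be in [0, 1)")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.state_mode not in ("features", "probability"):
            raise ValueError("state_mode must be 'features' or 'probability'")


class QTable:
    """state key -> 2 action values (0 = non-cancer, 1 = cancer);
    unseen keys read as zeros."""

    def __init__(self) -> None:
        self._q: dict[str, np.ndarray] = {}

    def get(self, key: str) -> np.ndarray:
        return self._q.get(key, np.zeros(2))

    def set(self, key: str, values: np.ndarray) -> None:
        self._q[key] = np.asarray(values, dtype=float)

    def __len__(self) -> int:
        return len(self._q)

    def __contains__(self, key: str) -> bool:
        return key in self._q

    def greedy_action(self, key: str) -> int:
        """Argmax action; ties (including unseen states) resolve to 0."""
        q = self.get(key)
        return int(q[1] > q[0])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(v) for k, v in self._q.items()}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "QTable":
        table = cls()
        with open(path) as fh:
            for k, v in json.load(fh).items():
                table.set(k, np.array(v))
        return table


def prediction_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """Binary Shannon entropy in nats, with 0*ln(0) = 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0))
    return float(h) if h.ndim == 0 else h


def select_uncertain(probs: np.ndarray, k: int,
                     threshold: float) -> np.ndarray:
    """Indices of the top-k samples with entropy >= threshold, ranked by
    entropy descending; ties keep original batch order; may be shorter
    than k (possibly empty)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    h = prediction_entropy(np.asarray(probs, dtype=float))
    qualifying = np.flatnonzero(h >= threshold)
    if qualifying.size == 0:
        logger.info("no sample meets the entropy threshold %.3f", threshold)
        return qualifying
    order = qualifying[np.argsort(-h[qualifying], kind="stable")]
    return order[:k]


def state_key(vector: np.ndarray, bins: int = 4,
              lo: float = -2.0, hi: float = 2.0) -> str:
    """Stable discrete key for a (standardized) feature vector: clip to
    [lo, hi], quantize each dimension into ``bins`` equal bins, hash the
    bin tuple."""
    v = np.asarray(vector, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("feature vector must be finite")
    clipped = np.clip(v, lo, hi)
    idx = np.minimum(((clipped - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    return hashlib.blake2b(idx.tobytes(), digest_size=12).hexdigest()


def reward(action: int, model_prediction: int) -> int:
    """+1 when the pseudo-label matches the model's predicted class,
    -1 otherwise."""
    return 1 if int(action) == int(model_prediction) else -1


def q_update(q: QTable, s: str, a: int, r: float, s_next: str | None,
             config: ARLConfig) -> QTable:
    """One Q-learning update in place; ``s_next is None`` marks the
    terminal transition (bootstrap term 0)."""
    values = q.get(s).copy()
    bootstrap = 0.0 if s_next is None else float(q.get(s_next).max())
    values[a] += config.alpha * (r + config.gamma * bootstrap - values[a])
    q.set(s, values)
    return q


def pseudo_label_batch(q: QTable, state_keys: list[str],
                       model_predictions: np.ndarray, config: ARLConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Run epsilon-greedy episodes over the selected samples (in
    selection order; the transition is 'move to the next image') and
    return the final greedy pseudo-labels."""
    if len(state_keys) == 0:
        raise ValueError("selection must be non-empty")
    preds = np.asarray(model_predictions, dtype=int)
    n = len(state_keys)
    for _ in range(config.episodes_per_batch):
        for i in range(n):
            s = state_keys[i]
            if rng.random() < config.epsilon:
                a = int(rng.integers(0, 2))
            else:
                a = q.greedy_action(s)
            r = reward(a, preds[i])
            s_next = state_keys[i + 1] if i + 1 < n else None
            q_update(q, s, a, r, s_next, config)
    return np.array([q.greedy_action(s) for s in state_keys], dtype=int)


@dataclass
class ARLHistory:
    """Per-iteration validation metrics and pool bookkeeping."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _val_metrics(model, val: tuple[np.ndarray, np.ndarray]) -> dict:
    Xv, yv = val
    p = model.predict_proba(Xv)
    cm = confusion_matrix(yv, p)
    m = threshold_metrics(cm)
    out = {"accuracy": m["accuracy"], "precision": m["precision"],
           "recall": m["recall"], "f1": m["f1"]}
    try:
        auc, _, _ = roc_pr_brier(yv, p)
        out["roc_auc"] = auc
    except ValueError:
        out["roc_auc"] = float("nan")
    return out


def arl_loop(labeled: tuple[np.ndarray, np.ndarray], unlabeled: np.ndarray,
             model, config: ARLConfig,
             val: tuple[np.ndarray, np.ndarray] | None = None,
             feature_fn=None, retrain_fn=None,
             true_unlabeled_labels: np.ndarray | None = None
             ) -> tuple[object, QTable, ARLHistory]:
    """Run the full active-reinforcement loop.

    ``feature_fn(images) -> (n, d) array`` supplies the state vectors
    (default: the model's 128-dim pooled features, standardized within
    the batch; with ``state_mode='probability'`` the predicted
    probability is used instead).  ``retrain_fn(model, X, y)`` retrains
    the classifier on the expanded pool (default: a no-op for models
    without a trainer; pass ``models.train_model`` wrapped with a
    config).  ``true_unlabeled_labels`` is phantom-only bookkeeping used
    to log pseudo-label noise; it never influences the loop.
    """
    X_lab = np.asarray(labeled[0])
    y_lab = np.asarray(labeled[1], dtype=int)
    X_unl = np.asarray(unlabeled)
    n_total = len(X_lab) + len(X_unl)
    q = QTable()
    history = ARLHistory()
    rng = np.random.default_rng(config.seed)
    if len(X_unl) == 0:
        logger.warning("unlabeled pool is empty: nothing to do")
        return model, q, history

    cursor = 0
    n_skipped = 0
    remaining_truth = true_unlabeled_labels
    iteration = 0
    while cursor < len(X_unl) and iteration < config.max_iterations:
        iteration += 1
        batch = X_unl[cursor:cursor + config.batch_size]
        truth = None
        if remaining_truth is not None:
            truth = remaining_truth[cursor:cursor + config.batch_size]
        cursor += len(batch)

        probs = model.predict_proba(batch)
        k = max(1, int(round(config.top_k_fraction * len(batch))))
        selected = select_uncertain(probs, k, config.entropy_threshold)
        unselected = np.setdiff1d(np.arange(len(batch)), selected)
        if config.recycle_unselected and unselected.size:
            X_unl = np.concatenate([X_unl, batch[unselected]])
            if remaining_truth is not None:
                remaining_truth = np.concatenate(
                    [remaining_truth, truth[unselected]])
        else:
            n_skipped += len(batch) - len(selected)

        n_pseudo = 0
        noise = float("nan")
        if len(selected) > 0:
            sel_imgs = batch[selected]
            sel_preds = (probs[selected] >= 0.5).astype(int)
            if config.state_mode == "probability":
                vectors = probs[selected, None]
                keys = [state_key(v, config.state_bins, 0.0, 1.0) for v in vectors]
            else:
                if feature_fn is not None:
                    vectors = np.asarray(feature_fn(sel_imgs))
                else:
                    vectors = model.pooled_features(sel_imgs)
                mu, sd = vectors.mean(axis=0), vectors.std(axis=0)
                vectors = (vectors - mu) / np.where(sd == 0, 1.0, sd)
                keys = [state_key(v, config.state_bins) for v in vectors]
            pseudo = pseudo_label_batch(q, keys, sel_preds, config, rng)
            X_lab = np.concatenate([X_lab, sel_imgs])
            y_lab = np.concatenate([y_lab, pseudo])
            n_pseudo = len(pseudo)
            if truth is not None:
                noise = float(np.mean(pseudo != truth[selected]))
            if retrain_fn is not None:
                retrain_fn(model, X_lab, y_lab)

        row = {"iteration": iteration, "labeled_pool": len(X_lab),
               "pseudo_labels": n_pseudo, "remaining_unlabeled": len(X_unl) - cursor,
               "skipped": n_skipped, "pseudo_label_noise": noise}
        if val is not None:
            row.update(_val_metrics(model, val))
        history.append(**row)
        # pool conservation: nothing is created or lost
        assert len(X_lab) + (len(X_unl) - cursor) + n_skipped == n_total

    return model, q, history
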