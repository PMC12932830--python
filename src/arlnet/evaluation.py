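"""Statistical evaluation suite.

Threshold metrics from the confusion counts, ROC/PR AUC and Brier score,
stratified-bootstrap AUC confidence intervals, the fast DeLong test for
paired ROC curves, paired t / Wilcoxon model comparisons, decision-curve
analysis (net benefit against treat-all / treat-none), the three feature
selectors (correlation-based forward search, forest importances,
recursive feature elimination) and a classical-classifier bench
(gradient-boosted trees, random forest, decision tree, Gaussian naive
Bayes standing in for the unspecified "Bayesian network").
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion counts and threshold metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(labels: np.ndarray, predictions: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    """Counts of the four cells; probability inputs are cut at
    ``threshold``."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions, dtype=float)
    if len(y) != len(p):
        raise ValueError("labels and predictions differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    yhat = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s is 0/0; returning 0", name)
        return 0.0
    return num / den


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """accuracy, precision, recall, F1, specificity from the counts;
    0/0 cells resolve to 0 with a warning."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    recall = _safe_ratio(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": _safe_ratio(c.tn, c.tn + c.fp, "specificity"),
    }


# ---------------------------------------------------------------------------
# probabilistic metrics
# ---------------------------------------------------------------------------

def roc_pr_brier(labels: np.ndarray, probabilities: np.ndarray
                 ) -> tuple[float, float, float]:
    """(ROC-AUC, PR-AUC, Brier).  ROC-AUC uses the rank (Mann-Whitney)
    formulation with tie correction; PR-AUC is step-interpolated average
    precision; Brier = mean (p - y)^2.  Single-class labels make the
    AUCs undefined (Brier is still computed by the caller if needed)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    brier = float(np.mean((p - y) ** 2))
    if len(np.unique(y)) < 2:
        raise ValueError(f"AUC undefined for single-class labels (brier={brier})")
    return (float(roc_auc_score(y, p)),
            float(average_precision_score(y, p)),
            brier)


def bootstrap_auc_ci(labels: np.ndarray, probabilities: np.ndarray,
                     B: int = 1000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile interval of ROC-AUC over B class-stratified resamples."""
    if B < 10:
        raise ValueError("B must be >= 10")
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        aucs[b] = roc_auc_score(y[idx], p[idx])
    alpha = (1 - level) / 2
    return (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha)))


# ---------------------------------------------------------------------------
# DeLong test (fast midrank algorithm)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return _stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, scores: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the positive/negative structural components V10, V01."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def delong_test(labels: np.ndarray, scores_a: np.ndarray,
                scores_b: np.ndarray) -> tuple[float, float, float]:
    """Paired comparison of two correlated ROC-AUCs.

    Returns (AUC_A - AUC_B, z statistic, two-sided p).  Identical score
    vectors give difference 0 and p = 1.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("labels and both score vectors must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_components(y, a)
    auc_b, v10_b, v01_b = _delong_components(y, b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    s = s10 / m + s01 / n
    var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 0.0, 1.0
        raise ValueError("degenerate DeLong variance with non-zero AUC difference")
    z = diff / np.sqrt(var)
    p = 2 * _stats.norm.sf(abs(z))
    return float(diff), float(z), float(p)


def paired_model_tests(series_a: np.ndarray, series_b: np.ndarray
                       ) -> tuple[float, float]:
    """Two-sided paired t and Wilcoxon signed-rank p-values over paired
    metric series (per-resample or per-fold).  All-zero differences are
    undefined for both tests and resolve to p = 1 with a warning."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must be paired (equal length)")
    if len(a) < 5:
        raise ValueError("need at least 5 paired values")
    d = a - b
    if np.allclose(d, 0):
        logger.warning("all paired differences are zero; p-values set to 1")
        return 1.0, 1.0
    t_p = float(_stats.ttest_rel(a, b).pvalue)
    if np.isnan(t_p):
        t_p = 1.0
    try:
        w_p = float(_stats.wilcoxon(a, b).pvalue)
    except ValueError:
        logger.warning("Wilcoxon undefined; p set to 1")
        w_p = 1.0
    return t_p, w_p


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

def decision_curve(labels: np.ndarray, probabilities: np.ndarray,
                   thresholds: np.ndarray) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/N - (FP/N) * pt/(1-pt) per threshold,
    with treat-all and treat-none reference strategies.

    Thresholds must lie in (0, 1); pt = 1 is excluded (division by
    zero)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must be strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        w = pt / (1 - pt)
        yhat = p >= pt
        tp = int((yhat & (y == 1)).sum())
        fp = int((yhat & (y == 0)).sum())
        nb_model = tp / n - (fp / n) * w
        nb_all = prevalence - (1 - prevalence) * w
        rows.append({"threshold": pt, "nb_model": nb_model,
                     "nb_all": nb_all, "nb_none": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return abs(float(np.corrcoef(x, y)[0, 1]))


def cfs_merit(X: np.ndarray, y: np.ndarray, subset: list[int]) -> float:
    """Correlation-based-selection merit of a feature subset:
    k * mean|r_cf| / sqrt(k + k(k-1) * mean|r_ff|)."""
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = np.mean([_abs_corr(X[:, j], y) for j in subset])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean([_abs_corr(X[:, i], X[:, j])
                    for a, i in enumerate(subset) for j in subset[a + 1:]])
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def cfs_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy forward search maximizing the CFS merit; stops at k
    features (constant features contribute zero correlation)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    while len(selected) < k and remaining:
        best_j, best_merit = None, -np.inf
        for j in remaining:
            merit = cfs_merit(X, y, selected + [j])
            if merit > best_merit:
                best_j, best_merit = j, merit
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def forest_select(X: np.ndarray, y: np.ndarray, k: int, seed: int = 0,
                  n_estimators: int = 200) -> tuple[list[int], np.ndarray]:
    """Top-k features by mean impurity-decrease importance of a fitted
    random forest; returns (indices ordered by importance, importances)."""
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, y)
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return list(map(int, order[:k])), imp


def rfe_select(X: np.ndarray, y: np.ndarray, k: int, step: int = 1,
               seed: int = 0) -> list[int]:
    """Recursive feature elimination with a logistic base estimator
    (coefficient-magnitude ranking), dropping ``step`` features per
    round until k remain."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    if k == X.shape[1]:
        return list(range(X.shape[1]))
    base = LogisticRegression(max_iter=2000, random_state=seed)
    rfe = RFE(base, n_features_to_select=k, step=step)
    rfe.fit(X, y)
    return list(map(int, np.flatnonzero(rfe.support_)))


# ---------------------------------------------------------------------------
# classical-classifier bench
# ---------------------------------------------------------------------------

def _make_classifier(name: str, seed: int):
    if name == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, max_depth=4, random_state=seed,
                             eval_metric="logloss", verbosity=0)
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


SELECTOR_NAMES = ("all", "cfs", "ff", "rfe")
CLASSIFIER_NAMES = ("xgb", "rf", "dt", "nb")


def run_classifier_bench(X_train: np.ndarray, y_train: np.ndarray,
                         X_test: np.ndarray, y_test: np.ndarray,
                         selectors: tuple[str, ...] = SELECTOR_NAMES,
                         classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
                         k_features: int = 40, seed: int = 0) -> pd.DataFrame:
    """Fit every (selector, classifier) pair on leak-free splits; one row
    per pair with train/test metrics, AUC and timings."""
    rows = []
    for sel in selectors:
        if sel == "all":
            idx = list(range(X_train.shape[1]))
        elif sel == "cfs":
            idx = cfs_select(X_train, y_train, k_features)
        elif sel == "ff":
            idx, _ = forest_select(X_train, y_train, k_features, seed=seed)
        elif sel == "rfe":
            idx = rfe_select(X_train, y_train, k_features, seed=seed)
        else:
            raise ValueError(f"unknown selector {sel!r}")
        if not idx:
            logger.warning("selector %r returned no features; skipped", sel)
            continue
        Xtr, Xte = X_train[:, idx], X_test[:, idx]
        for name in classifiers:
            clf = _make_classifier(name, seed)
            t0 = time.perf_counter()
            clf.fit(Xtr, y_train)
            fit_t = time.perf_counter() - t0
            t0 = time.perf_counter()
            p_te = clf.predict_proba(Xte)[:, 1]
            pred_t = time.perf_counter() - t0
            p_tr = clf.predict_proba(Xtr)[:, 1]
            m_te = threshold_metrics(confusion_matrix(y_test, p_te))
            m_tr = threshold_metrics(confusion_matrix(y_train, p_tr))
            try:
                auc, pr_auc, brier = roc_pr_brier(y_test, p_te)
            except ValueError:
                auc = pr_auc = brier = float("nan")
            rows.append({"selector": sel, "classifier": name,
                         "n_features": len(idx),
                         "train_accuracy": m_tr["accuracy"],
                         "test_accuracy": m_te["accuracy"],
                         "test_precision": m_te["precision"],
                         "test_recall": m_te["recall"],
                         "test_f1": m_te["f1"],
                         "test_specificity": m_te["specificity"],
                         "roc_auc": auc, "pr_auc": pr_auc, "brier": brier,
                         "train_time_s": fit_t, "test_time_s": pred_t})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Full evaluation of one probabilistic classifier on one test set."""

    confusion: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    roc_auc: float
    pr_auc: float
    brier: float
    auc_ci: tuple[float, float]
    decision_curve: pd.DataFrame

    def to_dict(self) -> dict:
        d = {"tp": self.confusion.tp, "tn": self.confusion.tn,
             "fp": self.confusion.fp, "fn": self.confusion.fn,
             "accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1,
             "specificity": self.specificity, "roc_auc": self.roc_auc,
             "pr_auc": self.pr_auc, "brier": self.brier,
             "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1]}
        return d


def evaluate_probabilities(labels: np.ndarray, probabilities: np.ndarray,
                           B: int = 1000, seed: int = 0,
                           thresholds: np.ndarray | None = None) -> EvalReport:
    """Assemble the full report for one score vector."""
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    cm = confusion_matrix(labels, probabilities)
    m = threshold_metrics(cm)
    roc, pr, brier = roc_pr_brier(labels, probabilities)
    ci = bootstrap_auc_ci(labels, probabilities, B=B, seed=seed)
    dca = decision_curve(labels, probabilities, thresholds)
    return EvalReport(confusion=cm, roc_auc=roc, pr_auc=pr, brier=brier,
                      auc_ci=ci, decision_curve=dca, **m)
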