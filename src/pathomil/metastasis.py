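"""Metastasis classification on fused slide features, with the full metric panel.

Three standard learners (random forest, XGBoost, LightGBM) are fitted on the
selected slide features; each cohort is scored with accuracy, AUC with a
DeLong 95% CI, and the threshold metrics sensitivity/specificity/PPV/NPV at a
Youden-optimal operating point chosen on the training cohort and frozen for
the test cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "xgboost", "lightgbm")


@dataclass
class ClassifierMetrics:
    model_name: str
    cohort: str
    accuracy: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    degenerate: bool = False  # flags 0/0 ratios reported as 0 or undefined AUC

    def as_dict(self) -> dict:
        return asdict(self)


def split_cohort(n: int, train_fraction: float = 0.7, seed: int = 0,
                 stratify: np.ndarray | None = None) -> np.ndarray:
    """Reproducible train/test assignment: array of 'train'/'test' of length n.

    Train size is floor(train_fraction * n) overall (e.g. 204 at 0.7 gives
    142/62).  With ``stratify`` the same floor rule applies within each level
    and leftover units fill the global train quota in shuffled order.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * n))
    assign = np.array(["test"] * n, dtype=object)
    if stratify is None:
        order = rng.permutation(n)
        assign[order[:n_train]] = "train"
        return assign
    stratify = np.asarray(stratify)
    chosen: list[int] = []
    leftovers: list[int] = []
    for level in np.unique(stratify):
        idx = rng.permutation(np.flatnonzero(stratify == level))
        k = int(np.floor(train_fraction * len(idx)))
        chosen.extend(idx[:k])
        leftovers.extend(idx[k:])
    leftovers = list(rng.permutation(np.asarray(leftovers, dtype=int)))
    while len(chosen) < n_train and leftovers:
        chosen.append(leftovers.pop(0))
    assign[np.asarray(chosen[:n_train], dtype=int)] = "train"
    return assign


def _make_model(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, eval_metric="logloss",
        )
    if name == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True,
        )
    raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


def train_classifiers(X_train: pd.DataFrame | np.ndarray, y_train: np.ndarray,
                      algos: tuple[str, ...] = ALGORITHMS, seed: int = 0) -> dict:
    """Fit one model per requested algorithm; rejects single-class labels."""
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    X_train = np.asarray(X_train, dtype=float)
    models = {}
    for name in algos:
        model = _make_model(name, seed)
        model.fit(X_train, y_train)
        models[name] = model
        logger.info("fitted %s (seed=%d) on %d samples", name, seed, len(y_train))
    return models


# ---------------------------------------------------------------- DeLong CI

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_ci(y: np.ndarray, scores: np.ndarray, alpha: float = 0.05
              ) -> tuple[float, float, float]:
    """AUC and its DeLong 95% CI (clipped to [0, 1]) for binary labels."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("DeLong CI needs both classes present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n           # structural components, positives
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m     # structural components, negatives
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    half = norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Score cutoff maximizing sensitivity + specificity - 1 on (y, scores)."""
    fpr, tpr, thresholds = roc_curve(y, scores)
    return float(thresholds[np.argmax(tpr - fpr)])


def contingency_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy/sens/spec/PPV/NPV from a 2x2 table; 0/0 ratios report 0, flagged."""
    def ratio(num: int, den: int) -> tuple[float, bool]:
        return (num / den, False) if den > 0 else (0.0, True)

    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty contingency table")
    sens, f1 = ratio(tp, tp + fn)
    spec, f2 = ratio(tn, tn + fp)
    ppv, f3 = ratio(tp, tp + fp)
    npv, f4 = ratio(tn, tn + fn)
    return {
        "accuracy": (tp + tn) / total, "sensitivity": sens, "specificity": spec,
        "ppv": ppv, "npv": npv, "degenerate": f1 or f2 or f3 or f4,
    }


def evaluate_classifier(model, X, y: np.ndarray, threshold: float,
                        model_name: str = "", cohort: str = "") -> ClassifierMetrics:
    """Score one cohort: rank AUC + DeLong CI, threshold metrics at ``threshold``.

    ``threshold`` is the frozen operating point (chosen on the training cohort
    with :func:`youden_threshold`).  A single-class cohort gets AUC reported as
    NaN with the degenerate flag set.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty evaluation cohort")
    y = np.asarray(y, dtype=int)
    scores = model.predict_proba(X)[:, 1] if hasattr(model, "predict_proba") \
        else np.asarray(model, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    cm = contingency_metrics(tp, fp, fn, tn)
    if len(np.unique(y)) < 2:
        auc, lo, hi = float("nan"), float("nan"), float("nan")
        cm["degenerate"] = True
    else:
        auc, lo, hi = delong_ci(y, scores)
    return ClassifierMetrics(
        model_name=model_name, cohort=cohort, accuracy=cm["accuracy"], auc=auc,
        auc_ci_low=lo, auc_ci_high=hi, sensitivity=cm["sensitivity"],
        specificity=cm["specificity"], ppv=cm["ppv"], npv=cm["npv"],
        threshold=threshold, degenerate=cm["degenerate"],
    )


def metastasis_metric_table(models: dict, X_train, y_train, X_test, y_test
                            ) -> pd.DataFrame:
    """Train+test metric rows for every fitted model (threshold frozen on train)."""
    rows = []
    for name, model in models.items():
        thr = youden_threshold(np.asarray(y_train, int),
                               model.predict_proba(np.asarray(X_train, float))[:, 1])
        rows.append(evaluate_classifier(model, X_train, y_train, thr, name, "train").as_dict())
        rows.append(evaluate_classifier(model, X_test, y_test, thr, name, "test").as_dict())
    return pd.DataFrame(rows)


def plot_roc(models: dict, X, y, path, title: str = "ROC") -> None:
    """One ROC panel for every model on a single cohort; saved as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    X = np.asarray(X, float)
    for name, model in models.items():
        scores = model.predict_proba(X)[:, 1]
        fpr, tpr, _ = roc_curve(y, scores)
        ax.plot(fpr, tpr, label=f"{name} (AUC={roc_auc_score(y, scores):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
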