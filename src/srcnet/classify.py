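"""SFS-wrapped linear discriminant classification under repeated stratified CV.

Two evaluation modes are provided for the sequential-forward-selection (SFS)
wrapper:

``paper``
    SFS runs once on the full data set, then the selected feature set is
    scored by 10x10-fold cross-validation. This select-then-validate protocol
    is common in applied decoding studies but is optimistically biased: the
    test folds were visible to the selector.
``nested``
    SFS is re-run inside every training fold and the held-out fold never
    touches the selector. This is the statistically sound estimate.

The LDA is the classical two-class discriminant from class means and pooled
within-class covariance, with a small ridge (1e-6 of the mean eigenvalue) for
stability under collinear features, and empirical class priors. It is
implemented directly in numpy because the SFS wrapper performs tens of
thousands of tiny fits per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

RIDGE = 1e-6


def _fit_lda(x: np.ndarray, y01: np.ndarray):
    """Fit weights/bias of a two-class LDA. y01 must contain both classes."""
    x0, x1 = x[y01 == 0], x[y01 == 1]
    n0, n1 = len(x0), len(x1)
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present in the training data")
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    d = x.shape[1]
    scatter = (x0 - m0).T @ (x0 - m0) + (x1 - m1).T @ (x1 - m1)
    cov = scatter / max(n0 + n1 - 2, 1)
    ridge = RIDGE * np.trace(cov) / d + 1e-12
    cov = cov + ridge * np.eye(d)
    w = np.linalg.solve(cov, m1 - m0)
    b = -0.5 * (m0 + m1) @ w + np.log(n1 / n0)
    return w, b


class LinearDiscriminant:
    """Two-class LDA: class means + pooled ridge-stabilized covariance.

    The decision function is positive for the class encoded 1 (``classes_[1]``).
    """

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LinearDiscriminant":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if x.ndim != 2 or x.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {len(self.classes_)}")
        y01 = (y == self.classes_[1]).astype(int)
        self.coef_, self.intercept_ = _fit_lda(x, y01)
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(x) > 0, self.classes_[1], self.classes_[0])


def lda_train(x: np.ndarray, y: np.ndarray) -> LinearDiscriminant:
    """Convenience constructor: fit a :class:`LinearDiscriminant`."""
    return LinearDiscriminant().fit(x, y)


def _fold_metrics(y_true01: np.ndarray, y_pred01: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) on one fold; positive class is 1."""
    acc = float((y_true01 == y_pred01).mean())
    pos, neg = y_true01 == 1, y_true01 == 0
    sens = float((y_pred01[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred01[neg] == 0).mean()) if neg.any() else np.nan
    return acc, sens, spec


def _resolve_folds(y01: np.ndarray, n_folds: int) -> int:
    smallest = int(np.bincount(y01, minlength=2).min())
    if smallest < 2:
        raise ValueError("each class needs at least 2 members for CV")
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds from "
            f"{n_folds} to {smallest}", stacklevel=3,
        )
        return smallest
    return n_folds


def _encode(y: np.ndarray, positive_label) -> tuple[np.ndarray, object]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if positive_label is None:
        positive_label = classes[1]
    elif positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {classes}")
    return (y == positive_label).astype(int), positive_label


def sfs_select(
    x: np.ndarray,
    y: np.ndarray,
    max_k: int = 30,
    seed: int | np.random.SeedSequence = 0,
    inner_cv: int = 10,
    positive_label=None,
) -> tuple[list[int], list[tuple[int, float]]]:
    """Greedy sequential forward selection with a CV-accuracy cost.

    At each step, the feature whose addition maximizes the mean stratified
    ``inner_cv``-fold LDA accuracy joins the set; ties break toward the lowest
    feature index. The search stops when no candidate improves the cost or at
    ``max_k`` features. Returns (selected indices giving the best cost, trace
    of (feature index, cost in %) for every step taken).
    """
    x = np.asarray(x, dtype=float)
    y01, _ = _encode(y, positive_label)
    n, d = x.shape
    if d < 1:
        raise ValueError("need at least one feature")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rs = int(ss.generate_state(1)[0] % (2**31 - 1))
    n_folds = _resolve_folds(y01, inner_cv)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    folds = list(skf.split(x, y01))

    def cost(cols: list[int]) -> float:
        accs = []
        xs = x[:, cols]
        for tr, te in folds:
            w, b = _fit_lda(xs[tr], y01[tr])
            pred = (xs[te] @ w + b > 0).astype(int)
            accs.append(float((pred == y01[te]).mean()))
        return float(np.mean(accs))

    selected: list[int] = []
    trace: list[tuple[int, float]] = []
    best_cost = -np.inf
    remaining = list(range(d))
    while remaining and len(selected) < max_k:
        step_costs = np.array([cost(selected + [f]) for f in remaining])
        best_i = int(np.argmax(step_costs))  # argmax takes the first max: lowest index
        if step_costs[best_i] <= best_cost:
            break
        best_cost = float(step_costs[best_i])
        selected.append(remaining.pop(best_i))
        trace.append((selected[-1], best_cost * 100.0))
    best_k = int(np.argmax([c for _, c in trace])) + 1 if trace else 0
    return selected[:best_k], trace


@dataclass
class CvReport:
    """Cross-validated performance of one binary classification pair."""

    accuracy: float          # percent, mean over all held-out folds
    sensitivity: float       # percent, recall of the positive class
    specificity: float       # percent
    n_features_selected: int
    selected_features: list[int]
    selected_feature_trace: list[tuple[int, float]]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    mode: str
    seed: int
    n_folds: int
    n_repeats: int
    positive_label: object = None
    fold_selections: list[list[int]] | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_features_selected": self.n_features_selected,
            "selected_features": [int(i) for i in self.selected_features],
            "selected_feature_trace": [[int(i), float(c)] for i, c in self.selected_feature_trace],
            "roc": {
                "fpr": [float(v) for v in self.roc_fpr],
                "tpr": [float(v) for v in self.roc_tpr],
                "auc": float(self.auc),
            },
            "mode": self.mode,
            "seed": int(self.seed),
            "n_folds": int(self.n_folds),
            "n_repeats": int(self.n_repeats),
            "positive_label": None if self.positive_label is None else str(self.positive_label),
        }


def roc_mean(
    fold_scores: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertically average per-fold ROC curves on a fixed false-positive grid.

    ``fold_scores`` holds (y_true01, decision_score) pairs, one per fold.
    Each fold's empirical ROC is a staircase; it is evaluated on the grid by
    step (previous-value) interpolation, taking the highest TPR attained at a
    given FPR, then averaged vertically. Returns (fpr grid, mean tpr, AUC of
    the mean curve).
    """
    if not fold_scores:
        raise ValueError("need at least one fold")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for y_true, score in fold_scores:
        y_true = np.asarray(y_true)
        if not (y_true == 1).any() or not (y_true == 0).any():
            raise ValueError("every fold needs both classes for a ROC curve")
        fpr, tpr, _ = roc_curve(y_true, score)
        # collapse duplicate FPR values to the max TPR reached there
        last_at = np.r_[fpr[1:] != fpr[:-1], True]
        fpr, tpr = fpr[last_at], tpr[last_at]
        idx = np.searchsorted(fpr, grid, side="right") - 1
        tprs.append(tpr[np.clip(idx, 0, len(tpr) - 1)])
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return grid, mean_tpr, auc


def cv_10x10(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
    n_repeats: int = 10,
    positive_label=None,
    selector=None,
):
    """Repeated stratified k-fold CV of the LDA; metrics averaged over all folds.

    ``selector(x_train, y_train, fold_seed) -> column indices`` (optional) is
    applied inside every training fold (nested selection). Returns a dict with
    mean metrics (percent), per-fold scores for ROC averaging, and the per-fold
    selections.
    """
    x = np.asarray(x, dtype=float)
    y01, pos = _encode(y, positive_label)
    if len(y01) != len(x):
        raise ValueError("label/feature row mismatch")
    n_folds = _resolve_folds(y01, n_folds)
    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(n_repeats)
    accs, senss, specs = [], [], []
    fold_scores = []
    fold_selections = []
    for rep_ss in repeat_seeds:
        rs = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for tr, te in skf.split(x, y01):
            cols = list(range(x.shape[1]))
            if selector is not None:
                cols = list(selector(x[tr], y01[tr], rep_ss))
            w, b = _fit_lda(x[tr][:, cols], y01[tr])
            score = x[te][:, cols] @ w + b
            pred = (score > 0).astype(int)
            a, s, p = _fold_metrics(y01[te], pred)
            accs.append(a)
            if not np.isnan(s):
                senss.append(s)
            if not np.isnan(p):
                specs.append(p)
            fold_scores.append((y01[te], score))
            fold_selections.append(cols)
    return {
        "accuracy": 100.0 * float(np.mean(accs)),
        "sensitivity": 100.0 * float(np.mean(senss)),
        "specificity": 100.0 * float(np.mean(specs)),
        "fold_scores": fold_scores,
        "fold_selections": fold_selections,
        "n_folds": n_folds,
        "n_repeats": n_repeats,
        "positive_label": pos,
    }


def run_pair(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "paper",
    seed: int = 0,
    max_k: int = 30,
    inner_cv: int = 10,
    n_folds: int = 10,
    n_repeats: int = 10,
    positive_label=None,
) -> CvReport:
    """Evaluate one binary classification pair with SFS + LDA under 10x10 CV.

    See the module docstring for the ``paper`` vs ``nested`` modes.
    """
    if mode not in ("paper", "nested"):
        raise ValueError("mode must be 'paper' or 'nested'")
    x = np.asarray(x, dtype=float)
    root = np.random.SeedSequence(seed)
    sfs_ss, cv_ss = root.spawn(2)
    cv_seed = int(cv_ss.generate_state(1)[0] % (2**31 - 1))

    if mode == "paper":
        selected, trace = sfs_select(
            x, y, max_k=max_k, seed=sfs_ss, inner_cv=inner_cv,
            positive_label=positive_label,
        )
        res = cv_10x10(x[:, selected], y, seed=cv_seed, n_folds=n_folds,
                       n_repeats=n_repeats, positive_label=positive_label)
        fold_selections = None
        n_sel = len(selected)
    else:
        def selector(x_tr, y_tr, fold_ss):
            sel, _ = sfs_select(x_tr, y_tr, max_k=max_k, seed=fold_ss.spawn(1)[0],
                                inner_cv=inner_cv)
            return sel

        res = cv_10x10(x, y, seed=cv_seed, n_folds=n_folds, n_repeats=n_repeats,
                       positive_label=positive_label, selector=selector)
        fold_selections = res["fold_selections"]
        counts = np.bincount(np.concatenate(fold_selections), minlength=x.shape[1])
        n_sel = int(round(np.mean([len(s) for s in fold_selections])))
        selected = [int(i) for i in np.argsort(-counts)[:n_sel]]
        trace = []

    fpr, tpr, auc = roc_mean(res["fold_scores"])
    return CvReport(
        accuracy=res["accuracy"],
        sensitivity=res["sensitivity"],
        specificity=res["specificity"],
        n_features_selected=n_sel,
        selected_features=list(selected),
        selected_feature_trace=trace,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        mode=mode,
        seed=seed,
        n_folds=res["n_folds"],
        n_repeats=res["n_repeats"],
        positive_label=res["positive_label"],
        fold_selections=fold_selections,
    )
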