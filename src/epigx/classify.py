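"""Disease-status classification: logistic baselines and the balanced
random forest (BRF) pipeline.

The BRF trains each tree on a balanced bootstrap: an equal number of
subjects drawn with replacement from each class, the majority class
under-sampled to the minority count.  Evaluation uses repeated stratified
k-fold cross-validation (default 10 splits x 3 repeats); the more severe
dysglycemic class is the positive target.  Feature selection follows the
forest's own impurity-based (Gini) importances: first an implicit screen
retaining features above the mean importance, then pruning to the top-k
ranked features.

AUC uses the rank (Mann-Whitney) formulation with tie correction;
sensitivity, specificity and precision are computed at a fixed decision
threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

__all__ = ["CVConfig", "Metrics", "ClassifierReport", "BalancedRandomForest",
           "compute_metrics", "logistic_classify", "balanced_rf_cv",
           "implicit_feature_select", "gini_prune", "roc_plot"]


@dataclass
class CVConfig:
    n_splits: int = 10
    n_repeats: int = 3
    holdout_fraction: float = 0.30
    seed: int = 0
    top_k: int = 13
    decision_threshold: float = 0.5
    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    max_depth: int | None = None
    aggregate: str = "mean_folds"  # or "pooled"

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class Metrics:
    auc: float
    sensitivity: float
    specificity: float
    precision: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]


@dataclass
class ClassifierReport:
    model_tag: str
    per_fold: pd.DataFrame
    aggregate: Metrics
    pooled_confusion: np.ndarray
    features: list[str]
    importances: pd.Series | None = None


class BalancedRandomForest:
    """Random forest with per-tree balanced under-sampled bootstraps.

    Each tree draws, with replacement, ``n_minority`` subjects from each
    class, so every tree sees exactly equal class counts (recorded in
    ``tree_class_counts_`` as an instrumentation hook).  Probabilities are
    the mean of the per-tree class probabilities; Gini importances are the
    mean of per-tree impurity-based importances.
    """

    def __init__(self, n_estimators=500, max_features="sqrt",
                 min_samples_leaf=1, max_depth=None, random_state=0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("BalancedRandomForest requires binary labels")
        idx_by_class = [np.flatnonzero(y == c) for c in self.classes_]
        n_draw = min(len(ix) for ix in idx_by_class)
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.tree_class_counts_ = []
        for _ in range(self.n_estimators):
            boot = np.concatenate([
                rng.choice(ix, size=n_draw, replace=True) for ix in idx_by_class
            ])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            counts = {int(c): int((y[boot] == c).sum()) for c in self.classes_}
            self.tree_class_counts_.append(counts)
        imps = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        self.feature_importances_ = imps
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), 2))
        for tree in self.trees_:
            proba = tree.predict_proba(X)
            # map tree's class order onto self.classes_
            cols = {c: k for k, c in enumerate(tree.classes_)}
            for k, c in enumerate(self.classes_):
                if c in cols:
                    out[:, k] += proba[:, cols[c]]
        return out / len(self.trees_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def compute_metrics(scores, labels, threshold: float = 0.5) -> Metrics:
    """Rank-formulation AUC (tie-corrected) and thresholded rates.

    Positive class = label 1.  Confusion layout [[TN, FP], [FN, TP]].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for a one-class label vector")
    ranks = rankdata(scores)  # midranks handle ties
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    return Metrics(float(auc), sens, spec, prec,
                   np.array([[tn, fp], [fn, tp]]))


def logistic_classify(features: pd.DataFrame, labels, config: CVConfig,
                      model_tag: str = "logistic") -> ClassifierReport:
    """Logistic baseline on a stratified 70/30 train/test split."""
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.holdout_fraction, stratify=y,
        random_state=config.seed,
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")
    model = LogisticRegression(max_iter=2000)
    model.fit(X_tr, y_tr)
    scores = model.predict_proba(X_te)[:, 1]
    m = compute_metrics(scores, y_te, config.decision_threshold)
    per_fold = pd.DataFrame([{
        "fold": 0, "auc": m.auc, "sensitivity": m.sensitivity,
        "specificity": m.specificity, "precision": m.precision,
        "n_test": len(y_te),
    }])
    return ClassifierReport(model_tag, per_fold, m, m.confusion,
                            list(features.columns))


def balanced_rf_cv(features: pd.DataFrame, labels, config: CVConfig,
                   model_tag: str = "brf") -> ClassifierReport:
    """Repeated stratified k-fold evaluation of the balanced random forest."""
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    counts = np.bincount(y)
    if counts.min() < config.n_splits:
        raise ValueError(
            f"smallest class ({counts.min()}) < n_splits ({config.n_splits}); "
            "reduce n_splits"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=config.n_splits, n_repeats=config.n_repeats,
        random_state=config.seed,
    )
    fold_rows, importances, pooled = [], [], np.zeros((2, 2), dtype=int)
    pooled_scores, pooled_labels = [], []
    for k, (tr, te) in enumerate(cv.split(X, y)):
        brf = BalancedRandomForest(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf,
            max_depth=config.max_depth,
            random_state=config.seed * 100_003 + k,
        ).fit(X[tr], y[tr])
        scores = brf.predict_proba(X[te])[:, 1]
        m = compute_metrics(scores, y[te], config.decision_threshold)
        fold_rows.append({
            "fold": k, "auc": m.auc, "sensitivity": m.sensitivity,
            "specificity": m.specificity, "precision": m.precision,
            "n_test": len(te),
        })
        pooled += m.confusion
        pooled_scores.append(scores)
        pooled_labels.append(y[te])
        importances.append(brf.feature_importances_)
    per_fold = pd.DataFrame(fold_rows)
    if config.aggregate == "pooled":
        agg = compute_metrics(np.concatenate(pooled_scores),
                              np.concatenate(pooled_labels),
                              config.decision_threshold)
        agg.confusion = pooled
    else:
        means = per_fold[["auc", "sensitivity", "specificity", "precision"]] \
            .mean(skipna=True)
        agg = Metrics(means["auc"], means["sensitivity"], means["specificity"],
                      means["precision"], pooled)
    imp = pd.Series(np.mean(importances, axis=0), index=features.columns)
    return ClassifierReport(model_tag, per_fold, agg, pooled,
                            list(features.columns), importances=imp)


def implicit_feature_select(features: pd.DataFrame, labels, config: CVConfig,
                            always_keep=()) -> list[str]:
    """Screen features by forest importance above the mean importance.

    One balanced forest is fitted on all the data; features whose mean
    decrease in impurity exceeds the mean across features survive.
    ``always_keep`` columns (covariates, the target CpG) are always retained.
    """
    y = np.asarray(labels, dtype=int)
    brf = BalancedRandomForest(
        n_estimators=config.n_estimators, max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf, max_depth=config.max_depth,
        random_state=config.seed,
    ).fit(features.to_numpy(dtype=float), y)
    imp = pd.Series(brf.feature_importances_, index=features.columns)
    selected = set(imp.index[imp > imp.mean()]) | set(always_keep)
    return [c for c in features.columns if c in selected]


def gini_prune(features: pd.DataFrame, labels, config: CVConfig,
               always_keep=()) -> tuple[pd.DataFrame, ClassifierReport]:
    """Rank by CV-averaged Gini importance, keep top-k, refit.

    Importances are averaged over the cross-validation folds; ties break
    lexicographically by feature id.  Returns the ranking table and the
    report of the refitted pruned model.
    """
    report = balanced_rf_cv(features, labels, config, model_tag="brf_full")
    imp = report.importances.sort_index()  # lexicographic tie-break base
    ranking = imp.sort_values(ascending=False, kind="mergesort")
    k = config.top_k
    if k > len(ranking):
        import warnings
        warnings.warn(
            f"top_k={k} exceeds {len(ranking)} features; keeping all",
            stacklevel=2,
        )
        k = len(ranking)
    keep = list(ranking.index[:k])
    keep_set = set(keep) | set(always_keep)
    keep = [c for c in features.columns if c in keep_set]
    pruned = balanced_rf_cv(features[keep], labels, config,
                            model_tag="brf_pruned")
    table = pd.DataFrame({
        "rank": np.arange(1, len(ranking) + 1),
        "feature": ranking.index,
        "gini_importance": ranking.to_numpy(),
        "retained": [f in keep_set for f in ranking.index],
    })
    return table, pruned


def roc_plot(scores, labels, path):
    """Basic ROC curve plus the pooled confusion matrix as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    m = compute_metrics(scores, labels)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].plot(fpr, tpr)
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.7)
    axes[0].set_xlabel("false positive rate")
    axes[0].set_ylabel("true positive rate")
    axes[0].set_title(f"AUC = {m.auc:.2f}")
    axes[1].imshow(m.confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(m.confusion):
        axes[1].text(j, i, str(v), ha="center", va="center")
    axes[1].set_xticks([0, 1], ["pred 0", "pred 1"])
    axes[1].set_yticks([0, 1], ["true 0", "true 1"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
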