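"""Classifier benchmarking: repeated stratified 5-fold CV and binary metrics.

Metrics follow the confusion-table definitions

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)          SPE = TN / (TN + FP)      (standard)

plus an ``as_printed`` convention (SEN = TP/(TP+FP), SPE = TP/(TP+FN)) so
both readings of the sensitivity/specificity formulas are reproducible;
the two agree whenever FP = FN.  AUC is the pairwise concordance

    AUC = #{(pos, neg): score_pos > score_neg} + 0.5 * #ties
          -------------------------------------------------
                     positiveNum * negativeNum

over all positive/negative sample pairs, equivalent to the area under
the ROC curve.

Cross-validation is stratified 5-fold by default, repeated with
re-shuffled folds; when a selector specification is supplied, feature
selection is re-fit on each training fold so no information leaks from
the held-out fold into the selection step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .matrix import LabeledMatrix
from .selection import (
    SelectionResult,
    nmf_relieff_select,
    pca_relieff_select,
    relieff_select,
    svm_rfe_select,
)

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvalReport",
    "SelectorSpec",
    "compute_metrics",
    "pairwise_auc",
    "cross_validate",
    "feature_correlation",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("svm", "rf", "knn")
METRIC_NAMES = ("ACC", "SEN", "SPE", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class FoldResult:
    confusion: ConfusionCounts
    ACC: float
    SEN: float
    SPE: float
    AUC: float
    repeat: int = 0
    fold: int = 0

    def metrics(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class EvalReport:
    """Per-fold and aggregate ACC/SEN/SPE/AUC over folds x repeats."""

    per_fold: list[FoldResult]
    classifier: str
    n_folds: int
    n_repeats: int
    seed: int
    metric_convention: str = "standard"
    selector: Optional[dict] = None

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.per_fold]))

    def se(self, metric: str) -> float:
        vals = np.array([getattr(f, metric) for f in self.per_fold])
        if len(vals) < 2:
            return 0.0
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for m in METRIC_NAMES:
            out[m] = self.mean(m)
            out[f"se_{m}"] = self.se(m)
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "metric_convention": self.metric_convention,
            "selector": self.selector,
            "summary": self.summary(),
            "per_fold": [
                {
                    "repeat": f.repeat,
                    "fold": f.fold,
                    "TP": f.confusion.TP,
                    "TN": f.confusion.TN,
                    "FP": f.confusion.FP,
                    "FN": f.confusion.FN,
                    **f.metrics(),
                }
                for f in self.per_fold
            ],
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_row(self, method: str = "") -> str:
        s = self.summary()
        cells = [method, self.classifier] + [f"{s[m]:.4f}" for m in METRIC_NAMES]
        cells += [f"{s['se_' + m]:.4f}" for m in METRIC_NAMES]
        return "\t".join(cells)


# ---------------------------------------------------------------------------
# metrics


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance AUC over all positive/negative pairs; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    convention: str = "standard",
) -> FoldResult:
    """Confusion counts and ACC/SEN/SPE/AUC from per-sample scores.

    Samples with ``score >= threshold`` are predicted positive; labels are
    binary 0/1 with 1 the positive class.
    """
    if convention not in ("standard", "as_printed"):
        raise ValueError(f"unknown metric convention {convention!r}")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    TP = int(np.sum((pred == 1) & (labels == 1)))
    TN = int(np.sum((pred == 0) & (labels == 0)))
    FP = int(np.sum((pred == 1) & (labels == 0)))
    FN = int(np.sum((pred == 0) & (labels == 1)))
    acc = _safe_div(TP + TN, TP + TN + FP + FN)
    if convention == "standard":
        sen = _safe_div(TP, TP + FN)
        spe = _safe_div(TN, TN + FP)
    else:  # formulas exactly as printed: precision / recall of the positive class
        sen = _safe_div(TP, TP + FP)
        spe = _safe_div(TP, TP + FN)
    auc = pairwise_auc(scores, labels)
    return FoldResult(ConfusionCounts(TP, TN, FP, FN), acc, sen, spe, auc)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class SelectorSpec:
    """Recipe for re-fitting a selector inside each training fold."""

    method: str  # nmf_relieff | relieff | pca_relieff | svm_rfe
    n_select: int
    rank: Optional[int] = None
    k: int = 10
    mode: str = "gene"
    step: int = 1
    use_mrmr: bool = False

    def fit(self, train: LabeledMatrix, seed: int) -> SelectionResult:
        if self.method == "nmf_relieff":
            return nmf_relieff_select(
                train, rank=self.rank, k=self.k, n_select=self.n_select,
                mode=self.mode, seed=seed,
            )
        if self.method == "relieff":
            return relieff_select(train, k=self.k, n_select=self.n_select, seed=seed)
        if self.method == "pca_relieff":
            return pca_relieff_select(
                train, n_components=self.rank, k=self.k, n_select=self.n_select, seed=seed
            )
        if self.method == "svm_rfe":
            return svm_rfe_select(
                train, n_select=self.n_select, step=self.step,
                use_mrmr=self.use_mrmr, seed=seed,
            )
        raise ValueError(f"unknown selector method {self.method!r}")

    def transform(self, train: LabeledMatrix, test: LabeledMatrix, seed: int):
        """Fit on the training fold, project both folds into selected space."""
        result = self.fit(train, seed)
        if self.method == "relieff" or (self.method == "nmf_relieff" and self.mode == "gene") or self.method == "svm_rfe":
            return train.values[result.selected].T, test.values[result.selected].T
        if self.method == "nmf_relieff":  # component mode: encode via basis W
            # least-squares nonnegative-free encoding against the training H rows
            # is avoided; instead project onto the selected H-space via W's pseudoinverse
            raise ValueError(
                "component-mode NMF-ReliefF cannot embed unseen samples; "
                "use mode='gene' inside cross-validation"
            )
        # pca_relieff: project test samples onto the selected components
        from sklearn.decomposition import PCA

        pca = PCA(n_components=result.params["n_components"], svd_solver="full")
        tr = pca.fit_transform(train.values.T)
        te = pca.transform(test.values.T)
        comps = pca.components_
        flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        return (tr * flip)[:, result.selected], (te * flip)[:, result.selected]


def _make_classifier(name: str, seed: int, params: dict | None = None):
    params = params or {}
    if name == "svm":
        kw = {"kernel": "linear", "C": 1.0, "random_state": seed, **params}
        return SVC(**kw)
    if name == "rf":
        kw = {"n_estimators": 500, "random_state": seed, **params}
        return RandomForestClassifier(**kw)
    if name == "knn":
        kw = {"n_neighbors": 5, "metric": "euclidean", **params}
        return KNeighborsClassifier(**kw)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def _decision_scores(name: str, clf, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Continuous per-sample scores plus the positive-decision threshold."""
    if name == "svm":
        return clf.decision_function(X), 0.0
    # rf/knn: fraction of trees / neighbors voting for the positive class
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col], 0.5


def cross_validate(
    data: LabeledMatrix,
    selector: SelectorSpec | SelectionResult | None = None,
    classifier: str = "svm",
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    convention: str = "standard",
    classifier_params: dict | None = None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of a (selector, classifier) pair.

    ``selector`` may be a :class:`SelectorSpec` (re-fit inside every
    training fold — the leakage-safe protocol), a pre-computed
    :class:`SelectionResult` (its feature set is fixed across folds, i.e.
    selection happened outside CV), or ``None`` (all features).  Repeats
    re-shuffle the folds with ``seed + repeat``.  Labels are binarized
    with the lexicographically larger class as positive.
    """
    if data.labels is None:
        raise ValueError("cross-validation requires labels")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(data.labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"binary evaluation requires 2 classes, got {len(classes)}")
    small = classes[np.argmin(counts)]
    if counts.min() < n_folds:
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than n_folds={n_folds}"
        )
    y = (data.labels == classes[1]).astype(int)

    fixed_idx = None
    if isinstance(selector, SelectionResult):
        fixed_idx = selector.selected

    folds: list[FoldResult] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for fold_no, (tr, te) in enumerate(skf.split(data.values.T, y)):
            train = data.subset_samples(tr)
            test = data.subset_samples(te)
            train.labels = y[tr]
            test.labels = y[te]
            if isinstance(selector, SelectorSpec):
                Xtr, Xte = selector.transform(train, test, seed + rep)
            elif fixed_idx is not None:
                Xtr, Xte = train.values[fixed_idx].T, test.values[fixed_idx].T
            else:
                Xtr, Xte = train.values.T, test.values.T
            scaler = MinMaxScaler().fit(Xtr)
            Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
            clf = _make_classifier(classifier, seed + rep, classifier_params)
            clf.fit(Xtr_s, y[tr])
            scores, thr = _decision_scores(classifier, clf, Xte_s)
            fr = compute_metrics(scores, y[te], threshold=thr, convention=convention)
            fr.repeat, fr.fold = rep, fold_no
            folds.append(fr)

    sel_info = None
    if isinstance(selector, SelectorSpec):
        sel_info = {"method": selector.method, "n_select": selector.n_select, "refit_per_fold": True}
    elif isinstance(selector, SelectionResult):
        sel_info = {"method": selector.method, "n_select": len(selector.selected), "refit_per_fold": False}
    return EvalReport(folds, classifier, n_folds, n_repeats, seed, convention, sel_info)


# ---------------------------------------------------------------------------
# feature correlation


def feature_correlation(data: LabeledMatrix, selected: SelectionResult | None = None) -> np.ndarray:
    """Pearson correlation between all pairs of (selected) features.

    Zero-variance features get correlation 0 to every other feature (with
    a warning) and 1 on the diagonal.
    """
    if data.n_samples < 2:
        raise ValueError("correlation needs at least 2 samples")
    X = data.values if selected is None else data.values[selected.selected]
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance feature(s); their correlations are recorded as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def correlation_heatmap(corr: np.ndarray, path, feature_ids=None) -> None:
    """Optional rendering of the feature-correlation matrix as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(corr, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if feature_ids is not None and len(feature_ids) <= 60:
        ax.set_xticks(range(len(feature_ids)))
        ax.set_yticks(range(len(feature_ids)))
        ax.set_xticklabels(feature_ids, rotation=90, fontsize=6)
        ax.set_yticklabels(feature_ids, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
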