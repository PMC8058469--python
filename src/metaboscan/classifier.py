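"""Two-class simple-logistic classifier fitted by LogitBoost.

Each boosting iteration fits a weighted least-squares regression on every
single feature (the "simple" base learner), keeps the one minimizing weighted
SSE, and adds half of it to the additive logit F; class probability is
``p = 1 / (1 + exp(-2 F))``.  The iteration count is chosen by stratified
k-fold cross-validation (pooled held-out accuracy, smallest count on ties).

Working responses are clipped to ``[-z_max, z_max]`` and weights floored at
``w_min`` for numerical stability; features are standardized to zero mean and
unit variance on the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .dataio import DataError

logger = logging.getLogger(__name__)

Z_MAX = 3.0
W_MIN = 2e-6
SHRINKAGE = 0.5

POSITIVE = "case"
NEGATIVE = "control"


class ClassifierError(DataError):
    pass


@dataclass
class BaseLearner:
    feature: str
    slope: float
    intercept: float


@dataclass
class SimpleLogisticModel:
    """Additive logit over standardized single features."""

    base_learners: list[BaseLearner]
    feature_means: pd.Series
    feature_scales: pd.Series
    shrinkage: float = SHRINKAGE
    positive: str = POSITIVE
    negative: str = NEGATIVE

    @property
    def n_iterations(self) -> int:
        return len(self.base_learners)

    def features_used(self) -> list[str]:
        seen: dict[str, None] = {}
        for bl in self.base_learners:
            seen.setdefault(bl.feature, None)
        return list(seen)


@dataclass
class CrossValidationResult:
    k: int
    folds: pd.Series                      # fold index per row id
    accuracy_curve: np.ndarray            # pooled CV accuracy at 0..max iters
    selected_iterations: int
    cv_accuracy: float                    # pooled accuracy at selected count
    fold_accuracies: list[float] = field(default_factory=list)
    seed: int | None = None


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    subgroups: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "roc_points": [list(pt) for pt in self.roc_points],
        }
        if self.subgroups:
            out["subgroups"] = {k: v.to_dict()
                                for k, v in self.subgroups.items()}
        return out


def _encode_labels(labels: pd.Series, positive: str = POSITIVE) -> np.ndarray:
    classes = set(labels.unique())
    if positive not in classes or len(classes) < 2:
        raise ClassifierError(
            f"need both classes present; saw {sorted(classes)}")
    if len(classes) > 2:
        raise ClassifierError(f"more than two classes: {sorted(classes)}")
    return (labels == positive).to_numpy(dtype=float)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _best_base_learner(Xs: np.ndarray, z: np.ndarray, w: np.ndarray,
                       feature_names: list[str]):
    """Weighted simple OLS on each column; return (col, slope, intercept).

    The column minimizing weighted SSE wins; exact ties go to the
    lexicographically smallest feature name so the choice is independent of
    column order.
    """
    sw = w.sum()
    zbar = (w @ z) / sw
    xbar = (w[:, None] * Xs).sum(axis=0) / sw
    xc = Xs - xbar
    zc = z - zbar
    cov = (w[:, None] * xc * zc[:, None]).sum(axis=0)
    var = (w[:, None] * xc * xc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    sse = (w * zc * zc).sum() - slope * cov
    best = sse.min()
    candidates = np.flatnonzero(sse <= best + 0.0)
    j = min(candidates, key=lambda c: feature_names[c])
    b = float(slope[j])
    a = float(zbar - b * xbar[j])
    return j, b, a


def fit_logitboost(features: pd.DataFrame, labels: pd.Series,
                   n_iterations: int, positive: str = POSITIVE,
                   z_max: float = Z_MAX, w_min: float = W_MIN,
                   shrinkage: float = SHRINKAGE) -> SimpleLogisticModel:
    """Fit the boosted simple-logistic model for a fixed iteration count."""
    if n_iterations < 0:
        raise ClassifierError("n_iterations must be >= 0")
    labels = labels.reindex(features.index)
    y = _encode_labels(labels, positive)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ClassifierError("need >= 2 subjects per class")
    names = [str(c) for c in features.columns]
    X = features.to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    F = np.zeros(len(y))
    learners: list[BaseLearner] = []
    for _ in range(n_iterations):
        p = expit(2.0 * F)
        w = np.maximum(p * (1.0 - p), w_min)
        z = np.clip((y - p) / np.maximum(p * (1.0 - p), w_min), -z_max, z_max)
        j, b, a = _best_base_learner(Xs, z, w, names)
        learners.append(BaseLearner(names[j], b, a))
        F += shrinkage * (a + b * Xs[:, j])
    neg = sorted(set(labels.unique()) - {positive})[0]
    return SimpleLogisticModel(
        base_learners=learners,
        feature_means=pd.Series(mu, index=names),
        feature_scales=pd.Series(sd, index=names),
        shrinkage=shrinkage,
        positive=positive,
        negative=neg)


def decision_function(model: SimpleLogisticModel,
                      features: pd.DataFrame) -> pd.Series:
    """Additive logit F(x) over the model's base learners."""
    for bl in model.base_learners:
        if bl.feature not in features.columns:
            raise ClassifierError(f"missing feature {bl.feature!r}")
    F = np.zeros(len(features))
    for bl in model.base_learners:
        x = features[bl.feature].to_numpy(dtype=float)
        xs = (x - model.feature_means[bl.feature]) \
            / model.feature_scales[bl.feature]
        F += model.shrinkage * (bl.intercept + bl.slope * xs)
    return pd.Series(F, index=features.index, name="F")


def predict_proba(model: SimpleLogisticModel,
                  features: pd.DataFrame) -> pd.Series:
    """Probability of the positive class, ``1 / (1 + exp(-2F))``."""
    F = decision_function(model, features)
    return pd.Series(expit(2.0 * F.to_numpy()), index=F.index,
                     name="p_positive")


def predict_label(model: SimpleLogisticModel,
                  features: pd.DataFrame) -> pd.Series:
    proba = predict_proba(model, features)
    return pd.Series(np.where(proba >= 0.5, model.positive, model.negative),
                     index=features.index, name="label")


def stratified_folds(labels: pd.Series, k: int, seed: int,
                     groups: pd.Series | None = None) -> pd.Series:
    """Deterministic stratified fold assignment (per-class round robin).

    With ``groups`` (e.g. subject ids for run-level rows), stratification and
    assignment happen at the group level so all rows of a group share a fold.
    """
    if groups is not None:
        groups = groups.reindex(labels.index)
        unit_labels = labels.groupby(groups).first()
        unit_folds = stratified_folds(unit_labels, k, seed)
        return groups.map(unit_folds).rename("fold").astype(int)
    rng = np.random.default_rng(seed)
    fold = pd.Series(index=labels.index, dtype=int, name="fold")
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) < k:
            raise ClassifierError(
                f"k={k} exceeds class {cls!r} size {len(ids)}")
        rng.shuffle(ids)
        for i, rid in enumerate(ids):
            fold[rid] = i % k
    return fold


def select_iterations(features: pd.DataFrame, labels: pd.Series, k: int = 10,
                      max_iterations: int = 100, seed: int = 0,
                      groups: pd.Series | None = None,
                      positive: str = POSITIVE,
                      z_max: float = Z_MAX,
                      w_min: float = W_MIN) -> CrossValidationResult:
    """Choose the LogitBoost iteration count by stratified k-fold CV.

    Held-out accuracy is recorded at every iteration count from 0 to
    ``max_iterations``; the selected count maximizes pooled CV accuracy with
    the smallest count winning ties.
    """
    if max_iterations < 1:
        raise ClassifierError("max_iterations must be >= 1")
    labels = labels.reindex(features.index)
    y_all = _encode_labels(labels, positive)
    folds = stratified_folds(labels, k, seed, groups=groups)
    n = len(labels)
    correct = np.zeros((max_iterations + 1, n), dtype=bool)
    names = [str(c) for c in features.columns]
    X_all = features.to_numpy(dtype=float)
    for f in range(k):
        test = (folds == f).to_numpy()
        train = ~test
        Xs, mu, sd = _standardize(X_all[train])
        Xt = (X_all[test] - mu) / sd
        y = y_all[train]
        F = np.zeros(train.sum())
        Ft = np.zeros(test.sum())
        correct[0, test] = (Ft >= 0) == (y_all[test] == 1)
        for it in range(1, max_iterations + 1):
            p = expit(2.0 * F)
            w = np.maximum(p * (1.0 - p), w_min)
            z = np.clip((y - p) / np.maximum(p * (1.0 - p), w_min),
                        -z_max, z_max)
            j, b, a = _best_base_learner(Xs, z, w, names)
            F += SHRINKAGE * (a + b * Xs[:, j])
            Ft += SHRINKAGE * (a + b * Xt[:, j])
            correct[it, test] = (Ft >= 0) == (y_all[test] == 1)
    curve = correct.mean(axis=1)
    selected = int(np.argmax(curve))  # argmax returns the first (smallest)
    fold_acc = [float(correct[selected, (folds == f).to_numpy()].mean())
                for f in range(k)]
    return CrossValidationResult(
        k=k, folds=folds, accuracy_curve=curve,
        selected_iterations=selected,
        cv_accuracy=float(curve[selected]),
        fold_accuracies=fold_acc, seed=seed)


def _confusion(y_true: np.ndarray, y_pos: np.ndarray):
    tp = int(np.sum(y_pos & (y_true == 1)))
    fp = int(np.sum(y_pos & (y_true == 0)))
    fn = int(np.sum(~y_pos & (y_true == 1)))
    tn = int(np.sum(~y_pos & (y_true == 0)))
    return tp, fp, fn, tn


def roc_curve(y_true: np.ndarray, proba: np.ndarray):
    """ROC points by sweeping thresholds over the distinct probabilities."""
    thresholds = np.unique(proba)[::-1]
    n_pos = (y_true == 1).sum()
    n_neg = (y_true == 0).sum()
    points = [(0.0, 0.0)]
    for thr in thresholds:
        pred = proba >= thr
        tp = np.sum(pred & (y_true == 1))
        fp = np.sum(pred & (y_true == 0))
        points.append((fp / n_neg if n_neg else 0.0,
                       tp / n_pos if n_pos else 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc_score(y_true: np.ndarray, proba: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count one half."""
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("AUC needs both classes present")
    ranks = rankdata(proba)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(model: SimpleLogisticModel, features: pd.DataFrame,
             labels: pd.Series,
             subgroups: pd.Series | None = None) -> EvaluationReport:
    """Confusion counts, accuracy/sensitivity/specificity, ROC and AUC.

    ``subgroups`` (e.g. age strata per subject) adds one nested report per
    stratum.
    """
    labels = labels.reindex(features.index)
    proba = predict_proba(model, features).to_numpy()
    y = (labels == model.positive).to_numpy(dtype=int)
    report = _evaluate_arrays(y, proba)
    if subgroups is not None:
        subgroups = subgroups.reindex(features.index)
        for name in sorted(subgroups.dropna().unique()):
            sel = (subgroups == name).to_numpy()
            if y[sel].min(initial=1) == y[sel].max(initial=0):
                logger.warning("subgroup %s has a single class; skipped", name)
                continue
            report.subgroups[str(name)] = _evaluate_arrays(y[sel], proba[sel])
    return report


def _evaluate_arrays(y: np.ndarray, proba: np.ndarray) -> EvaluationReport:
    tp, fp, fn, tn = _confusion(y, proba >= 0.5)
    total = tp + fp + fn + tn
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=auc_score(y, proba),
        roc_points=roc_curve(y, proba))


def write_model(model: SimpleLogisticModel, path) -> None:
    """Serialize as a plain-text table: feature, slope, intercept, mean, scale."""
    with open(path, "w") as fh:
        fh.write(f"# simple-logistic model; shrinkage={model.shrinkage}; "
                 f"positive={model.positive}; negative={model.negative}\n")
        fh.write("feature\tslope\tintercept\tmean\tscale\n")
        for bl in model.base_learners:
            fh.write(f"{bl.feature}\t{bl.slope:.17g}\t{bl.intercept:.17g}\t"
                     f"{model.feature_means[bl.feature]:.17g}\t"
                     f"{model.feature_scales[bl.feature]:.17g}\n")


def read_model(path) -> SimpleLogisticModel:
    with open(path) as fh:
        header = fh.readline().strip()
    meta = {}
    for part in header.lstrip("# ").split(";"):
        if "=" in part:
            key, val = part.strip().split("=", 1)
            meta[key] = val
    table = pd.read_csv(path, sep="\t", comment="#")
    learners = [BaseLearner(str(r.feature), float(r.slope), float(r.intercept))
                for r in table.itertuples()]
    means, scales = {}, {}
    for r in table.itertuples():
        means[str(r.feature)] = float(r.mean)
        scales[str(r.feature)] = float(r.scale)
    return SimpleLogisticModel(
        base_learners=learners,
        feature_means=pd.Series(means, dtype=float),
        feature_scales=pd.Series(scales, dtype=float),
        shrinkage=float(meta.get("shrinkage", SHRINKAGE)),
        positive=meta.get("positive", POSITIVE),
        negative=meta.get("negative", NEGATIVE))
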