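"""Stratified splitting, stratified K-fold CV, and the SAMME.R stump ensemble.

The integrated cleavage-probability score is the class-1 probability of a
real-boosting (SAMME.R) AdaBoost ensemble of decision stumps trained on the
per-tool score columns.  Defaults mirror the reference protocol: 280
estimators, learning rate 0.1, depth-1 stumps, 80/20 train/test split
stratified within every (cell type x label) cell, 5-fold stratified CV for
reporting.

SAMME.R recurrence (binary case, classes {0,1}):

1. start with uniform instance weights w_i = 1/n;
2. each round, fit the stump minimizing total weighted Gini impurity over all
   (feature, threshold) pairs, thresholds being midpoints of consecutive
   distinct sorted feature values; ties broken by (lower feature index, lower
   threshold);
3. estimate leaf class probabilities from the instance weights, clip to
   [eps, 1-eps] with eps = 1e-15;
4. the stump's additive vote for class k is
   h_k(x) = (K-1) * (log p_k(x) - mean_k' log p_k'(x));
5. update w_i <- w_i * exp(-lr * (K-1)/K * y_i . log p(x_i)) with the true
   class coded +1 and the other -1/(K-1), then renormalize;
6. stop at n_estimators, or early when a round degenerates: no split improves
   impurity, the chosen stump's weighted 0/1 error exceeds 1/2, or both
   leaves are pure (the perfect stump is kept).

The predicted probability is the softmax of the summed votes; class-1
probability is the integrated score used for ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import feature_columns

__all__ = [
    "ModelFormatError",
    "Stump",
    "BoostModel",
    "SplitPlan",
    "stratified_split",
    "stratified_kfold",
    "fit_adaboost_samme_r",
    "predict_integrated",
    "save_model",
    "load_model",
    "train_report",
]

EPS = 1e-15
MODEL_SCHEMA_VERSION = 1


class ModelFormatError(ValueError):
    """A serialized model file is unreadable or from an unknown schema."""


# ---------------------------------------------------------------------------
# Stratified machinery
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Train/test row indices of one stratified split, with provenance."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int
    strata: dict = field(default_factory=dict)


def _strata_of(labels: np.ndarray, groups: np.ndarray | None):
    if groups is None:
        groups = np.zeros(len(labels), dtype=int)
    keys = [(str(g), int(y)) for g, y in zip(groups, labels)]
    strata: dict[tuple[str, int], list[int]] = {}
    for i, k in enumerate(keys):
        strata.setdefault(k, []).append(i)
    return strata


def stratified_split(
    table: pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
    label_col: str = "label",
    group_col: str = "cell_type",
) -> SplitPlan:
    """80/20-style split performed independently within each (group, label) cell.

    Reproducible for a given seed; per-stratum class counts in the train part
    equal round(fraction * n_cell), so class ratios are preserved within one
    sample per stratum.  A cell with a single member goes to the train side
    with a warning (best effort).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    labels = table[label_col].to_numpy()
    groups = table[group_col].to_numpy() if group_col in table.columns else None
    rng = np.random.default_rng(seed)
    train, test = [], []
    detail = {}
    strata = _strata_of(labels, groups)
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < 2:
            warnings.warn(
                f"stratum {key} has a single member; assigned to train",
                stacklevel=2,
            )
            train.extend(idx.tolist())
            detail[str(key)] = {"n": 1, "n_train": 1}
            continue
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[perm[:n_train]].tolist())
        test.extend(idx[perm[n_train:]].tolist())
        detail[str(key)] = {"n": int(len(idx)), "n_train": int(n_train)}
    return SplitPlan(
        train_idx=np.array(sorted(train), dtype=int),
        test_idx=np.array(sorted(test), dtype=int),
        fraction=fraction,
        seed=seed,
        strata=detail,
    )


def stratified_kfold(
    labels: np.ndarray | pd.Series,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Fold id (0..k-1) per row; per-fold class counts differ by at most one.

    Each class's shuffled indices are dealt into the k folds as evenly as
    possible, with the remainder rotated across folds so fold sizes stay
    balanced overall.
    """
    labels = np.asarray(labels)
    counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    minority = min(counts.values())
    if k > minority:
        raise ValueError(
            f"k={k} exceeds the minority class count ({minority}); "
            "every fold needs at least one member of each class"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    offset = 0
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        assign = (np.arange(len(idx)) + offset) % k
        folds[idx] = assign
        offset += len(idx) % k
    return folds


# ---------------------------------------------------------------------------
# SAMME.R AdaBoost over decision stumps
# ---------------------------------------------------------------------------


@dataclass
class Stump:
    """Depth-1 tree: x[feature] <= threshold goes left.

    ``left``/``right`` hold the clipped weighted class-probability estimates
    (p0, p1) on each side.
    """

    feature: int
    threshold: float
    left: tuple[float, float]
    right: tuple[float, float]

    def side(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.feature] <= self.threshold

    def proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((len(X), 2))
        mask = self.side(X)
        out[mask] = self.left
        out[~mask] = self.right
        return out


@dataclass
class BoostModel:
    """Fitted SAMME.R ensemble with training metadata."""

    stumps: list[Stump]
    feature_names: list[str]
    learning_rate: float
    n_estimators: int
    prior: tuple[float, float]
    training_meta: dict = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return len(self.stumps)


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray, presort: np.ndarray):
    """Minimum-weighted-Gini stump over all (feature, midpoint-threshold) pairs.

    Returns (feature, threshold, best_impurity) or None when no candidate
    split exists.  Vectorized per feature via cumulative weight sums over the
    presorted order; ties resolved to the lowest feature index, then the
    lowest threshold (argmin picks the first of equal minima in ascending
    threshold order, and the cross-feature comparison is strict).
    """
    n, d = X.shape
    total_w = w.sum()
    total_w1 = float(w @ y)
    best = None  # (impurity, feature, threshold)
    for f in range(d):
        order = presort[:, f]
        xs = X[order, f]
        ws = w[order]
        ys = y[order]
        cw = np.cumsum(ws)
        cw1 = np.cumsum(ws * ys)
        cut = np.flatnonzero(xs[:-1] != xs[1:])  # boundaries between distinct values
        if len(cut) == 0:
            continue
        wl = cw[cut]
        wl1 = cw1[cut]
        wr = total_w - wl
        wr1 = total_w1 - wl1
        # side impurity: W - (W1^2 + W0^2)/W, summed over sides
        imp = (
            wl - (wl1**2 + (wl - wl1) ** 2) / wl
            + wr - (wr1**2 + (wr - wr1) ** 2) / wr
        )
        j = int(np.argmin(imp))
        if best is None or imp[j] < best[0]:
            thr = 0.5 * (xs[cut[j]] + xs[cut[j] + 1])
            best = (float(imp[j]), f, float(thr))
    return best


def _leaf_probs(y: np.ndarray, w: np.ndarray, mask: np.ndarray, prior):
    sub_w = w[mask]
    if sub_w.sum() <= 0:
        p1 = prior[1]
    else:
        p1 = float(w[mask] @ y[mask] / sub_w.sum())
    p1 = min(max(p1, EPS), 1 - EPS)
    return (1.0 - p1, p1)


def fit_adaboost_samme_r(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series | None = None,
    n_estimators: int = 280,
    learning_rate: float = 0.1,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> BoostModel:
    """Fit the SAMME.R decision-stump ensemble (see module docstring).

    ``X`` may be a feature table DataFrame (labels taken from its ``label``
    column when ``y`` is None) or a plain array with explicit ``y``.  The
    procedure is deterministic given its inputs; ``seed`` is recorded in the
    metadata and used only by optional downstream CV reporting.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = feature_columns(X)
        if y is None:
            y = X["label"].to_numpy()
        X = X[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        if y is None:
            raise ValueError("y is required when X is an array")
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary {0,1}")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    n, d = X.shape

    prior1 = float(np.clip(y.mean(), EPS, 1 - EPS))
    prior = (1.0 - prior1, prior1)
    presort = np.argsort(X, axis=0, kind="stable")

    w = np.full(n, 1.0 / n)
    stumps: list[Stump] = []
    stop_reason = "n_estimators"
    for _ in range(n_estimators):
        parent_imp = w.sum() - ((w @ y) ** 2 + (w @ (1 - y)) ** 2) / w.sum()
        found = _best_stump(X, y, w, presort)
        if found is None or found[0] >= parent_imp - 1e-12:
            stop_reason = "no_impurity_improvement"
            break
        _, f, thr = found
        mask = X[:, f] <= thr
        left = _leaf_probs(y, w, mask, prior)
        right = _leaf_probs(y, w, ~mask, prior)
        stump = Stump(feature=f, threshold=thr, left=left, right=right)

        proba = stump.proba(X)
        pred = (proba[:, 1] >= proba[:, 0]).astype(int)
        err = float(w @ (pred != y))
        if err > 0.5:
            stop_reason = "weighted_error_above_half"
            break
        stumps.append(stump)

        pure = (
            min(left) <= EPS * 2 and min(right) <= EPS * 2
        )
        if pure:
            stop_reason = "pure_leaves"
            break

        # SAMME.R weight update, K = 2: exponent = -lr/2 * (log p_true - log p_other)
        logp = np.log(proba)
        margin = np.where(y == 1, logp[:, 1] - logp[:, 0], logp[:, 0] - logp[:, 1])
        w = w * np.exp(-0.5 * learning_rate * margin)
        w = w / w.sum()

    if not stumps:
        warnings.warn(
            "no informative split found; model predicts the class prior",
            stacklevel=2,
        )
    return BoostModel(
        stumps=stumps,
        feature_names=list(feature_names),
        learning_rate=learning_rate,
        n_estimators=n_estimators,
        prior=prior,
        training_meta={
            "seed": int(seed),
            "n_train": int(n),
            "stop_reason": stop_reason,
            "n_rounds": len(stumps),
        },
    )


def decision_scores(model: BoostModel, X: np.ndarray) -> np.ndarray:
    """Summed class-1 additive votes sum_m h_1(x) (class-0 vote is its negation)."""
    F = np.zeros(len(X))
    for stump in model.stumps:
        logp = np.log(stump.proba(X))
        # h_1 = (K-1)(log p1 - mean log p) = (log p1 - log p0)/2 for K = 2
        F += 0.5 * (logp[:, 1] - logp[:, 0])
    return F


def predict_integrated(model: BoostModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Integrated cleavage probability: softmax class-1 probability of the votes."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks model columns: {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    if not model.stumps:
        return np.full(len(X), model.prior[1])
    F = decision_scores(model, X)
    # softmax over (h_0, h_1) = (-F, F)
    return 1.0 / (1.0 + np.exp(-2.0 * np.clip(F, -350, 350)))


# ---------------------------------------------------------------------------
# Persistence and CV reporting
# ---------------------------------------------------------------------------


def save_model(model: BoostModel, path: str | Path) -> None:
    obj = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_names": model.feature_names,
        "learning_rate": model.learning_rate,
        "n_estimators": model.n_estimators,
        "prior": list(model.prior),
        "training_meta": model.training_meta,
        "stumps": [
            {
                "feature": s.feature,
                "threshold": s.threshold,
                "left": list(s.left),
                "right": list(s.right),
            }
            for s in model.stumps
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)
        fh.write("\n")


def load_model(path: str | Path) -> BoostModel:
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"unreadable model file {path}: {exc}") from exc
    version = obj.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"model schema version {version!r} != supported {MODEL_SCHEMA_VERSION}"
        )
    try:
        return BoostModel(
            stumps=[
                Stump(
                    feature=int(s["feature"]),
                    threshold=float(s["threshold"]),
                    left=tuple(s["left"]),
                    right=tuple(s["right"]),
                )
                for s in obj["stumps"]
            ],
            feature_names=list(obj["feature_names"]),
            learning_rate=float(obj["learning_rate"]),
            n_estimators=int(obj["n_estimators"]),
            prior=tuple(obj["prior"]),
            training_meta=dict(obj.get("training_meta", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model file {path}: {exc}") from exc


def train_report(
    table: pd.DataFrame,
    n_estimators: int = 280,
    learning_rate: float = 0.1,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Per-fold stratified-CV ROC/PR-AUC of the ensemble on a feature table.

    CV is for reporting generalization, not re-tuning; the returned dict is
    JSON-serializable for the training report file.
    """
    from .evaluation import pr_auc, roc_auc

    feats = feature_columns(table)
    labels = table["label"].to_numpy()
    folds = stratified_kfold(labels, k=k, seed=seed)
    per_fold = []
    for f in range(k):
        tr, te = folds != f, folds == f
        model = fit_adaboost_samme_r(
            table.loc[tr, feats], labels[tr],
            n_estimators=n_estimators, learning_rate=learning_rate, seed=seed,
            feature_names=feats,
        )
        p = predict_integrated(model, table.loc[te, feats])
        per_fold.append(
            {
                "fold": f,
                "n_test": int(te.sum()),
                "roc_auc": roc_auc(p, labels[te]).auc,
                "pr_auc": pr_auc(p, labels[te]).auc,
            }
        )
    return {
        "k": k,
        "seed": seed,
        "n_estimators": n_estimators,
        "learning_rate": learning_rate,
        "folds": per_fold,
        "mean_roc_auc": float(np.mean([f["roc_auc"] for f in per_fold])),
        "mean_pr_auc": float(np.mean([f["pr_auc"] for f in per_fold])),
    }
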