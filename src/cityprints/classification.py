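"""City-of-origin classifiers on common-level normalized profiles.

Two complementary approaches:

* A bagged-tree random forest (bootstrap aggregation of CART trees, a random
  subset of predictors at each split) scored by its out-of-bag (OOB) error,
  with per-predictor importance measured as the mean decrease in OOB accuracy
  when that predictor is permuted, tree by tree.
* A pairwise *ensemble classifier* for two cities at a time: a roster of
  component classifiers is trained and assessed on the training fold, ranked
  on several performance metrics, rank-aggregated into voting weights, and
  the weighted vote predicts the test fold.  Repeated stratified 2-fold
  cross-validation yields per-iteration accuracy, sensitivity, specificity
  and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import PreconditionError
from .preprocess import NormalizedTable
from .rng import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "RfReport",
    "EnsembleReport",
    "rf_city_classifier",
    "ensemble_pairwise",
    "rank_aggregate",
    "default_components",
]


@dataclass
class RfReport:
    oob_error: float
    per_city_error: pd.Series
    importance: pd.DataFrame          # level x (mda, se)
    settings: dict
    n_scored: int                     # samples with >= 1 OOB vote


@dataclass
class EnsembleReport:
    pair: tuple
    positive_class: str
    metrics: pd.DataFrame             # iteration x (accuracy, sensitivity, specificity, auc)
    mean_weights: pd.Series           # component -> mean voting weight
    settings: dict

    def summary(self) -> pd.Series:
        return self.metrics.mean(axis=0)


def rf_city_classifier(
    norm: NormalizedTable,
    trees: int = 1000,
    vars_per_split: int = 10,
    seed: int = 0,
    compute_importance: bool = True,
) -> RfReport:
    """Random forest of ``trees`` CART trees with OOB error and MDA importance.

    ``vars_per_split`` is capped at the number of predictor levels.  The OOB
    error uses only trees whose bootstrap excluded the sample; importance is
    the mean over trees of (OOB accuracy - OOB accuracy after permuting one
    predictor column).
    """
    X = norm.values.T.to_numpy(dtype=float)
    labels = norm.meta["city"].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise PreconditionError("random forest needs >= 2 cities")
    for c in classes:
        if (labels == c).sum() < 2:
            raise PreconditionError(f"city {c!r} has < 2 samples")
    n, p = X.shape
    m = min(int(vars_per_split), p)
    rng = stage_rng(seed, "rf_city_classifier")

    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features=m),
        n_estimators=int(trees),
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    forest.fit(X, labels)
    classes = forest.classes_
    # bagging fits its inner estimators on integer-encoded labels
    y_enc = np.searchsorted(classes, labels)

    votes = np.zeros((n, len(classes)), dtype=float)
    imp = np.zeros((len(forest.estimators_), p)) if compute_importance else None
    for t, (est, inbag) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size == 0:
            continue
        pred = np.asarray(est.predict(X[oob]), dtype=int)
        for i, c in zip(oob, pred):
            votes[i, c] += 1.0
        if compute_importance:
            acc = float(np.mean(pred == y_enc[oob]))
            Xo = X[oob]
            for j in range(p):
                perm = rng.permutation(oob.size)
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                acc_perm = float(np.mean(est.predict(Xp) == y_enc[oob]))
                imp[t, j] = acc - acc_perm

    scored = votes.sum(axis=1) > 0
    if not scored.all():
        logger.warning("%d samples received no OOB votes", int((~scored).sum()))
    oob_pred = classes[np.argmax(votes[scored], axis=1)]
    y_scored = labels[scored]
    oob_error = float(np.mean(oob_pred != y_scored))
    per_city = pd.Series(
        {
            c: float(np.mean(oob_pred[y_scored == c] != c))
            for c in classes
        },
        name="oob_error",
    )
    if compute_importance:
        importance = pd.DataFrame(
            {
                "mda": imp.mean(axis=0),
                "se": imp.std(axis=0, ddof=1) / np.sqrt(imp.shape[0]),
            },
            index=norm.values.index,
        )
    else:
        importance = pd.DataFrame(columns=["mda", "se"])
    return RfReport(
        oob_error=oob_error,
        per_city_error=per_city,
        importance=importance,
        settings={"trees": int(trees), "vars_per_split": m, "seed": int(seed)},
        n_scored=int(scored.sum()),
    )


def rank_aggregate(performance: pd.DataFrame) -> pd.Series:
    """Borda (mean-rank) aggregation of a classifier x metric matrix.

    Higher metric values are better.  Per metric, classifiers get ranks
    1..C (ties averaged); mean ranks are mapped to non-negative weights
    ``C + 1 - meanrank`` and normalized to sum to one.
    """
    if performance.size == 0:
        raise PreconditionError("empty performance matrix")
    ranks = performance.apply(lambda col: rankdata(-col.to_numpy()), axis=0)
    mean_rank = ranks.mean(axis=1)
    c = performance.shape[0]
    raw = (c + 1) - mean_rank
    return raw / raw.sum()


def default_components(seed: int = 0) -> dict:
    """The default component-classifier roster for the pairwise ensemble."""
    rng = stage_rng(seed, "ensemble_components")

    def rs():
        return int(rng.integers(2**31 - 1))

    return {
        "lda": LinearDiscriminantAnalysis(),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "cart": DecisionTreeClassifier(random_state=rs()),
        "svm_linear": SVC(kernel="linear", random_state=rs()),
        "rf": RandomForestClassifier(n_estimators=50, random_state=rs()),
        "plr": LogisticRegression(max_iter=500),
    }


def _fit_component(template, X, y):
    est = clone(template)
    if isinstance(est, KNeighborsClassifier):
        est.set_params(n_neighbors=min(est.n_neighbors, len(y)))
    est.fit(X, y)
    return est


def _component_metrics(y_true, y_pred, score, positive) -> dict:
    pos = y_true == positive
    acc = float(np.mean(y_pred == y_true))
    sens = float(np.mean(y_pred[pos] == positive)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[~pos] != positive)) if (~pos).any() else np.nan
    if score is None or len(np.unique(y_true)) < 2:
        auc = 0.5
    else:
        auc = float(roc_auc_score(pos.astype(int), score))
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


def _decision_scores(est, X, positive):
    """Positive-class score in a common orientation, if the model offers one."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, list(est.classes_).index(positive)]
    if hasattr(est, "decision_function"):
        raw = est.decision_function(X)
        # decision_function is oriented toward classes_[1]
        return raw if est.classes_[1] == positive else -raw
    return None


def ensemble_pairwise(
    norm: NormalizedTable,
    pair,
    folds: int = 2,
    iterations: int = 100,
    seed: int = 0,
    components: dict | None = None,
) -> EnsembleReport:
    """Adaptive weighted-vote ensemble for one city pair.

    Per iteration: a random stratified ``folds``-fold split; on each training
    fold the components are assessed by internal 2-fold cross-validation,
    ranked on (accuracy, sensitivity, specificity, AUC) and rank-aggregated
    into weights; the refitted components then vote, weighted, on the held-out
    fold.  The vote score (total weight voting positive) supplies the AUC.
    Metrics are averaged over the folds of each iteration.

    The positive class is the first label of ``pair``.
    """
    pair = tuple(pair)
    if len(pair) != 2 or pair[0] == pair[1]:
        raise PreconditionError("pair must name exactly two distinct cities")
    cities = set(norm.meta["city"])
    missing = [c for c in pair if c not in cities]
    if missing:
        raise PreconditionError(f"cities not in dataset: {missing}")
    mask = norm.meta["city"].isin(pair).to_numpy()
    X = norm.values.T.to_numpy(dtype=float)[mask]
    y = norm.meta["city"].to_numpy()[mask]
    positive = pair[0]
    for c in pair:
        if (y == c).sum() < 2 * folds:
            raise PreconditionError(
                f"city {c!r} needs >= {2 * folds} samples for {folds}-fold CV"
            )

    if components is None:
        components = default_components(seed)
    rng = stage_rng(seed, "ensemble_pairwise")
    records = []
    weight_sums = pd.Series(0.0, index=list(components))
    n_weightings = 0
    for _ in range(int(iterations)):
        outer = StratifiedKFold(n_splits=folds, shuffle=True,
                                random_state=int(rng.integers(2**31 - 1)))
        fold_metrics = []
        for train_idx, test_idx in outer.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xte, yte = X[test_idx], y[test_idx]
            # internal assessment of each component on the training fold
            inner = StratifiedKFold(n_splits=2, shuffle=True,
                                    random_state=int(rng.integers(2**31 - 1)))
            perf_rows = {}
            for name, template in components.items():
                y_pred = np.empty_like(ytr)
                score = np.zeros(len(ytr))
                has_score = True
                for itr, ite in inner.split(Xtr, ytr):
                    est = _fit_component(template, Xtr[itr], ytr[itr])
                    y_pred[ite] = est.predict(Xtr[ite])
                    s = _decision_scores(est, Xtr[ite], positive)
                    if s is None:
                        has_score = False
                    else:
                        score[ite] = s
                perf_rows[name] = _component_metrics(
                    ytr, y_pred, score if has_score else None, positive
                )
            perf = pd.DataFrame(perf_rows).T[
                ["accuracy", "sensitivity", "specificity", "auc"]
            ]
            weights = rank_aggregate(perf)
            weight_sums = weight_sums.add(weights, fill_value=0.0)
            n_weightings += 1
            # refit on the full training fold, weighted vote on the test fold
            vote_score = np.zeros(len(yte))
            for name, template in components.items():
                est = _fit_component(template, Xtr, ytr)
                vote_score += weights[name] * (est.predict(Xte) == positive)
            y_hat = np.where(vote_score >= 0.5, positive,
                             pair[1] if positive == pair[0] else pair[0])
            fold_metrics.append(
                _component_metrics(yte, y_hat, vote_score, positive)
            )
        records.append(pd.DataFrame(fold_metrics).mean(axis=0))

    metrics = pd.DataFrame(records)
    metrics.index.name = "iteration"
    return EnsembleReport(
        pair=pair,
        positive_class=positive,
        metrics=metrics,
        mean_weights=weight_sums / max(n_weightings, 1),
        settings={"folds": int(folds), "iterations": int(iterations),
                  "seed": int(seed), "components": list(components)},
    )
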