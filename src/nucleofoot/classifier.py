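"""Promoter-profiling classifier: per-feature optimal-cutoff
discretization, L1-penalized logistic regression, and repeated
stratified cross-validation with ROC/AUC summaries.

Each feature (TSS occupancy) is binarized at the threshold maximizing
balanced accuracy, ``(sensitivity + specificity) / 2``, on the training
samples of the current fold; the rules are then applied unchanged to
held-out samples. A LASSO-penalized logistic model is fitted on the
binary matrix, with the penalty chosen by an inner cross-validation
minimizing binomial deviance on the training data only. Stratified
fivefold cross-validation, repeated (100 times by default), yields the
per-fold AUC distribution and its median.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import FitError, ParameterError, ValidationError
from .occupancy import OccupancyMatrix

N_LAMBDA = 50
LAMBDA_DECADES = 4.0


@dataclasses.dataclass(frozen=True)
class CutoffRule:
    """Per-feature discretization rule, learned on training data only.

    ``orientation`` is "greater" when values strictly above the
    threshold map to 1, "less" when values strictly below map to 1.
    A value exactly at the threshold always maps to 0.
    """

    feature_id: str
    threshold: float
    orientation: str
    balanced_accuracy: float = float("nan")

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.orientation == "greater":
            return (v > self.threshold).astype(np.int8)
        return (v < self.threshold).astype(np.int8)


def optimal_cutoff(values, labels, feature_id: str = "") -> CutoffRule:
    """Threshold and orientation maximizing (sensitivity + specificity)/2.

    Candidate thresholds are the midpoints between adjacent distinct
    sorted values, plus -inf and +inf. Ties are broken toward the
    smallest threshold, then toward the "greater" orientation.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ParameterError("labels must be binary 0/1")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present to learn a cutoff")
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], (y[order] == 1)
    n = len(vs)
    cum1 = np.concatenate(([0], np.cumsum(ys)))  # ones among first i values
    # candidate split positions: i values at or below the threshold
    boundary = np.flatnonzero(np.diff(vs) > 0) + 1
    positions = np.concatenate(([0], boundary, [n]))
    thresholds = np.where(
        positions == 0,
        -np.inf,
        np.where(positions == n, np.inf,
                 (vs[np.clip(positions, 1, n) - 1] + vs[np.clip(positions, 0, n - 1)]) / 2.0),
    )
    best = None
    for i, t in zip(positions, thresholds):
        c1 = cum1[i]
        # "greater": predict 1 for the n - i values above t
        ba_g = ((n1 - c1) / n1 + (i - c1) / n0) / 2.0
        # "less": predict 1 for the i values below t
        ba_l = (c1 / n1 + ((n - i) - (n1 - c1)) / n0) / 2.0
        for ba, orient in ((ba_g, "greater"), (ba_l, "less")):
            if best is None or ba > best[0] + 1e-12:
                best = (ba, float(t), orient)
    ba, t, orient = best
    return CutoffRule(feature_id=feature_id, threshold=t, orientation=orient,
                      balanced_accuracy=float(ba))


def learn_cutoffs(matrix: pd.DataFrame, labels) -> dict:
    """Learn one CutoffRule per feature row of a feature x sample matrix."""
    y = np.asarray(labels)
    return {
        fid: optimal_cutoff(matrix.loc[fid].to_numpy(), y, feature_id=str(fid))
        for fid in matrix.index
    }


def discretize(matrix: pd.DataFrame, rules: Mapping) -> pd.DataFrame:
    """Apply per-feature cutoff rules; entries become 0/1.

    Rules learned on training samples are applied verbatim to held-out
    samples; a feature without a rule is an error.
    """
    missing = [f for f in matrix.index if f not in rules]
    if missing:
        raise ValidationError(f"no cutoff rule for features: {missing[:3]}")
    out = {}
    for fid in matrix.index:
        out[fid] = rules[fid].apply(matrix.loc[fid].to_numpy())
    return pd.DataFrame(out, index=matrix.columns).T.astype(np.int8)


@dataclasses.dataclass
class LassoLogisticModel:
    """L1-penalized logistic model over binary promoter features."""

    feature_ids: list
    coef: np.ndarray
    intercept: float
    lambda_: float
    lambda_grid: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    @property
    def selected_features(self) -> list:
        return [f for f, c in zip(self.feature_ids, self.coef) if c != 0]


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    if lam_max <= 0:
        raise FitError("all features are constant; no penalty path exists")
    return np.geomspace(lam_max, lam_max * 10.0 ** (-LAMBDA_DECADES), n_lambda)


def _fit_path(X, y, lambdas, tol, max_iter=5000, solver="saga"):
    """Warm-started L1 logistic fits along a descending penalty path.

    ``saga`` leaves the intercept unpenalized; the faster ``liblinear``
    (used only to rank penalties in the inner CV) penalizes it weakly
    via a large ``intercept_scaling``. Whenever the fitted coefficients
    are all zero the intercept is replaced by its closed-form optimum,
    the log-odds of class prevalence.
    """
    n = len(y)
    extra = {"intercept_scaling": 100.0} if solver == "liblinear" else {}
    clf = LogisticRegression(
        l1_ratio=1.0, solver=solver, warm_start=True, max_iter=max_iter,
        tol=tol, fit_intercept=True, C=1.0, random_state=0, **extra,
    )
    prevalence_logit = float(np.log(y.mean() / (1.0 - y.mean())))
    coefs, intercepts = [], []
    with warnings.catch_warnings():
        # near-unpenalized path ends on separable data may hit the
        # iteration cap; the deviance comparison is insensitive to that
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            clf.C = 1.0 / (n * lam)
            clf.fit(X, y)
            w = clf.coef_[0].copy()
            b = float(clf.intercept_[0])
            if not w.any():
                b = prevalence_logit
            coefs.append(w)
            intercepts.append(b)
    return coefs, intercepts


def fit_lasso_logistic(
    X,
    y,
    feature_ids: Optional[Sequence] = None,
    lambda_grid=None,
    n_lambda: int = N_LAMBDA,
    inner_folds: int = 5,
    seed: int = 0,
) -> LassoLogisticModel:
    """LASSO logistic regression with the penalty chosen by inner CV.

    The grid descends log-spaced from the data-derived ``lambda_max``
    (the smallest penalty shrinking every coefficient to zero) over four
    decades. The chosen penalty minimizes mean binomial deviance over an
    inner stratified CV within the supplied (training) data; ties go to
    the heavier penalty. The intercept is unpenalized, so in the fully
    penalized limit it equals the log-odds of class prevalence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ParameterError("X must be samples x features aligned with y")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ParameterError("need at least 2 samples per class")
    if np.all(X == X[0]):
        raise FitError("all samples are identical; model is unidentifiable")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if lambda_grid is None:
        lambda_grid = _lambda_grid(X, y, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    if len(lambda_grid) > 1:
        k = min(inner_folds, int((y == 1).sum()), int((y == 0).sum()))
        skf = StratifiedKFold(n_splits=max(2, k), shuffle=True,
                              random_state=seed % (2**31))
        deviance = np.zeros(len(lambda_grid))
        for tr, va in skf.split(X, y):
            coefs, intercepts = _fit_path(X[tr], y[tr], lambda_grid,
                                          tol=1e-3, max_iter=800,
                                          solver="liblinear")
            for j, (w, b) in enumerate(zip(coefs, intercepts)):
                p = 1.0 / (1.0 + np.exp(-(X[va] @ w + b)))
                p = np.clip(p, 1e-12, 1.0 - 1e-12)
                deviance[j] += float(
                    -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1.0 - p))
                )
        best_j = int(np.argmin(deviance))  # argmin takes first = heaviest penalty
        lam = float(lambda_grid[best_j])
    else:
        lam = float(lambda_grid[0])

    coefs, intercepts = _fit_path(X, y, np.asarray([lam]), tol=1e-5)
    return LassoLogisticModel(
        feature_ids=list(feature_ids),
        coef=coefs[-1],
        intercept=intercepts[-1],
        lambda_=lam,
        lambda_grid=np.asarray(lambda_grid),
    )


def roc_auc(scores, labels) -> float:
    """AUC: probability a random positive outscores a random negative,
    ties counted one half (equivalent to the trapezoidal ROC area)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclasses.dataclass
class CvReport:
    """Repeated cross-validation summary."""

    aucs: np.ndarray  # shape (n_repeats, n_folds)
    median_auc: float
    selected_features: list  # per repeat: sorted list of feature ids
    n_repeats: int
    n_folds: int
    seed: int
    fold_details: Optional[list] = None

    def to_json_dict(self) -> dict:
        return {
            "median_auc": self.median_auc,
            "aucs": [[float(a) for a in row] for row in self.aucs],
            "selected_features": [list(s) for s in self.selected_features],
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def _fit_fold(X_train: pd.DataFrame, y_train, seed: int,
              filter_features=None, lambda_kwargs=None):
    """Learn all training artifacts for one fold: feature subset,
    cutoff rules, and the penalized model. Sees training data only."""
    lambda_kwargs = lambda_kwargs or {}
    feats = list(X_train.index) if filter_features is None else list(filter_features)
    Xt = X_train.loc[feats]
    rules = learn_cutoffs(Xt, y_train)
    Xb = discretize(Xt, rules)
    model = fit_lasso_logistic(
        Xb.T.to_numpy(), y_train, feature_ids=feats, seed=seed, **lambda_kwargs
    )
    return feats, rules, model


def repeated_cv(
    matrix,
    labels: Mapping,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    filter_thresholds=None,
    filter_scope: Optional[str] = None,
    lambda_kwargs: Optional[dict] = None,
    collect_details: bool = False,
) -> CvReport:
    """Stratified k-fold CV of the discretized-LASSO classifier,
    repeated ``n_repeats`` times with reshuffled folds.

    ``labels`` maps sample id -> 0/1 (or two group names; the
    lexicographically larger becomes class 1). With
    ``filter_scope='fold'`` the differential feature filter
    (``filter_thresholds``) is re-applied within each training fold;
    with ``'global'`` it is applied once on the full matrix before CV
    (the leakier variant, provided for comparison). Folds are assigned
    on the canonical (sorted) sample ordering, so the report is
    invariant to the input column order given the same seed.
    """
    from .differential import call_differential  # local import, avoids cycle

    df = matrix.df if isinstance(matrix, OccupancyMatrix) else matrix
    samples = sorted(df.columns)
    labels = dict(labels)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValidationError(f"samples without labels: {missing[:3]}")
    raw = [labels[s] for s in samples]
    classes = sorted(set(raw))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    y = np.array([1 if r == classes[1] else 0 for r in raw])
    if (y == 1).sum() < n_folds or (y == 0).sum() < n_folds:
        raise ParameterError("each class must have at least n_folds samples")
    X = df[samples]

    if filter_scope not in (None, "fold", "global"):
        raise ParameterError("filter_scope must be None, 'fold', or 'global'")
    if filter_scope is not None and filter_thresholds is None:
        raise ParameterError("filter_scope requires filter_thresholds")

    def significant(sub_X, sub_y_mask):
        sub_labels = {s: ("g1" if y[i] else "g0")
                      for i, s in enumerate(samples) if sub_y_mask[i]}
        table = call_differential(sub_X, sub_labels, filter_thresholds,
                                  group_a="g0", group_b="g1")
        feats = list(table.index[table["call"] != "ns"])
        return feats if feats else list(sub_X.index)  # fall back to all

    if filter_scope == "global":
        X = X.loc[significant(X, np.ones(len(samples), dtype=bool))]

    aucs = np.empty((n_repeats, n_folds))
    selected = []
    details = [] if collect_details else None
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(np.random.SeedSequence((seed, r)).generate_state(1)[0] % (2**31)),
        )
        picked = set()
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), y)):
            train_samples = [samples[i] for i in tr]
            test_samples = [samples[i] for i in te]
            X_train = X[train_samples]
            if filter_scope == "fold":
                mask = np.zeros(len(samples), dtype=bool)
                mask[tr] = True
                feats = significant(X_train, mask)
            else:
                feats = None
            fold_seed = int(np.random.SeedSequence((seed, r, f)).generate_state(1)[0])
            feats, rules, model = _fit_fold(X_train, y[tr], fold_seed,
                                            filter_features=feats,
                                            lambda_kwargs=lambda_kwargs)
            Xb_test = discretize(X.loc[feats, test_samples], rules)
            scores = model.predict_proba(Xb_test.T.to_numpy())
            aucs[r, f] = roc_auc(scores, y[te])
            picked.update(model.selected_features)
            if collect_details:
                details.append({
                    "repeat": r, "fold": f,
                    "train_samples": train_samples,
                    "test_samples": test_samples,
                    "features": list(feats),
                    "rules": rules,
                    "lambda": model.lambda_,
                    "coef": model.coef.copy(),
                    "intercept": model.intercept,
                })
        selected.append(sorted(picked))
    return CvReport(
        aucs=aucs,
        median_auc=float(np.median(aucs)),
        selected_features=selected,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
        fold_details=details,
    )
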