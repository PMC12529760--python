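"""Imbalanced-learning protocol for Asn reactivity classification.

Reactive residues are rare (13 of 63 in the reference dataset), so the
protocol is: stratified 70/30 train/test split (three different seeds),
SMOTE oversampling of the minority class on the training set only,
exhaustive hyperparameter grid search with 8-fold stratified CV scored by
ROC-AUC, evaluation with macro (unweighted) precision/recall/F1, accuracy,
rank-based AUC and Matthews correlation coefficient, per-residue deamidation
scores (predicted probability of reactivity, thresholded at 0.5), and
leave-one-feature-out (LOFO) importance for single features and for the
chemical feature groups.

Model families mirror the reference protocol: Random Forest, Gaussian Naive
Bayes and L2 logistic regression (liblinear, max 100 iterations).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors

from .featureset import FEATURES, FEATURE_GROUPS

__all__ = [
    "ModelSpec",
    "default_specs",
    "stratified_split",
    "smote_oversample",
    "tune",
    "evaluate",
    "EvalResult",
    "rank_auc",
    "matthews_cc",
    "lofo_importance",
    "run_protocol",
]

DEFAULT_TEST_FRACTION = 0.30

#: reduced Random-Forest search grid for interactive/desk-scale runs; spans
#: the same hyperparameter ranges as the full default grid at a fraction of
#: the fit count. Pass to ``default_specs(rf_grid=SMALL_RF_GRID)``.
SMALL_RF_GRID = {
    "n_estimators": [50, 200],
    "max_depth": [10, None],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 2],
    "max_features": ["sqrt"],
}
DEFAULT_THRESHOLD = 0.5
DEFAULT_CV_FOLDS = 8
DEFAULT_SPLIT_SEEDS = (1, 2, 3)


@dataclass
class ModelSpec:
    """One model family plus its hyperparameter search space."""

    family: str  # random_forest | gaussian_naive_bayes | logistic_regression
    grid: dict
    cv_folds: int = DEFAULT_CV_FOLDS
    scoring: str = "roc_auc"

    def estimator(self, seed: int):
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=seed)
        if self.family == "gaussian_naive_bayes":
            return GaussianNB()
        if self.family == "logistic_regression":
            return LogisticRegression(
                solver="liblinear", penalty="l2", max_iter=100, random_state=seed
            )
        raise ValueError(f"unknown model family {self.family!r}")


def default_specs(rf_grid: dict | None = None) -> dict[str, ModelSpec]:
    """The three model specs with their full search grids.

    NB smoothing: 50 log-spaced values in [1e-9, 10]; LR C: 20 log-spaced
    values in [0.01, 10]; RF: trees {10..300}, depth {5..30, none},
    min-split {2,5,10}, min-leaf {1,2}, max-features {sqrt, log2}. A smaller
    ``rf_grid`` may be supplied for quick runs.
    """
    return {
        "gaussian_naive_bayes": ModelSpec(
            "gaussian_naive_bayes",
            {"var_smoothing": np.logspace(-9, 1, 50).tolist()},
        ),
        "logistic_regression": ModelSpec(
            "logistic_regression",
            {"C": np.logspace(np.log10(0.01), np.log10(10), 20).tolist()},
        ),
        "random_forest": ModelSpec(
            "random_forest",
            rf_grid
            or {
                "n_estimators": [10, 50, 100, 200, 300],
                "max_depth": [5, 10, 20, 30, None],
                "min_samples_split": [2, 5, 10],
                "min_samples_leaf": [1, 2],
                "max_features": ["sqrt", "log2"],
            },
        ),
    }


def _xy(table: pd.DataFrame, features=None):
    feats = list(features) if features is not None else [c for c in FEATURES if c in table.columns]
    return table[feats].to_numpy(float), table["label"].to_numpy(int), feats


def stratified_split(table: pd.DataFrame, test_fraction: float = DEFAULT_TEST_FRACTION,
                     seed: int = 0):
    """Deterministic stratified train/test split preserving class balance."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = table["label"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 members for stratification")
    train, test = train_test_split(
        table, test_size=test_fraction, stratify=table["label"], random_state=seed
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def smote_oversample(train: pd.DataFrame, k_neighbors: int = 5, seed: int = 0) -> pd.DataFrame:
    """Balance the training table by synthetic minority oversampling.

    New minority rows are convex combinations x + u·(x_nn − x) with
    u ~ U(0,1), x a minority point and x_nn one of its k nearest minority
    neighbours (Euclidean distance in feature space). k is reduced to
    (minority size − 1) when the class is too small, with a warning.
    """
    counts = train["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("need both classes to oversample")
    minority_label = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class must have at least 2 members")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return train.reset_index(drop=True)
    feats = [
        c for c in train.columns
        if c not in ("label", "protein_id", "residue")
        and np.issubdtype(train[c].dtype, np.number)
    ]
    Xmin = train.loc[train["label"] == minority_label, feats].to_numpy(float)
    k = k_neighbors
    if k > n_min - 1:
        k = n_min - 1
        warnings.warn(f"k_neighbors reduced to {k} (minority size {n_min})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, nbr = nn.kneighbors(Xmin)  # first neighbour is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = Xmin[base]
    xn = Xmin[nbr[base, pick]]
    synth = x + u[:, None] * (xn - x)
    new_rows = pd.DataFrame(synth, columns=feats)
    new_rows["label"] = minority_label
    for col in train.columns:
        if col not in new_rows.columns:
            new_rows[col] = "synthetic"
    out = pd.concat([train, new_rows[train.columns]], ignore_index=True)
    return out


def tune(train: pd.DataFrame, spec: ModelSpec, seed: int = 0, features=None):
    """Exhaustive grid search (stratified k-fold CV, mean ROC-AUC).

    Ties are broken in favour of the first grid point; the winner is refit
    on the full training table. Returns (fitted model, best params, CV score).
    """
    X, y, _ = _xy(train, features)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        spec.estimator(seed), spec.grid, scoring=spec.scoring, cv=cv, refit=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_), float(gs.best_score_)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the Mann–Whitney rank statistic (ties get midranks)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = np.sum(ranks[y_true == 1])
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def matthews_cc(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC = (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 when any
    denominator factor vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class EvalResult:
    """Test-set metrics, confusion counts and per-residue deamidation scores."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int
    scores: np.ndarray = field(repr=False, default=None)
    residues: list = field(repr=False, default_factory=list)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("precision", "recall", "f1", "accuracy", "auc", "mcc",
                      "tp", "tn", "fp", "fn")
        }


def evaluate(model, test: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
             features=None) -> EvalResult:
    """Score a fitted model on the test table.

    The deamidation score is the predicted probability of the reactive
    class; scores exactly at the threshold classify positive. Precision,
    recall and F1 are macro (unweighted) averages over the two classes; AUC
    is the rank statistic over the scores.
    """
    X, y, _ = _xy(test, features)
    classes = list(getattr(model, "classes_", [0, 1]))
    scores = model.predict_proba(X)[:, classes.index(1)]
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    p1, r1, f1_1 = prf(tp, fp, fn)          # reactive class
    p0, r0, f1_0 = prf(tn, fn, fp)          # nonreactive class
    auc = rank_auc(y, scores)
    residues = (
        list(zip(test.get("protein_id", [""] * len(test)), test.get("residue", range(len(test)))))
    )
    return EvalResult(
        precision=0.5 * (p0 + p1),
        recall=0.5 * (r0 + r1),
        f1=0.5 * (f1_0 + f1_1),
        accuracy=(tp + tn) / len(y),
        auc=auc,
        mcc=matthews_cc(tp, tn, fp, fn),
        tp=tp, tn=tn, fp=fp, fn=fn,
        scores=scores,
        residues=residues,
    )


def lofo_importance(
    table: pd.DataFrame,
    spec: ModelSpec,
    units: dict[str, list[str]] | None = None,
    seeds=DEFAULT_SPLIT_SEEDS,
    retune: bool = False,
    smote_k: int = 5,
    test_fraction: float = DEFAULT_TEST_FRACTION,
) -> dict[str, float]:
    """Leave-one-feature-out importance, averaged over the split seeds.

    ``units`` maps unit name → feature list (default: each single feature
    plus the chemical groups). For each split: the full model is tuned on
    the SMOTE-balanced training set; then for each unit the features are
    removed from the already-balanced training set and the test set and the
    model retrained (reusing the tuned hyperparameters by default; set
    ``retune`` to rerun the grid search per unit). Importance is the mean
    accuracy drop relative to the full model.
    """
    if units is None:
        units = {f: [f] for f in FEATURES if f in table.columns}
        units.update({g: cols for g, cols in FEATURE_GROUPS.items()})
    feats_all = [c for c in FEATURES if c in table.columns]
    extra = [c for c in table.columns if c not in FEATURES + ["label"]
             and np.issubdtype(table[c].dtype, np.number) and c != "residue"]
    feats_all = feats_all + extra
    drops: dict[str, list[float]] = {u: [] for u in units}
    for seed in seeds:
        train, test = stratified_split(table, test_fraction, seed)
        train_bal = smote_oversample(train, k_neighbors=smote_k, seed=seed)
        model, best, _ = tune(train_bal, spec, seed, features=feats_all)
        acc_full = evaluate(model, test, features=feats_all).accuracy
        for unit, cols in units.items():
            keep = [f for f in feats_all if f not in cols]
            if len(keep) < 2:
                raise ValueError("at least 2 features must remain after removal")
            if retune:
                sub_model, _, _ = tune(train_bal, spec, seed, features=keep)
            else:
                sub_model = clone(spec.estimator(seed)).set_params(**best)
                Xk, yk, _ = _xy(train_bal, keep)
                sub_model.fit(Xk, yk)
            acc_unit = evaluate(sub_model, test, features=keep).accuracy
            drops[unit].append(acc_full - acc_unit)
    return {u: float(np.mean(v)) for u, v in drops.items()}


def run_protocol(
    table: pd.DataFrame,
    specs: dict[str, ModelSpec] | None = None,
    split_seeds=DEFAULT_SPLIT_SEEDS,
    smote_k: int = 5,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    lofo: bool = True,
) -> dict:
    """Full protocol: splits × models → metrics, best split, averages, LOFO.

    Returns a JSON-serialisable report: per model, the metrics of every
    split seed, the best split (highest MCC) and the across-split averages,
    plus per-feature and per-group LOFO importances.
    """
    specs = specs or default_specs()
    report: dict = {"models": {}, "split_seeds": list(split_seeds)}
    for name, spec in specs.items():
        per_split = []
        for seed in split_seeds:
            train, test = stratified_split(table, test_fraction, seed)
            train_bal = smote_oversample(train, k_neighbors=smote_k, seed=seed)
            model, best, cv_score = tune(train_bal, spec, seed)
            res = evaluate(model, test)
            per_split.append(
                {
                    "seed": int(seed),
                    "best_params": {k: (None if v is None else v) for k, v in best.items()},
                    "cv_roc_auc": cv_score,
                    "metrics": res.as_dict(),
                    "deamidation_scores": [
                        {"protein_id": str(p), "residue": int(r), "score": float(s)}
                        for (p, r), s in zip(res.residues, res.scores)
                    ],
                }
            )
        best_split = max(per_split, key=lambda d: d["metrics"]["mcc"])
        avg = {
            k: float(np.mean([d["metrics"][k] for d in per_split]))
            for k in ("precision", "recall", "f1", "accuracy", "auc", "mcc")
        }
        entry = {"splits": per_split, "best_split": best_split, "average_metrics": avg}
        if lofo:
            entry["lofo"] = lofo_importance(
                table, spec, seeds=split_seeds, smote_k=smote_k,
                test_fraction=test_fraction,
            )
        report["models"][name] = entry
    return report
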