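"""Classifier benchmarking over exhaustive feature combinations.

Conserved (CWM) vs free (FWM) binding-site waters are discriminated with
seven classifier families — support vector machine (SVM), k-nearest
neighbours (KNN), decision tree (DT), logistic regression (LR),
discriminant analysis (DA), naive Bayes (NB) and an ensemble of bagged
trees (EL).  Every non-empty subset of the feature letters (63 subsets for
the six features A–F) is evaluated with stratified five-fold
cross-validation; per-combination metrics are averaged over the seven
families, and the best combination is the one that wins the most of the
five criteria (ACC, SN, PPV, F-score, AUC) within a ±0.001 tolerance band.

CWM is the positive class throughout.  Out-of-fold predictions are pooled
over the five folds and one metric set is computed on the pooled confusion
counts; undefined ratios (zero denominators) are reported as missing, never
coerced to 0.  Rows are canonically ordered before the fold split, so
pooled metrics are invariant under permutations of the input rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _itercombos
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger("conswat.ml")

POSITIVE = "CWM"
NEGATIVE = "FWM"

FAMILIES: tuple[str, ...] = ("SVM", "KNN", "DT", "LR", "DA", "NB", "EL")

CRITERIA: tuple[str, ...] = ("acc", "sn", "ppv", "fscore", "auc")

ARTIFACT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameters and seed."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")


#: families whose distance/margin geometry needs standardised features
_SCALED_FAMILIES = frozenset({"SVM", "KNN", "LR", "DA"})


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator behind a :class:`ModelSpec`.

    Defaults: SVM — RBF kernel, C=1, scaled gamma; KNN — k=5, Euclidean;
    DT — Gini, unlimited depth; LR — L2, C=1; DA — linear; NB — Gaussian;
    EL — bagged decision trees (random-forest style), 100 trees.  Features
    are z-scored inside the fold for the scale-sensitive families
    (SVM/KNN/LR/DA); trees and NB run on raw features.
    """
    hp = dict(spec.hyperparams)
    family = spec.family
    if family == "SVM":
        clf = SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), random_state=spec.seed, **hp)
    elif family == "KNN":
        clf = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    elif family == "DT":
        clf = DecisionTreeClassifier(criterion=hp.pop("criterion", "gini"), random_state=spec.seed, **hp)
    elif family == "LR":
        clf = LogisticRegression(C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 1000), random_state=spec.seed, **hp)
    elif family == "DA":
        clf = LinearDiscriminantAnalysis(**hp)
    elif family == "NB":
        clf = GaussianNB(**hp)
    elif family == "EL":
        clf = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, n_jobs=1, **hp)
    else:  # pragma: no cover — guarded by ModelSpec
        raise ValueError(family)
    if family in _SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def positive_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Positive-class (CWM) score per row, always in [0, 1].

    Class probabilities when the estimator provides them; otherwise the
    decision margin, oriented towards the positive class and squashed
    through a logistic so that a 0.5 threshold reproduces the predicted
    label.  The squashing is monotone, so AUC is unaffected.
    """
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        pos = list(estimator.classes_).index(POSITIVE)
        return proba[:, pos]
    s = np.asarray(estimator.decision_function(X), dtype=float)
    if list(estimator.classes_)[-1] != POSITIVE:
        s = -s
    return 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """TP/FP/TN/FN with CWM as the positive class.

    True positive: a CWM identified as CWM; false positive: an FWM called
    CWM; and so on.
    """
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(predicted)} predictions")
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    valid = {POSITIVE, NEGATIVE}
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t not in valid or p not in valid:
            raise ValueError(f"unknown label value in pair ({t!r}, {p!r})")
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass(frozen=True)
class MetricSet:
    """ACC, SN, PPV, F-score and AUC for one evaluation.

    Undefined ratios (zero denominator) are ``None`` — an absent value is
    meaningfully different from 0 and is excluded from averages.
    """

    acc: float | None
    sn: float | None
    ppv: float | None
    fscore: float | None
    auc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {c: getattr(self, c) for c in CRITERIA}

    def average_performance(self) -> float:
        """Mean of the five criteria (defined values only)."""
        vals = [v for v in self.as_dict().values() if v is not None]
        if len(vals) < len(CRITERIA):
            logger.warning("average performance over %d of %d defined criteria", len(vals), len(CRITERIA))
        return float(np.mean(vals))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def auc_score(truth: Sequence[str], scores: Sequence[float]) -> float | None:
    """Probability a random positive outranks a random negative (ties ½).

    Equals the trapezoidal area under the ROC curve.  ``None`` with a
    warning when only one class is present.
    """
    y = np.asarray([1 if t == POSITIVE else 0 for t in truth])
    if y.min() == y.max():
        logger.warning("AUC undefined: only one class present")
        return None
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def compute_metrics(
    counts: ConfusionCounts,
    truth: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> MetricSet:
    """Metric set from confusion counts (+ optional scores for AUC)."""
    if counts.n < 1:
        raise ValueError("empty confusion counts")
    auc = auc_score(truth, scores) if truth is not None and scores is not None else None
    return MetricSet(
        acc=_ratio(counts.tp + counts.tn, counts.n),
        sn=_ratio(counts.tp, counts.tp + counts.fn),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        fscore=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# cross-validation


def _feature_matrix(data: pd.DataFrame, letters: str) -> np.ndarray:
    missing = [c for c in letters if c not in data.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    X = data[list(letters)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Content-stable row order: folds depend on values, not input order."""
    keys = [y.astype("U8")] + [X[:, j] for j in range(X.shape[1] - 1, -1, -1)]
    return np.lexsort(keys)


def five_fold_cv(
    data: pd.DataFrame,
    spec: ModelSpec,
    letters: str = "ABCDEF",
    seed: int = 0,
    n_folds: int = 5,
) -> MetricSet:
    """Stratified k-fold cross-validation, metrics on pooled predictions.

    Out-of-fold labels and scores from all folds are pooled and one
    :class:`MetricSet` is computed on the pooled confusion counts — well
    defined even when a single fold would have an empty ratio denominator.
    """
    X = _feature_matrix(data, letters)
    y = data["label"].to_numpy(dtype="U8")
    classes, class_n = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if class_n.min() < n_folds:
        raise ValueError(f"each class needs at least {n_folds} rows for {n_folds}-fold CV")

    order = _canonical_order(X, y)
    Xs, ys = X[order], y[order]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(ys)
    score = np.empty(len(ys), dtype=float)
    for train_idx, test_idx in skf.split(Xs, ys):
        est = build_estimator(spec)
        est.fit(Xs[train_idx], ys[train_idx])
        pred[test_idx] = est.predict(Xs[test_idx])
        score[test_idx] = positive_scores(est, Xs[test_idx])
    counts = confusion_counts(list(ys), list(pred))
    return compute_metrics(counts, truth=list(ys), scores=score)


# ---------------------------------------------------------------------------
# feature-combination sweep


def enumerate_combinations(letters: str = "ABCDEF") -> list[str]:
    """All non-empty feature subsets, larger subsets first, then lexicographic.

    For six features this yields 63 combinations, starting with the full
    set ``ABCDEF`` and ending with ``F``.
    """
    letters = "".join(sorted(dict.fromkeys(letters)))
    if not 1 <= len(letters) <= 12:
        raise ValueError("feature set must contain 1–12 letters")
    out: list[str] = []
    for size in range(len(letters), 0, -1):
        out.extend("".join(c) for c in _itercombos(letters, size))
    return out


@dataclass
class CombinationReport:
    """Per-model and model-averaged metrics for one feature combination."""

    combination: str
    per_model: dict[str, MetricSet]
    averaged: MetricSet

    @classmethod
    def from_averaged(cls, combination: str, **criteria: float) -> "CombinationReport":
        """Report holding only pre-computed averaged values (fixture entry)."""
        return cls(combination, {}, MetricSet(**{c: criteria.get(c) for c in CRITERIA}))


def average_metrics(metric_sets: Iterable[MetricSet]) -> MetricSet:
    """Arithmetic mean per criterion over models; missing values excluded."""
    sets = list(metric_sets)
    if not sets:
        raise ValueError("no metric sets to average")
    avg: dict[str, float | None] = {}
    for c in CRITERIA:
        vals = [m.as_dict()[c] for m in sets]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            logger.warning("%s undefined for %d of %d models; averaging the rest", c, len(vals) - len(defined), len(vals))
        avg[c] = float(np.mean(defined)) if defined else None
    return MetricSet(**avg)


def default_model_specs(seed: int, hyperparams: dict[str, dict] | None = None) -> list[ModelSpec]:
    hyperparams = hyperparams or {}
    return [ModelSpec(f, hyperparams.get(f, {}), seed=seed) for f in FAMILIES]


def evaluate_combinations(
    data: pd.DataFrame,
    seed: int = 0,
    letters: str = "ABCDEF",
    families: Sequence[str] = FAMILIES,
    hyperparams: dict[str, dict] | None = None,
) -> list[CombinationReport]:
    """Cross-validate every feature combination under every model family."""
    specs = [s for s in default_model_specs(seed, hyperparams) if s.family in set(families)]
    reports = []
    for combo in enumerate_combinations(letters):
        per_model = {s.family: five_fold_cv(data, s, letters=combo, seed=seed) for s in specs}
        reports.append(
            CombinationReport(combo, per_model, average_metrics(per_model.values()))
        )
    return reports


def rank_combinations(
    reports: Sequence[CombinationReport],
    criterion: str,
    tolerance: float = 0.001,
) -> list[str]:
    """Combinations within *tolerance* of the best value of *criterion*.

    The tolerance band treats values reported to finite precision as ties.
    """
    if not reports:
        raise ValueError("no reports to rank")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    vals = {r.combination: r.averaged.as_dict()[criterion] for r in reports}
    defined = {k: v for k, v in vals.items() if v is not None}
    if not defined:
        return []
    best = max(defined.values())
    return [r.combination for r in reports if defined.get(r.combination, -np.inf) >= best - tolerance]


def select_best_combination(
    reports: Sequence[CombinationReport],
    tolerance: float = 0.001,
    criteria: Sequence[str] = CRITERIA,
) -> tuple[str, dict[str, list[str]]]:
    """Overall winner: the combination topping the most criteria.

    Returns the winner and the per-criterion best sets.  Ties are broken in
    favour of the larger combination, then lexicographically.
    """
    best_sets = {c: rank_combinations(reports, c, tolerance) for c in criteria}
    wins: dict[str, int] = {r.combination: 0 for r in reports}
    for combos in best_sets.values():
        for c in combos:
            wins[c] += 1
    winner = min(wins, key=lambda k: (-wins[k], -len(k), k))
    return winner, best_sets


def combination_table(reports: Sequence[CombinationReport]) -> pd.DataFrame:
    """Report list as a flat table (one row per combination)."""
    rows = []
    for i, r in enumerate(reports, start=1):
        row = {"no": i, "combination": r.combination}
        row.update(r.averaged.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison on a fixed combination


def compare_models(
    data: pd.DataFrame,
    combination: str = "ABCDEF",
    seed: int = 0,
    families: Sequence[str] = FAMILIES,
    hyperparams: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Per-family metrics on one combination plus the average-performance score.

    The average performance of a model is the mean of its five criteria;
    the row with the highest average performance is the selected model.
    """
    specs = [s for s in default_model_specs(seed, hyperparams) if s.family in set(families)]
    rows = []
    for s in specs:
        m = five_fold_cv(data, s, letters=combination, seed=seed)
        row = {"model": s.family}
        row.update(m.as_dict())
        row["average_performance"] = m.average_performance()
        rows.append(row)
    return pd.DataFrame(rows)


def best_model(comparison: pd.DataFrame) -> str:
    """Family with the highest average performance."""
    return str(comparison.loc[comparison["average_performance"].idxmax(), "model"])


# ---------------------------------------------------------------------------
# final model: training, persistence, prediction


def train_final(
    data: pd.DataFrame,
    spec: ModelSpec,
    combination: str = "ABCDEF",
    path: str | Path | None = None,
    config_hash: str = "",
) -> dict:
    """Fit *spec* on the full table and (optionally) persist the artifact.

    The artifact is a joblib bundle carrying the fitted estimator together
    with the combination, family, seed, config hash and a format version;
    loading re-checks the version so stale artifacts fail loudly.
    """
    X = _feature_matrix(data, combination)
    y = data["label"].to_numpy(dtype="U8")
    est = build_estimator(spec)
    est.fit(X, y)
    artifact = {
        "format_version": ARTIFACT_VERSION,
        "family": spec.family,
        "combination": combination,
        "seed": spec.seed,
        "hyperparams": dict(spec.hyperparams),
        "config_hash": config_hash,
        "estimator": est,
    }
    if path is not None:
        joblib.dump(artifact, path)
    return artifact


def load_artifact(path: str | Path) -> dict:
    artifact = joblib.load(path)
    version = artifact.get("format_version")
    if version != ARTIFACT_VERSION:
        raise ValueError(f"artifact version {version!r} not supported (expected {ARTIFACT_VERSION})")
    return artifact


def predict(artifact: dict, features: pd.DataFrame) -> pd.DataFrame:
    """Per-water label and positive-class score from a trained artifact.

    *features* must contain the artifact's feature columns; any NaN is an
    error (features are never imputed).
    """
    combination = artifact["combination"]
    X = _feature_matrix(features, combination)
    est = artifact["estimator"]
    out = features.copy()
    out["predicted_label"] = est.predict(X)
    out["score"] = positive_scores(est, X)
    return out
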