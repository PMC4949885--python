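"""Nested, repeated, stratified cross-validation and accuracy metrics.

One replicate = one label-noise draw + one 5-fold split of the samples. Per
outer fold, hyperparameters are tuned by an inner 5-fold cross-validation of
the training partition (noisy labels only — the truth is unavailable at
tuning time), the chosen model is refitted on the full training partition,
and the validation partition is scored against the ORIGINAL labels.

Folds are stratified by default: with only 24 negatives among 123 samples,
plain random 5-fold splits can produce validation folds without a negative,
leaving AUC undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import rng_for, seed_for
from .classifiers import default_grid, make_model
from .noise import flip_labels, minority_class_frequency

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "make_folds",
    "classification_metrics",
    "auc",
    "tune_hyperparameters",
    "run_replicate",
    "records_to_frame",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion matrix counts; positive = high vigor (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricRecord:
    """Per-fold evaluation outcome."""

    replicate: int
    fold: int
    p: float
    family: str
    params: dict
    tp: int
    fp: int
    tn: int
    fn: int
    ter: float
    fpr: float
    fnr: float
    tpr: float
    tnr: float
    auc: float
    n_val: int
    minority_freq: float  # realized original-minority frequency of the noisy labels


def make_folds(labels, k: int = 5, seed: int = 0, stratified: bool = True) -> np.ndarray:
    """Assign each sample a fold index in 0..k-1.

    Fold sizes differ by at most one; with stratification, class proportions
    per fold differ from the global proportions by at most one sample. A
    class smaller than k triggers a best-effort unstratified fallback with a
    warning.
    """
    y = np.asarray(labels)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            warnings.warn("a class has fewer members than folds; falling back to plain split")
            stratified = False
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=int(seed))
    )
    assign = np.empty(n, dtype=int)
    for f, (_, val_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assign[val_idx] = f
    return assign


def classification_metrics(c: ConfusionCounts) -> dict:
    """TER, FPR, FNR, TPR, TNR from confusion counts.

    TER = (FP+FN)/n; FNR = FN/(TP+FN); FPR = FP/(FP+TN); TPR = 1-FNR;
    TNR = 1-FPR. A rate with an empty denominator is NaN (flagged undefined).
    """
    if c.n == 0:
        raise ValueError("empty confusion counts")
    ter = (c.fp + c.fn) / c.n
    fnr = c.fn / (c.tp + c.fn) if (c.tp + c.fn) > 0 else np.nan
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else np.nan
    return {
        "ter": ter,
        "fpr": fpr,
        "fnr": fnr,
        "tpr": 1.0 - fnr if np.isfinite(fnr) else np.nan,
        "tnr": 1.0 - fpr if np.isfinite(fpr) else np.nan,
    }


def auc(y_true, scores) -> float:
    """Area under the ROC curve, Mann-Whitney form with mid-ranks for ties.

    Equals (concordant pairs + half the tied pairs) / (n_pos * n_neg), which
    is exactly the trapezoidal area under the ROC curve.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def tune_hyperparameters(
    X,
    y_noisy,
    family: str,
    grid: list[dict] | None = None,
    seed: int = 0,
    inner_k: int = 5,
    stratified: bool = True,
) -> dict:
    """Inner-CV grid search maximizing mean AUC on the noisy labels.

    The same inner folds are reused for every grid point. Ties break toward
    the grid point listed first (grids are ordered simplest-first). Inner
    folds whose validation part is single-class are skipped; if every fold is
    degenerate for all points, the grid midpoint is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    y_noisy = np.asarray(y_noisy)
    if grid is None:
        grid = default_grid(family, n_markers=X.shape[1])
    if not grid:
        raise ValueError("empty tuning grid")
    if len(grid) == 1:
        return grid[0]
    folds = make_folds(y_noisy, k=inner_k, seed=seed_for(seed, "inner-folds"), stratified=stratified)
    best_params, best_score = None, -np.inf
    for gi, params in enumerate(grid):
        scores = []
        for f in range(inner_k):
            tr, va = folds != f, folds == f
            if len(np.unique(y_noisy[va])) < 2 or len(np.unique(y_noisy[tr])) < 2:
                continue
            model = make_model(family, params, seed=seed_for(seed, "inner-fit", gi, f))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y_noisy[tr])
                scores.append(auc(y_noisy[va], model.decision_scores(X[va])))
        if scores and np.mean(scores) > best_score:
            best_score, best_params = float(np.mean(scores)), params
    if best_params is None:
        warnings.warn("all inner folds degenerate; falling back to the grid midpoint")
        best_params = grid[len(grid) // 2]
    return best_params


def run_replicate(
    X,
    y_true,
    family: str,
    p: float,
    seed: int,
    grid: list[dict] | None = None,
    k: int = 5,
    inner_k: int = 5,
    replicate_id: int = 0,
    stratified: bool = True,
    flip_scope: str = "global",
) -> list[MetricRecord]:
    """One replicate: flip labels, 5-fold CV with nested tuning, score vs truth.

    ``flip_scope='global'`` (default) injects noise once over the full sample
    before fold splitting; ``'per-fold'`` flips independently within each
    outer training partition instead, leaving validation labels untouched
    either way (predictions are always scored against the original labels).
    """
    X = np.asarray(X, dtype=float)
    y_true = np.asarray(y_true)
    if flip_scope not in ("global", "per-fold"):
        raise ValueError("flip_scope must be 'global' or 'per-fold'")
    if flip_scope == "global":
        y_noisy, _ = flip_labels(y_true, p, seed_for(seed, "flip"))
    folds = make_folds(y_true, k=k, seed=seed_for(seed, "outer-folds"), stratified=stratified)
    records = []
    for f in range(k):
        tr, va = folds != f, folds == f
        if flip_scope == "per-fold":
            y_noisy = y_true.copy()
            flipped_tr, _ = flip_labels(y_true[tr], p, seed_for(seed, "flip", f))
            y_noisy[tr] = flipped_tr
        try:
            params = tune_hyperparameters(
                X[tr], y_noisy[tr], family, grid=grid,
                seed=seed_for(seed, "tune", f), inner_k=inner_k, stratified=stratified,
            )
            model = make_model(family, params, seed=seed_for(seed, "fit", f))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y_noisy[tr])
            scores = model.decision_scores(X[va])
            preds = model.predict(X[va])
            counts = ConfusionCounts.from_predictions(y_true[va], preds)
            metrics = classification_metrics(counts)
            try:
                fold_auc = auc(y_true[va], scores)
            except ValueError:
                fold_auc = np.nan  # single-class validation fold; skipped in means
        except Exception as exc:
            raise RuntimeError(
                f"replicate {replicate_id}, fold {f}, family {family}, p={p}: {exc}"
            ) from exc
        records.append(
            MetricRecord(
                replicate=replicate_id,
                fold=f,
                p=float(p),
                family=family,
                params=params,
                tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn,
                ter=metrics["ter"], fpr=metrics["fpr"], fnr=metrics["fnr"],
                tpr=metrics["tpr"], tnr=metrics["tnr"],
                auc=fold_auc,
                n_val=counts.n,
                minority_freq=minority_class_frequency(y_true, y_noisy),
            )
        )
    return records


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["params"] = repr(sorted(d["params"].items()))
        rows.append(d)
    return pd.DataFrame(rows)


def aggregate(records, by=("family", "p")) -> pd.DataFrame:
    """Mean and SD of TER/FPR/FNR/AUC per (family, noise level) cell.

    NaN metrics (undefined rates on degenerate folds) are excluded from the
    cell means; ``n_records`` counts the fold-records entering each cell.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    metrics = ["ter", "fpr", "fnr", "tpr", "tnr", "auc"]
    grouped = df.groupby(list(by))
    out = grouped[metrics].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out["minority_freq"] = grouped["minority_freq"].mean()
    out["n_records"] = grouped.size()
    return out.reset_index()
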