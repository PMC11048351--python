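"""Predict miRNA localization from thresholded motif-strength features.

Each motif found significant in either enrichment direction becomes one
feature: the miRNA's best scaled match score, set to 0 when it falls below
that motif's optimal enrichment threshold. Random Forest (100 trees,
mtry = floor(log2 m) + 1, unlimited-depth Gini trees, hard votes) and
Gaussian Naive Bayes are evaluated under seeded stratified
k-fold cross-validation with pooled out-of-fold probabilities; ROC/AUC is
computed on the pooled predictions. The positive class is SEV_ENRICHED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_formats import MotifModel, SequenceSet
from .localization import LocalizationTable
from .motif_enrichment import (
    MotifEnrichmentResult,
    MotifScanResult,
    sea_enrich,
    scan,
    significant_motifs,
)

logger = logging.getLogger(__name__)

MODELS = ("random_forest", "naive_bayes")
POSITIVE_CLASS = "SEV_ENRICHED"
NEGATIVE_CLASS = "CELL_ENRICHED"


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """miRNA x motif matrix of thresholded match strengths plus binary label.

    Values lie in [0, 1]; a positive value is always >= the motif's
    enrichment threshold. Label 1 = SEV_ENRICHED. NEUTRAL miRNAs are
    excluded (binary classification only).
    """

    X: pd.DataFrame
    y: pd.Series
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and labels are misaligned")

    def to_tsv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, sep="\t", index_label="mirna_id")


def build_features(
    scans: Iterable[MotifScanResult],
    enriched: Iterable[MotifEnrichmentResult],
    calls: LocalizationTable,
    e_threshold: float = 0.05,
) -> FeatureMatrix:
    """Assemble the classifier input from scans, enrichment, and class calls.

    ``enriched`` should concatenate both enrichment directions; motifs
    significant in either become columns, ordered by (e_value, motif_id)
    with duplicates keeping their smaller E-value. Scores below a motif's
    optimal threshold are tagged as 0.
    """
    sig = significant_motifs(enriched, e_threshold)
    if not sig:
        raise ValueError(
            f"no motif is significant at E < {e_threshold}; "
            "relax the E-value threshold to build features"
        )
    best: dict[str, MotifEnrichmentResult] = {}
    for r in sig:
        if r.motif_id not in best or r.e_value < best[r.motif_id].e_value:
            best[r.motif_id] = r
    cols = sorted(best, key=lambda m: (best[m].e_value, m))

    rows = [
        m for m in calls.table.index
        if calls.table.at[m, "call"] in (POSITIVE_CLASS, NEGATIVE_CLASS)
    ]
    row_set = set(rows)
    X = pd.DataFrame(0.0, index=pd.Index(rows, name="mirna_id"), columns=cols)
    for s in scans:
        if not s.present or s.motif_id not in best or s.mirna_id not in row_set:
            continue
        if s.best_scaled >= best[s.motif_id].threshold:
            X.at[s.mirna_id, s.motif_id] = s.best_scaled
    y = pd.Series(
        (calls.table.loc[rows, "call"] == POSITIVE_CLASS).astype(int),
        index=X.index,
        name="label",
    )
    return FeatureMatrix(X, y, {m: best[m].threshold for m in cols})


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


def naive_bayes_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    var_floor: float = 1e-9,
) -> np.ndarray:
    """Gaussian Naive Bayes posterior P(positive | x).

    Class-conditional Gaussians per feature (maximum-likelihood mean and
    variance, variance floored at ``var_floor``); class priors are the
    training frequencies.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, int)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    log_joint = []
    for cls in (0, 1):
        Xc = X_train[y_train == cls]
        mu = Xc.mean(axis=0)
        var = np.maximum(Xc.var(axis=0), var_floor)
        ll = -0.5 * (np.log(2 * np.pi * var) + (X_test - mu) ** 2 / var).sum(axis=1)
        log_joint.append(np.log(Xc.shape[0] / X_train.shape[0]) + ll)
    a = np.stack(log_joint, axis=1)
    a -= a.max(axis=1, keepdims=True)
    num = np.exp(a)
    return num[:, 1] / num.sum(axis=1)


def random_forest_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    seed: int = 1,
) -> np.ndarray:
    """Random Forest probability of the positive class as the fraction of
    trees voting for it (bootstrap CART, Gini, unlimited depth)."""
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, int)
    if np.unique(y_train).size < 2:
        raise ValueError("training data contains a single class")
    m = X_train.shape[1]
    if mtry is None:
        mtry = int(np.floor(np.log2(m))) + 1 if m > 0 else 1
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=min(mtry, m),
        bootstrap=True,
        random_state=seed,
    )
    rf.fit(X_train, y_train)
    X_test = np.asarray(X_test, float)
    votes = np.stack([t.predict(X_test) for t in rf.estimators_])
    return votes.mean(axis=0)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_points(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) over all score thresholds; starts at (0,0),
    ends at (1,1), non-decreasing in both coordinates."""
    fpr, tpr, _ = roc_curve(np.asarray(y_true, int), np.asarray(scores, float),
                            drop_intermediate=False)
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def auc_score(y_true, scores) -> float:
    fpr, tpr = roc_points(y_true, scores)
    return auc_trapezoid(fpr, tpr)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Pooled out-of-fold evaluation of one classifier."""

    model: str
    mirna_ids: list[str]
    y_true: np.ndarray
    probabilities: np.ndarray  # pooled P(SEV | x), out of fold
    fold: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc_roc: float
    confusion: dict[str, int]  # tp/fp/tn/fn at probability 0.5

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model": self.model, "fpr": self.fpr, "tpr": self.tpr})


def _confusion_at_half(y: np.ndarray, p: np.ndarray) -> dict[str, int]:
    pred = p >= 0.5
    pos = y == 1
    return {
        "tp": int((pred & pos).sum()),
        "fp": int((pred & ~pos).sum()),
        "fn": int((~pred & pos).sum()),
        "tn": int((~pred & ~pos).sum()),
    }


def _fit_predict(model: str, X_tr, y_tr, X_te, seed: int) -> np.ndarray:
    if model == "random_forest":
        return random_forest_fit_predict(X_tr, y_tr, X_te, seed=seed)
    if model == "naive_bayes":
        return naive_bayes_fit_predict(X_tr, y_tr, X_te)
    raise ValueError(f"unknown model {model!r}; available: {MODELS}")


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"cannot stratify: minority class has {counts.min()} member(s)"
        )
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        logger.warning("reducing folds from %d to %d to keep both classes "
                       "in every fold", k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fold = np.empty(y.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        fold[test_idx] = f
    return fold


def cross_validate(
    features: FeatureMatrix,
    k: int = 10,
    seed: int = 1,
    models: Sequence[str] = MODELS,
) -> dict[str, CVReport]:
    """Seeded stratified k-fold CV with pooled out-of-fold probabilities."""
    X = features.X.to_numpy(float)
    y = features.y.to_numpy(int)
    fold = _stratified_folds(y, k, seed)
    reports = {}
    for model in models:
        prob = np.empty(y.size)
        for f in np.unique(fold):
            te = fold == f
            prob[te] = _fit_predict(model, X[~te], y[~te], X[te], seed=seed + f)
        fpr, tpr = roc_points(y, prob)
        reports[model] = CVReport(
            model=model,
            mirna_ids=list(features.X.index),
            y_true=y,
            probabilities=prob,
            fold=fold,
            fpr=fpr,
            tpr=tpr,
            auc_roc=auc_trapezoid(fpr, tpr),
            confusion=_confusion_at_half(y, prob),
        )
    return reports


def cross_validate_nested(
    calls: LocalizationTable,
    seqs: SequenceSet,
    motifs: Sequence[MotifModel],
    k: int = 10,
    seed: int = 1,
    models: Sequence[str] = MODELS,
    e_threshold: float = 0.05,
    holdout_frac: float = 0.10,
) -> dict[str, CVReport]:
    """Leakage-free variant: motif enrichment and thresholds are recomputed
    inside each training fold before features are built.

    The standard :func:`cross_validate` mode selects significant motifs on
    the full labeled set first (as the original analysis did), which leaks
    label information into feature selection; this mode quantifies that
    optimism and is expected to score no higher on average.
    """
    ids = [
        m for m in calls.table.index
        if calls.table.at[m, "call"] in (POSITIVE_CLASS, NEGATIVE_CLASS)
        and m in seqs.records
    ]
    y = np.array(
        [int(calls.table.at[m, "call"] == POSITIVE_CLASS) for m in ids]
    )
    fold = _stratified_folds(y, k, seed)
    all_scans = [r for motif in motifs for r in scan(seqs.subset(ids), motif)]
    prob = {model: np.empty(y.size) for model in models}
    for f in np.unique(fold):
        te = fold == f
        train_ids = [m for m, t in zip(ids, te) if not t]
        test_ids = [m for m, t in zip(ids, te) if t]
        pos_tr = seqs.subset([m for m in train_ids
                              if calls.table.at[m, "call"] == POSITIVE_CLASS])
        bg_tr = seqs.subset([m for m in train_ids
                             if calls.table.at[m, "call"] == NEGATIVE_CLASS])
        enr = sea_enrich(pos_tr, bg_tr, motifs, holdout_frac, seed=seed) + \
            sea_enrich(bg_tr, pos_tr, motifs, holdout_frac, seed=seed)
        try:
            fm = build_features(all_scans, enr, calls, e_threshold)
        except ValueError:
            # no motif survives selection in this fold: predict the prior
            prior = y[~te].mean()
            for model in models:
                prob[model][te] = prior
            continue
        X_tr = fm.X.reindex(train_ids, fill_value=0.0).to_numpy(float)
        X_te = fm.X.reindex(test_ids, fill_value=0.0).to_numpy(float)
        y_tr = y[~te]
        for model in models:
            prob[model][te] = _fit_predict(model, X_tr, y_tr, X_te, seed=seed + f)
    reports = {}
    for model in models:
        fpr, tpr = roc_points(y, prob[model])
        reports[model] = CVReport(
            model=model,
            mirna_ids=ids,
            y_true=y,
            probabilities=prob[model],
            fold=fold,
            fpr=fpr,
            tpr=tpr,
            auc_roc=auc_trapezoid(fpr, tpr),
            confusion=_confusion_at_half(y, prob[model]),
        )
    return reports


def write_cv_reports(reports: dict[str, CVReport], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    pd.concat([r.roc_frame() for r in reports.values()]).to_csv(
        out_dir / "roc_points.tsv", sep="\t", index=False
    )
    rows = []
    for r in reports.values():
        rows.append({"model": r.model, "auc_roc": r.auc_roc, "n": len(r.y_true),
                     **r.confusion})
    pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
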