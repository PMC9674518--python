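"""Benign-vs-malignant differential expression and diagnostic signatures.

The signature builder mirrors common clinical-biomarker practice: a
stratified 80/20 train/test split, recursive feature elimination (RFE) over
an L2-regularized logistic regression, subset scoring by stratified
cross-validated AUC averaged over several fold counts, the one-standard-
error rule to pick the smallest competitive panel, and a final comparison
of five classifier families (LR, SVM, NB, RF, KNN) by ROC/AUC on the
held-out split.  Test samples never influence standardization, feature
elimination or model fitting.

Differential expression uses the Wilcoxon rank-sum test per gene with
log2 fold-change computed as log2((mean_PTC + 1) / (mean_BTN + 1)) on the
linear scale; the "changed" flag is the literal disjunction p < 0.05 or
|log2FC| > 1 (an ``require_both`` flag switches to the conjunction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, rng_for

logger = logging.getLogger("thyrotype")

__all__ = [
    "SignatureModel",
    "differential_expression",
    "stratified_split",
    "rfe_signature",
    "evaluate_classifiers",
    "CLASSIFIERS",
]

POSITIVE_CLASS = "PTC"


# ---------------------------------------------------------------------------
# Differential expression


def differential_expression(
    m: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    fc_cutoff: float = 1.0,
    require_both: bool = False,
) -> pd.DataFrame:
    """Per-gene PTC-vs-BTN Wilcoxon rank-sum with fold-change flagging.

    ``labels`` maps sample -> {PTC, BTN}.  Returns one row per gene with
    log2 fold-change, two-sided p, BH q, direction ('up' = higher in PTC)
    and the 'changed' flag (p < alpha or |log2FC| > fc_cutoff by default;
    the conjunction when ``require_both``).
    """
    labels = labels.loc[m.samples]
    classes = set(labels.unique())
    if not {"PTC", "BTN"} <= classes:
        raise ValueError(f"labels must contain both PTC and BTN, got {sorted(classes)}")
    ptc = labels == "PTC"
    if ptc.sum() < 3 or (~ptc).sum() < 3:
        raise ValueError("need >= 3 samples per class")
    values = m.values
    x = values[:, ptc.to_numpy()]
    y = values[:, (~ptc).to_numpy()]

    log2fc = np.log2((x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.array([len(np.unique(values[i])) == 1 for i in range(values.shape[0])])
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    changed = (
        (p < alpha) & (np.abs(log2fc) > fc_cutoff)
        if require_both
        else (p < alpha) | (np.abs(log2fc) > fc_cutoff)
    )
    return pd.DataFrame(
        {
            "gene": m.genes,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "changed": changed,
        }
    ).set_index("gene", drop=False)


# ---------------------------------------------------------------------------
# Stratified split


def stratified_split(
    samples: list[str],
    labels: pd.Series,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Per-class random partition preserving the class ratio.

    The test side gets round(n_class * fraction) samples per class, at
    least 1 and at most n_class - 1.  Disjoint and exhaustive by
    construction; deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = rng_for(seed, "stratified_split")
    labels = labels.loc[list(samples)]
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        members = [s for s in samples if labels[s] == cls]
        if len(members) < 5:
            raise ValueError(f"class {cls!r} has fewer than 5 samples")
        n_test = int(np.clip(round(len(members) * test_fraction), 1, len(members) - 1))
        order = rng.permutation(len(members))
        test.extend(members[i] for i in sorted(order[:n_test]))
        train.extend(members[i] for i in sorted(order[n_test:]))
    return sorted(train, key=samples.index), sorted(test, key=samples.index)


# ---------------------------------------------------------------------------
# RFE signature


@dataclass
class SignatureModel:
    """A fitted diagnostic gene panel."""

    panel: list[str]
    coefficients: pd.Series  # per panel gene, final LR fit
    intercept: float
    scaler_mean: pd.Series
    scaler_sd: pd.Series
    cv_path: pd.DataFrame  # subset size, mean CV AUC, standard error
    folds: tuple[int, ...]
    seed: int
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, m: ExpressionMatrix) -> pd.Series:
        x = self._standardize(m)
        z = x @ self.coefficients.to_numpy() + self.intercept
        return pd.Series(z, index=m.samples, name="score")

    def _standardize(self, m: ExpressionMatrix) -> np.ndarray:
        data = m.data.loc[self.panel]
        z = data.sub(self.scaler_mean.loc[self.panel], axis=0).div(
            self.scaler_sd.loc[self.panel], axis=0
        )
        return z.T.to_numpy()


def _cv_aucs(
    x: np.ndarray, y: np.ndarray, folds: tuple[int, ...], seed: int
) -> list[float]:
    """Stratified k-fold LR AUCs pooled over every fold count in ``folds``."""
    aucs: list[float] = []
    for k in folds:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + k)
        for train_idx, val_idx in splitter.split(x, y):
            if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
                logger.warning("single-class fold skipped (k=%d)", k)
                continue
            clf = LogisticRegression(max_iter=2000)
            clf.fit(x[train_idx], y[train_idx])
            aucs.append(roc_auc_score(y[val_idx], clf.decision_function(x[val_idx])))
    return aucs


def rfe_signature(
    train: ExpressionMatrix,
    labels: pd.Series,
    candidates: list[str],
    folds: tuple[int, ...] = (4, 6, 8, 10),
    seed: int = 0,
    panel_size: int | None = None,
) -> SignatureModel:
    """Recursive feature elimination over logistic regression.

    Features (candidate genes) are standardized with training statistics
    only.  At each subset size the pooled stratified-CV AUC over every fold
    count is recorded; the feature with the smallest |coefficient| is then
    dropped (10% of features at a time while more than 100 remain).  The
    selected panel is the smallest subset whose mean CV AUC is within one
    standard error of the best mean ("one-SE rule"); ``panel_size`` forces
    an exact size instead.  The final model is an L2 logistic regression
    refit on the full training set with the selected panel.
    """
    present = [g for g in candidates if g in train.data.index]
    if len(present) < 2:
        raise ValueError("need at least 2 candidate genes present in the training matrix")
    if len(present) < len(candidates):
        logger.warning("rfe_signature: %d candidate genes missing", len(candidates) - len(present))
    y = (labels.loc[train.samples] == POSITIVE_CLASS).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("both classes need >= 2 training samples")

    data = train.data.loc[present]
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1).replace(0.0, 1.0)
    z_all = data.sub(mu, axis=0).div(sd, axis=0)

    seed_int = int(rng_for(seed, "rfe_signature").integers(2**31))
    active = list(present)
    path: list[dict] = []
    subsets: dict[int, list[str]] = {}
    while True:
        x = z_all.loc[active].T.to_numpy()
        aucs = _cv_aucs(x, y, folds, seed_int)
        path.append(
            {
                "size": len(active),
                "mean_auc": float(np.mean(aucs)),
                "se_auc": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))),
            }
        )
        subsets[len(active)] = list(active)
        if len(active) == 1:
            break
        clf = LogisticRegression(max_iter=2000)
        clf.fit(x, y)
        coef = np.abs(clf.coef_[0])
        n_drop = max(1, len(active) // 10) if len(active) > 100 else 1
        drop_idx = np.argsort(coef, kind="mergesort")[:n_drop]
        active = [g for i, g in enumerate(active) if i not in set(drop_idx)]

    cv_path = pd.DataFrame(path)
    if panel_size is not None:
        if panel_size not in subsets:
            raise ValueError(f"no RFE subset of size {panel_size} on the elimination path")
        chosen = panel_size
    else:
        best = cv_path.loc[cv_path["mean_auc"].idxmax()]
        threshold = best["mean_auc"] - best["se_auc"]
        eligible = cv_path[cv_path["mean_auc"] >= threshold]
        chosen = int(eligible["size"].min())
    panel = sorted(subsets[chosen])

    x_final = z_all.loc[panel].T.to_numpy()
    final = LogisticRegression(max_iter=2000)
    final.fit(x_final, y)
    return SignatureModel(
        panel=panel,
        coefficients=pd.Series(final.coef_[0], index=panel),
        intercept=float(final.intercept_[0]),
        scaler_mean=mu,
        scaler_sd=sd,
        cv_path=cv_path,
        folds=tuple(folds),
        seed=seed,
        metadata={"n_candidates": len(present), "chosen_size": chosen},
    )


# ---------------------------------------------------------------------------
# Multi-classifier evaluation


def _make_classifier(name: str, seed: int):
    if name == "LR":
        return LogisticRegression(max_iter=2000)
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier {name!r}")


CLASSIFIERS = ("LR", "SVM", "NB", "RF", "KNN")


def _scores(clf, x: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(x)
    return clf.predict_proba(x)[:, 1]


def evaluate_classifiers(
    model: SignatureModel,
    train: ExpressionMatrix,
    train_labels: pd.Series,
    test: ExpressionMatrix,
    test_labels: pd.Series,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    seed: int = 0,
) -> dict[str, dict]:
    """Train each classifier on the panel and report CV + held-out ROC/AUC.

    All features are standardized by training statistics.  Per classifier:
    pooled stratified-CV AUC on the training split (over the model's fold
    list) and a held-out ROC curve with trapezoidal AUC.
    """
    missing = [g for g in model.panel if g not in test.data.index]
    if missing:
        raise ValueError(f"panel genes absent from test matrix: {missing[:5]}")
    x_train = model._standardize(train)
    x_test = model._standardize(test)
    y_train = (train_labels.loc[train.samples] == POSITIVE_CLASS).to_numpy()
    y_test = (test_labels.loc[test.samples] == POSITIVE_CLASS).to_numpy()
    seed_int = int(rng_for(seed, "evaluate_classifiers").integers(2**31))

    results: dict[str, dict] = {}
    for name in classifiers:
        cv_aucs: list[float] = []
        for k in model.folds:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed_int + k)
            for tr, va in splitter.split(x_train, y_train):
                if len(np.unique(y_train[va])) < 2 or len(np.unique(y_train[tr])) < 2:
                    continue
                clf = _make_classifier(name, seed_int)
                clf.fit(x_train[tr], y_train[tr])
                cv_aucs.append(roc_auc_score(y_train[va], _scores(clf, x_train[va])))
        clf = _make_classifier(name, seed_int)
        clf.fit(x_train, y_train)
        score = _scores(clf, x_test)
        fpr, tpr, thresholds = roc_curve(y_test, score)
        results[name] = {
            "train_cv_auc": float(np.mean(cv_aucs)),
            "test_auc": float(_trapezoid_auc(fpr, tpr)),
            "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        }
    return results
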