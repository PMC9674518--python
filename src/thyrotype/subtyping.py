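"""Molecular subtype discovery and transfer.

Pipeline: filter genes on the linear RPKM scale (low-expression and
low-variability rules), log2-transform, run consensus non-negative matrix
factorization (NMF) at a fixed rank, rank per-factor exemplar genes by their
loading margin, select per-subtype marker genes with a permutation-tested
one-vs-rest random-forest importance, and transfer the subtypes to a new
cohort with Nearest Template Prediction (NTP).

NMF uses Lee-Seung multiplicative updates on the Frobenius objective; each
restart hard-assigns samples by the argmax of their column of H, and the
consensus matrix is the co-assignment frequency over restarts.  Stability is
summarized by the cophenetic correlation of the consensus dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, rng_for

logger = logging.getLogger("thyrotype")

__all__ = [
    "FilteredMatrix",
    "NMFResult",
    "SubtypeModel",
    "filter_genes",
    "nmf_multiplicative",
    "fit_consensus_nmf",
    "rank_exemplar_genes",
    "select_markers",
    "ntp_classify",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Gene filtering


@dataclass
class FilteredMatrix:
    """Expression matrix restricted to genes passing both filter rules."""

    matrix: ExpressionMatrix
    n_input_genes: int
    n_removed_low_expression: int
    n_removed_low_cv: int

    @property
    def n_retained(self) -> int:
        return self.matrix.shape[0]


def filter_genes(
    m: ExpressionMatrix,
    low_expr_threshold: float = 1.0,
    cv_threshold: float = 0.8,
) -> FilteredMatrix:
    """Remove uninformative genes before unsupervised clustering.

    Rule 1 removes genes expressed at low levels (RPKM < ``low_expr_threshold``)
    in strictly more than half of the samples.  Rule 2 removes genes whose
    coefficient of variation (sample sd / mean, linear scale) is below
    ``cv_threshold``; a zero-mean gene has an undefined CV and is removed.
    Rules are applied in that order, so a gene failing both is counted under
    rule 1.
    """
    values = m.values
    n_samples = values.shape[1]
    low = (values < low_expr_threshold).sum(axis=1) > n_samples / 2

    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if n_samples > 1 else np.zeros(len(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    low_cv = ~low & (np.isnan(cv) | (cv < cv_threshold))
    if np.isnan(cv[~low]).any():
        logger.warning("filter_genes: removed %d zero-mean genes (CV undefined)", int(np.isnan(cv[~low]).sum()))

    keep = ~low & ~low_cv
    retained = ExpressionMatrix(m.data.loc[keep].copy())
    return FilteredMatrix(
        matrix=retained,
        n_input_genes=m.shape[0],
        n_removed_low_expression=int(low.sum()),
        n_removed_low_cv=int(low_cv.sum()),
    )


# ---------------------------------------------------------------------------
# Consensus NMF


def nmf_multiplicative(
    v: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One NMF fit by Lee-Seung multiplicative updates (Frobenius objective).

    Initialization is uniform random scaled so the initial product matches
    the matrix mean.  Returns (W, H, per-iteration objective values); the
    objective ||V - WH||_F is non-increasing across iterations, a property
    the test suite asserts iteration by iteration.
    """
    if (v < 0).any():
        raise ValueError("NMF input must be non-negative")
    n, p = v.shape
    if k > min(n, p):
        raise ValueError(f"rank k={k} exceeds min(genes, samples)={min(n, p)}")
    scale = np.sqrt(max(v.mean(), _EPS) / k)
    w = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    h = rng.uniform(0.0, 1.0, size=(k, p)) * scale + _EPS

    objectives: list[float] = []
    prev = None
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + _EPS)
        w *= (v @ h.T) / (w @ (h @ h.T) + _EPS)
        obj = float(np.linalg.norm(v - w @ h))
        objectives.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj
    else:
        logger.warning("NMF did not converge within %d iterations; best iterate returned", max_iter)
    return w, h, objectives


@dataclass
class NMFResult:
    """Consensus NMF output for one rank."""

    w: pd.DataFrame  # genes x factors, best restart
    h: pd.DataFrame  # factors x samples, best restart
    k: int
    objectives: list[float]  # final objective per restart
    consensus: pd.DataFrame  # samples x samples co-assignment frequency
    cophenetic: float
    assignments: pd.Series = field(default=None)  # sample -> factor index (argmax H)
    consensus_clusters: pd.Series = field(default=None)  # hierarchical cut at k


def fit_consensus_nmf(
    fm: ExpressionMatrix,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFResult:
    """Consensus NMF over random restarts on a log2-transformed matrix.

    Per restart, samples are hard-assigned by argmax over their H column;
    the consensus matrix is the mean co-assignment indicator.  The reported
    W/H come from the restart with the lowest final objective.  The
    cophenetic correlation is computed from the average-linkage dendrogram
    of (1 - consensus), and ``consensus_clusters`` cuts that dendrogram at k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    v = fm.values
    samples = fm.samples
    n_samples = len(samples)
    rng = rng_for(seed, "fit_consensus_nmf")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    finals: list[float] = []
    co = np.zeros((n_samples, n_samples))
    for _ in range(restarts):
        w, h, objectives = nmf_multiplicative(v, k, rng, max_iter=max_iter, tol=tol)
        finals.append(objectives[-1])
        labels = h.argmax(axis=0)
        co += (labels[:, None] == labels[None, :]).astype(float)
        if best is None or objectives[-1] < best[0]:
            best = (objectives[-1], w, h)
    consensus = co / restarts
    np.fill_diagonal(consensus, 1.0)

    if n_samples > 2 and not np.allclose(consensus, consensus[0, 0]):
        dist = squareform(1.0 - consensus, checks=False)
        linkage = average(dist)
        if dist.max() > 0:
            coph, _ = cophenet(linkage, dist)
            coph = float(coph)
        else:
            coph = 1.0
        clusters = pd.Series(fcluster(linkage, k, criterion="maxclust"), index=samples)
    else:
        coph = 1.0
        clusters = pd.Series(np.ones(n_samples, dtype=int), index=samples)

    _, w, h = best
    factor_names = [f"F{i + 1}" for i in range(k)]
    return NMFResult(
        w=pd.DataFrame(w, index=fm.genes, columns=factor_names),
        h=pd.DataFrame(h, index=factor_names, columns=samples),
        k=k,
        objectives=finals,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cophenetic=coph,
        assignments=pd.Series(h.argmax(axis=0), index=samples, name="factor"),
        consensus_clusters=clusters,
    )


def rank_exemplar_genes(nmf: NMFResult, factor: int) -> pd.DataFrame:
    """Rank genes by their loading margin for one factor.

    score(g, i) = W[g, i] - max over j != i of W[g, j]; genes sorted in
    descending score, ties broken by gene symbol.  A gene with a large
    positive margin loads on this factor and on no other — an "exemplar".
    """
    if nmf.k < 2:
        raise ValueError("exemplar ranking needs k >= 2 (no 'other factor' at k=1)")
    if not 0 <= factor < nmf.k:
        raise ValueError(f"factor index {factor} out of range for k={nmf.k}")
    w = nmf.w.to_numpy()
    others = np.delete(w, factor, axis=1).max(axis=1)
    score = w[:, factor] - others
    out = pd.DataFrame({"gene": nmf.w.index, "score": score})
    out = out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Marker selection (one-vs-rest ensemble with OOB permutation importance)


def _fit_forest(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_trees: int
) -> tuple[list[DecisionTreeClassifier], list[np.ndarray]]:
    n = x.shape[0]
    trees, oobs = [], []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(x[boot], y[boot])
        trees.append(tree)
        oobs.append(oob)
    return trees, oobs


def _oob_permutation_importance(
    x: np.ndarray,
    y: np.ndarray,
    trees: list[DecisionTreeClassifier],
    oobs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean decrease in out-of-bag accuracy when one feature is permuted."""
    n, p = x.shape
    importance = np.zeros(p)
    used = 0
    for tree, oob in zip(trees, oobs):
        if len(oob) < 2:
            continue
        x_oob = x[oob]
        y_oob = y[oob]
        base = float((tree.predict(x_oob) == y_oob).mean())
        perm = rng.permutation(len(oob))
        # stack the p single-feature-permuted copies into one predict call
        stacked = np.repeat(x_oob[None, :, :], p, axis=0)
        for j in range(p):
            stacked[j, :, j] = x_oob[perm, j]
        preds = tree.predict(stacked.reshape(p * len(oob), p)).reshape(p, len(oob))
        importance += base - (preds == y_oob[None, :]).mean(axis=1)
        used += 1
    if used == 0:
        return np.zeros(p)
    return importance / used


def select_markers(
    fm: ExpressionMatrix,
    labels: pd.Series,
    subtype: str,
    exemplar_genes: list[str],
    n_permutations: int = 100,
    seed: int = 0,
    n_trees: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-tested one-vs-rest marker selection for one subtype.

    A bootstrap ensemble of decision trees is trained to separate the
    subtype's samples from the rest using the exemplar genes as features.
    Observed importance is the mean decrease in out-of-bag accuracy when the
    feature is permuted; the null distribution per feature comes from
    refitting the ensemble under ``n_permutations`` label permutations.
    p = (1 + #null >= observed) / (1 + n_permutations), Benjamini-Hochberg
    adjusted across features; markers are features with adjusted p < alpha.
    """
    present = [g for g in exemplar_genes if g in fm.data.index]
    if len(present) < len(exemplar_genes):
        logger.warning(
            "select_markers(%s): %d exemplar genes missing from matrix",
            subtype,
            len(exemplar_genes) - len(present),
        )
    labels = labels.loc[fm.samples]
    y = (labels == subtype).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(f"subtype {subtype!r} needs >= 2 samples in and out of class")
    x = fm.data.loc[present].to_numpy().T  # samples x features

    rng = rng_for(seed, f"select_markers:{subtype}")
    trees, oobs = _fit_forest(x, y, rng, n_trees)
    observed = _oob_permutation_importance(x, y, trees, oobs, rng)

    null = np.empty((n_permutations, len(present)))
    for r in range(n_permutations):
        y_perm = rng.permutation(y)
        trees_r, oobs_r = _fit_forest(x, y_perm, rng, n_trees)
        null[r] = _oob_permutation_importance(x, y_perm, trees_r, oobs_r, rng)

    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_permutations)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": present,
            "importance": observed,
            "p_value": p,
            "q_value": q,
            "selected": q < alpha,
        }
    )
    return out.sort_values(["q_value", "gene"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nearest Template Prediction


def ntp_classify(
    cohort: ExpressionMatrix,
    markers: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify a new cohort against per-subtype marker templates.

    The sample vector is restricted to the union of markers and standardized
    per gene using the new cohort's own means and sds (no training-cohort
    statistics leak, preserving NTP's cross-platform intent).  The template
    for subtype s is the unit-normalized indicator of s's markers on the
    union; distance is 1 - cosine similarity, and a sample is assigned to
    the nearest template.  Significance: each permutation redraws all marker
    sets (same sizes) from the measured genes and recomputes the distance to
    the predicted subtype's random template; p = (1 + #perm <= observed) /
    (1 + n_permutations), Benjamini-Hochberg adjusted across samples.
    """
    subtypes = sorted(markers)
    present: dict[str, list[str]] = {}
    for s in subtypes:
        found = [g for g in markers[s] if g in cohort.data.index]
        if not found:
            raise ValueError(f"all markers missing from cohort for subtype {s!r}")
        if len(found) < len(markers[s]):
            logger.warning(
                "ntp_classify: dropped %d missing markers for %s",
                len(markers[s]) - len(found),
                s,
            )
        present[s] = found

    # per-gene standardization over the whole cohort
    data = cohort.data
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = data.sub(mu, axis=0).div(sd, axis=0)

    union = sorted(set(g for genes in present.values() for g in genes))
    z_union = z.loc[union].to_numpy()  # genes x samples
    templates = np.zeros((len(subtypes), len(union)))
    gene_pos = {g: i for i, g in enumerate(union)}
    for si, s in enumerate(subtypes):
        for g in present[s]:
            templates[si, gene_pos[g]] = 1.0
        templates[si] /= np.linalg.norm(templates[si])

    def _distances(z_sub: np.ndarray, tmpl: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(z_sub, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        cos = (tmpl @ z_sub) / norms[None, :]
        return 1.0 - cos  # subtypes x samples

    dist = _distances(z_union, templates)
    pred_idx = dist.argmin(axis=0)  # ties -> first (subtype name order)
    sorted_d = np.sort(dist, axis=0)
    low_conf = np.isclose(sorted_d[0], sorted_d[1]) if len(subtypes) > 1 else np.zeros(
        dist.shape[1], dtype=bool
    )
    observed = dist[pred_idx, np.arange(dist.shape[1])]

    rng = rng_for(seed, "ntp_classify")
    all_genes = np.array(cohort.genes)
    z_all = z.to_numpy()
    sizes = [len(present[s]) for s in subtypes]
    count_le = np.zeros(dist.shape[1])
    for _ in range(n_permutations):
        order = rng.permutation(len(all_genes))
        rand_sets, start = [], 0
        for size in sizes:
            rand_sets.append(order[start : start + size])
            start += size
        rand_union = np.concatenate(rand_sets)
        z_sub = z_all[rand_union]
        tmpl = np.zeros((len(subtypes), len(rand_union)))
        pos = 0
        for si, size in enumerate(sizes):
            tmpl[si, pos : pos + size] = 1.0
            tmpl[si] /= np.linalg.norm(tmpl[si])
            pos += size
        d_rand = _distances(z_sub, tmpl)
        count_le += d_rand[pred_idx, np.arange(dist.shape[1])] <= observed

    p = (1.0 + count_le) / (1.0 + n_permutations)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    out = pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "predicted": [subtypes[i] for i in pred_idx],
            "p_value": p,
            "q_value": q,
            "low_confidence": low_conf,
        }
    )
    for si, s in enumerate(subtypes):
        out[f"distance_{s}"] = dist[si]
    return out.set_index("sample_id", drop=False)
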