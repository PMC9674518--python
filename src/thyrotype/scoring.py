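"""Per-sample scores and group-comparison statistics.

Scores:

* **TDS** (thyroid differentiation score): for each thyroid-function gene,
  log2(RPKM + 1) is centered by its median across samples, and the centered
  values are summed per sample.  High TDS = well-differentiated.
* **Single-sample gene-set enrichment** (ssGSEA-style): per sample, genes are
  ranked by expression and the score accumulates the difference between the
  rank-weighted empirical CDF of in-set genes and the uniform CDF of out-set
  genes.  Positive score = set members concentrated at high expression.  The
  immune, stromal and T-cell-inflamed GEP scores are this statistic applied
  to the respective gene sets; they are used ordinally (higher = more
  active/infiltrated).
* **Group comparisons**: Wilcoxon rank-sum (exact enumeration for small
  tie-free groups, normal approximation with tie correction otherwise) and
  Pearson chi-square independence tests, both two-sided.

All scores are deterministic given their inputs; no RNG is involved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneSetCollection, log2_transform

logger = logging.getLogger("thyrotype")

__all__ = [
    "tds",
    "ssgsea_score",
    "immune_stromal_gep_scores",
    "compare_groups",
]


def tds(m: ExpressionMatrix, tds_genes: list[str], pseudocount: float = 1.0) -> pd.Series:
    """Thyroid differentiation score per sample.

    Per gene g in the set: c[g, s] = log2(RPKM+1)[g, s] - median over samples
    of log2(RPKM+1)[g, .]; TDS(s) = sum over g of c[g, s].  Missing genes are
    dropped with a warning; an empty overlap is an error.
    """
    present = [g for g in tds_genes if g in m.data.index]
    if not present:
        raise ValueError("no TDS genes present in the expression matrix")
    if len(present) < len(tds_genes):
        logger.warning("tds: %d of %d genes missing", len(tds_genes) - len(present), len(tds_genes))
    log2m = log2_transform(m, pseudocount).data.loc[present]
    centered = log2m.sub(log2m.median(axis=1), axis=0)
    return centered.sum(axis=0).rename("TDS")


def _single_sample_es(order: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Accumulated weighted-CDF difference for one sample.

    ``order`` gives gene indices sorted by descending expression; ``in_set``
    flags set membership per gene.  The in-set CDF weights position j
    (1-based from the top) by (N - j + 1)**tau; the out-set CDF is uniform.
    The score is the mean of (CDF_in - CDF_out) over the ranked list, so it
    lies in (-1, 1) and equals zero in expectation for random placement.
    """
    n = len(order)
    hits = in_set[order]
    n_in = int(hits.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a proper non-empty subset of measured genes")
    rank_weight = (n - np.arange(n)).astype(float) ** tau
    w_in = np.where(hits, rank_weight, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~hits) / (n - n_in)
    return float(np.mean(cdf_in - cdf_out))


def ssgsea_score(
    m: ExpressionMatrix, gene_set: list[str], tau: float = 0.25
) -> pd.Series:
    """Single-sample enrichment score of one gene set for every sample.

    Within each sample, genes are ranked by expression (descending; ties
    broken by gene order for determinism).  See :func:`_single_sample_es`
    for the statistic.  At tau = 0 the score is purely rank-based and is
    invariant under any strictly monotone transform of the sample's values.
    """
    in_set = np.isin(np.array(m.genes), list(dict.fromkeys(gene_set)))
    if not in_set.any():
        raise ValueError("gene set has no overlap with measured genes")
    values = m.values
    scores = {}
    gene_rank = np.arange(values.shape[0])
    for j, sample in enumerate(m.samples):
        # stable descending sort: primary key -value, tiebreak original order
        order = np.lexsort((gene_rank, -values[:, j]))
        scores[sample] = _single_sample_es(order, in_set, tau)
    return pd.Series(scores, name="ssgsea")


def immune_stromal_gep_scores(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    immune_set: str = "IMMUNE",
    stromal_set: str = "STROMAL",
    gep_set: str = "GEP",
    tau: float = 0.25,
) -> pd.DataFrame:
    """Immune, stromal and T-cell-inflamed GEP scores per sample.

    Each is the single-sample enrichment score of the corresponding set in
    ``collection``.  A higher immune score corresponds to more active
    immunological effects (orientation follows directly from the statistic:
    set members at high expression push the score up).
    """
    out = {}
    for column, name in (("immune", immune_set), ("stromal", stromal_set), ("gep", gep_set)):
        if name not in collection:
            raise ValueError(f"gene set {name!r} not found in collection")
        out[column] = ssgsea_score(m, collection[name], tau=tau)
    return pd.DataFrame(out)


def compare_groups(
    values: pd.Series | np.ndarray,
    grouping: pd.Series | np.ndarray,
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Two-sided group comparison used throughout the reporting layer.

    ``wilcoxon``: rank-sum test between exactly two groups; exact
    enumeration when both groups have <= 10 tie-free observations, normal
    approximation with tie correction otherwise.  Returns the rank-sum
    statistic of the first group (by sorted group label) and the p-value.

    ``chi_square``: ``values`` and ``grouping`` are two categorical vectors
    (or ``values`` is already a 2-D contingency table and ``grouping`` is
    ignored); Pearson chi-square, df = (r-1)(c-1), no continuity correction.
    """
    if test == "chi_square" and np.ndim(values) == 2:
        table = np.asarray(values)
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("chi_square needs at least a 2x2 contingency table")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    values = np.asarray(pd.Series(values))
    grouping = np.asarray(pd.Series(grouping))
    if test == "wilcoxon":
        groups = np.unique(grouping)
        if len(groups) != 2:
            raise ValueError(f"wilcoxon needs exactly 2 groups, got {len(groups)}")
        x = values[grouping == groups[0]].astype(float)
        y = values[grouping == groups[1]].astype(float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("both groups must be non-empty")
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        rank_sum = float(res.statistic + len(x) * (len(x) + 1) / 2)
        return rank_sum, float(min(res.pvalue, 1.0))
    if test == "chi_square":
        table = pd.crosstab(pd.Series(values), pd.Series(grouping)).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError("chi_square needs at least a 2x2 contingency table")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    raise ValueError(f"unknown test {test!r}")
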