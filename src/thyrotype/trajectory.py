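"""Pseudotemporal trajectory inference and branch-dependent expression.

Samples are embedded in two principal components, summarized by k-means
centroids, and connected by a Euclidean minimum spanning tree (MST).  Each
sample is projected onto its nearest tree edge; pseudotime is the geodesic
distance along the tree from the root node (the centroid nearest the
benign-adjacent root samples).  The first tree node of degree >= 3 past the
root is the bifurcation: samples on the root side are "pre", the two
subtrees are "fate1"/"fate2" (largest first).

This MST backbone deliberately replaces reversed-graph-embedding tree
learning: the claims exercised downstream — ordering from a benign root, a
single bifurcation, branch-dependent expression — are preserved by the
simpler, fully testable backbone, and an alternative embedding can be
plugged in via the ``embedding`` argument.

Branch-dependent expression (a BEAM-style test) compares a Gaussian model
with a shared natural cubic spline in pseudotime against one with
branch-specific spline coefficients for post-branch samples, via a
likelihood-ratio chi-square.  Expression is modelled as Gaussian on the
log2 scale because the pipeline's input is RPKM, not counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, rng_for

logger = logging.getLogger("thyrotype")

__all__ = [
    "TrajectoryState",
    "fit_trajectory",
    "beam_test",
    "cluster_branch_genes",
    "natural_spline_basis",
]


@dataclass
class TrajectoryState:
    embedding: pd.DataFrame  # samples x (pc1, pc2)
    pseudotime: pd.Series
    branch: pd.Series  # pre / fate1 / fate2
    tree: nx.Graph  # centroid backbone; nodes carry pos, edges carry length
    root_node: int
    branch_node: int | None
    root_samples: list[str]


def _project_to_segment(
    p: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[float, float, float]:
    """Return (distance to segment, clipped offset t in [0,1] from a, raw t)."""
    ab = b - a
    denom = float(ab @ ab)
    raw = 0.0 if denom == 0 else float((p - a) @ ab / denom)
    t = float(np.clip(raw, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t, raw


def fit_trajectory(
    m: ExpressionMatrix,
    root_samples: list[str],
    seed: int = 0,
    n_centroids: int = 0,
) -> TrajectoryState:
    """Fit the MST-backbone trajectory on a log2, variable-gene matrix."""
    samples = m.samples
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to fit a trajectory")
    missing = [s for s in root_samples if s not in samples]
    if missing:
        raise ValueError(f"root samples not in cohort: {missing[:5]}")
    if n_centroids <= 0:
        n_centroids = max(2, int(np.ceil(n / 10)))
    if n_centroids < 2:
        raise ValueError("need at least 2 centroids")

    x = m.data.T.to_numpy()  # samples x genes
    emb = PCA(n_components=2, svd_solver="full").fit_transform(x)
    embedding = pd.DataFrame(emb, index=samples, columns=["pc1", "pc2"])

    rng = rng_for(seed, "fit_trajectory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(
            n_clusters=n_centroids, n_init=10, random_state=int(rng.integers(2**31))
        ).fit(emb)
    centroids = km.cluster_centers_

    tree = nx.Graph()
    for i, c in enumerate(centroids):
        tree.add_node(i, pos=c)
    complete = nx.Graph()
    for i in range(n_centroids):
        for j in range(i + 1, n_centroids):
            complete.add_edge(i, j, length=float(np.linalg.norm(centroids[i] - centroids[j])))
    mst = nx.minimum_spanning_tree(complete, weight="length")
    tree.add_edges_from(mst.edges(data=True))

    root_mean = embedding.loc[list(root_samples)].mean(axis=0).to_numpy()
    root_node = int(np.argmin(np.linalg.norm(centroids - root_mean, axis=1)))
    node_dist = nx.single_source_dijkstra_path_length(tree, root_node, weight="length")

    # project samples onto nearest tree edge and read off geodesic pseudotime;
    # terminal edges are extended past their leaf so samples beyond the
    # backbone ends keep distinct, order-preserving positions (negative
    # upstream of the root; everything is shifted to a zero minimum below)
    edges = sorted(tuple(sorted(e)) for e in tree.edges)
    degree = dict(tree.degree)
    pseudotime = np.empty(n)
    nearest_node = np.empty(n, dtype=int)
    sample_edge: list[tuple[int, int]] = [None] * n
    for si in range(n):
        p = emb[si]
        best = None
        for u, v in edges:
            d, t, raw = _project_to_segment(p, centroids[u], centroids[v])
            if best is None or d < best[0]:
                length = tree[u][v]["length"]
                if raw > 1.0 and degree[v] == 1:
                    over = (raw - 1.0) * length
                    pt = -over if v == root_node else node_dist[v] + over
                elif raw < 0.0 and degree[u] == 1:
                    over = -raw * length
                    pt = -over if u == root_node else node_dist[u] + over
                else:
                    pt = min(node_dist[u] + t * length, node_dist[v] + (1 - t) * length)
                best = (d, pt, u if t <= 0.5 else v, (u, v))
        pseudotime[si] = best[1]
        nearest_node[si] = best[2]
        sample_edge[si] = best[3]
    pseudotime -= pseudotime.min()

    branch_candidates = [v for v in tree.nodes if tree.degree(v) >= 3]
    branch_node = min(branch_candidates, key=lambda v: (node_dist[v], v)) if branch_candidates else None

    if branch_node is None:
        labels = np.where(nearest_node == root_node, "pre", "fate1")
    else:
        cut = tree.copy()
        cut.remove_node(branch_node)
        comps = list(nx.connected_components(cut))
        root_comp = next((c for c in comps if root_node in c), set())
        others = sorted(
            (c for c in comps if c is not root_comp),
            key=lambda c: (-len(c), min(c)),
        )
        if len(others) > 2:
            logger.warning(
                "fit_trajectory: %d-way branch point; two largest subtrees become fates",
                len(others) + 1,
            )
        fate_of: dict[int, str] = {}
        for rank, comp in enumerate(others):
            label = "fate1" if rank == 0 else "fate2"
            for v in comp:
                fate_of[v] = label

        def _edge_label(edge: tuple[int, int]) -> str:
            # label by the component the projected edge reaches, so samples
            # on an edge leaving the branch point already belong to the fate
            ends = [v for v in edge if v != branch_node]
            if all(v in root_comp for v in ends):
                return "pre"
            fates = {fate_of[v] for v in ends if v in fate_of}
            return sorted(fates)[0] if fates else "pre"

        labels = np.array([_edge_label(sample_edge[si]) for si in range(n)])

    return TrajectoryState(
        embedding=embedding,
        pseudotime=pd.Series(pseudotime, index=samples, name="pseudotime"),
        branch=pd.Series(labels, index=samples, name="branch"),
        tree=tree,
        root_node=root_node,
        branch_node=branch_node,
        root_samples=list(root_samples),
    )


# ---------------------------------------------------------------------------
# Natural cubic spline basis (R ns()-style truncated power construction)


def natural_spline_basis(t: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with df columns (no intercept).

    Knots sit at quantiles of ``t``: two boundary knots at the extremes and
    df - 1 interior knots.  The basis is linear beyond the boundaries.
    """
    if df < 2:
        raise ValueError("spline df must be >= 2")
    t = np.asarray(t, dtype=float)
    knots = np.quantile(t, np.linspace(0.0, 1.0, df + 1))
    knots = np.unique(knots)
    if len(knots) < 3:  # degenerate spread: fall back to polynomial in t
        return np.column_stack([t**p for p in range(1, df + 1)])
    xi = knots
    k_last = xi[-1]
    k_penult = xi[-2]

    def d(k: float) -> np.ndarray:
        return (np.clip(t - k, 0, None) ** 3 - np.clip(t - k_last, 0, None) ** 3) / (k_last - k)

    d_penult = d(k_penult)
    cols = [t] + [d(k) - d_penult for k in xi[:-2]]
    basis = np.column_stack(cols)
    if basis.shape[1] < df:  # fewer unique knots than requested
        extra = [t ** (p + 1) for p in range(basis.shape[1], df)]
        basis = np.column_stack([basis, *extra])
    return basis[:, :df]


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares per column of y, plus the design rank."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return (resid**2).sum(axis=0), int(rank)


def beam_test(
    m: ExpressionMatrix,
    traj: TrajectoryState,
    genes: list[str] | None = None,
    spline_df: int = 3,
) -> pd.DataFrame:
    """Branch-dependent expression test for every (or the given) genes.

    Null: expression ~ intercept + natural cubic spline in pseudotime,
    shared across branches.  Alternative: additionally, branch-specific
    intercept and spline coefficients for post-branch fate-2 samples.
    Gaussian likelihood-ratio statistic n*log(RSS0/RSS1), p from chi-square
    with df = added design rank; Benjamini-Hochberg q over genes.
    """
    fates = set(traj.branch.unique()) - {"pre"}
    if len(fates) != 2:
        raise ValueError("beam_test needs a fitted trajectory with two fates")
    if genes is None:
        genes = m.genes
    samples = m.samples
    t = traj.pseudotime.loc[samples].to_numpy()
    branch = traj.branch.loc[samples].to_numpy()
    y = m.data.loc[genes].to_numpy().T  # samples x genes

    basis = natural_spline_basis(t, spline_df)
    x0 = np.column_stack([np.ones(len(t)), basis])
    fate2 = (branch == sorted(fates)[1]).astype(float)
    x1 = np.column_stack([x0, fate2[:, None] * x0])

    rss0, rank0 = _rss(x0, y)
    rss1, rank1 = _rss(x1, y)
    df_added = max(rank1 - rank0, 1)
    n = len(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = n * np.log(np.where(rss1 > 0, rss0 / rss1, 1.0))
    lr = np.where((rss0 <= 1e-12) | ~np.isfinite(lr), 0.0, np.clip(lr, 0.0, None))
    p = stats.chi2.sf(lr, df_added)
    p = np.where(lr == 0.0, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"gene": genes, "lr_stat": lr, "p_value": p, "q_value": q}
    ).set_index("gene", drop=False)


def _fate_curves(
    m: ExpressionMatrix,
    traj: TrajectoryState,
    genes: list[str],
    grid_size: int = 25,
    spline_df: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed mean expression on a pseudotime grid for each fate.

    Each fate's curve is fit on pre-branch plus that fate's samples.
    Returns (curve_fate1, curve_fate2, grid), curves gene x grid.
    """
    samples = m.samples
    t = traj.pseudotime.loc[samples].to_numpy()
    branch = traj.branch.loc[samples].to_numpy()
    y = m.data.loc[genes].to_numpy().T
    grid = np.linspace(t.min(), t.max(), grid_size)
    curves = []
    for fate in ("fate1", "fate2"):
        mask = (branch == "pre") | (branch == fate)
        tt = t[mask]
        basis = natural_spline_basis(tt, spline_df)
        x = np.column_stack([np.ones(mask.sum()), basis])
        coef, _, _, _ = np.linalg.lstsq(x, y[mask], rcond=None)
        # evaluate the same truncated-power basis at grid points
        gb = _eval_basis_like(tt, grid, spline_df)
        xg = np.column_stack([np.ones(grid_size), gb])
        curves.append((xg @ coef).T)  # genes x grid
    return curves[0], curves[1], grid


def _eval_basis_like(t_train: np.ndarray, t_new: np.ndarray, df: int) -> np.ndarray:
    """Evaluate the natural-spline basis built from t_train at t_new."""
    knots = np.unique(np.quantile(t_train, np.linspace(0.0, 1.0, df + 1)))
    if len(knots) < 3:
        return np.column_stack([t_new**p for p in range(1, df + 1)])
    k_last, k_penult = knots[-1], knots[-2]

    def d(k: float) -> np.ndarray:
        return (
            np.clip(t_new - k, 0, None) ** 3 - np.clip(t_new - k_last, 0, None) ** 3
        ) / (k_last - k)

    d_penult = d(k_penult)
    basis = np.column_stack([t_new] + [d(k) - d_penult for k in knots[:-2]])
    if basis.shape[1] < df:
        extra = [t_new ** (p + 1) for p in range(basis.shape[1], df)]
        basis = np.column_stack([basis, *extra])
    return basis[:, :df]


def cluster_branch_genes(
    results: pd.DataFrame,
    m: ExpressionMatrix,
    traj: TrajectoryState,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Catalogue significant branch genes into the three canonical patterns.

    Using smoothed per-fate mean curves: cluster I declines from the start
    on both fates; cluster II ends fate 1 above both the pre-branch mean and
    the fate-2 end; cluster III is the mirror image.  Genes matching no
    pattern are flagged ambiguous and assigned by seeded k-means (k=3) on
    their z-scored concatenated curves, with each k-means cluster mapped to
    the majority pattern of its unambiguous members.
    """
    significant = results.loc[results["q_value"] < q_threshold, "gene"].tolist()
    if len(significant) < 3:
        logger.warning("cluster_branch_genes: <3 significant genes, clustering skipped")
        return pd.DataFrame(columns=["gene", "cluster", "ambiguous"]).set_index(
            "gene", drop=False
        )
    c1, c2, _ = _fate_curves(m, traj, significant)
    branch = traj.branch.loc[m.samples]
    pre_mask = (branch == "pre").to_numpy()
    pre_mean = m.data.loc[significant].to_numpy()[:, pre_mask].mean(axis=1)

    start = (c1[:, 0] + c2[:, 0]) / 2
    end1, end2 = c1[:, -1], c2[:, -1]
    labels = np.full(len(significant), "", dtype=object)
    declining = (end1 < start) & (end2 < start)
    up1 = (end1 > pre_mean) & (end1 > end2)
    up2 = (end2 > pre_mean) & (end2 > end1)
    labels[declining] = "I"
    labels[~declining & up1] = "II"
    labels[~declining & up2] = "III"
    ambiguous = labels == ""

    if ambiguous.any():
        curves = np.hstack([c1, c2])
        mu = curves.mean(axis=1, keepdims=True)
        sd = curves.std(axis=1, keepdims=True)
        z = (curves - mu) / np.where(sd > 0, sd, 1.0)
        rng = rng_for(seed, "cluster_branch_genes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=3, n_init=10, random_state=int(rng.integers(2**31))).fit(z)
        mapping = {}
        for c in range(3):
            members = labels[(km.labels_ == c) & ~ambiguous]
            mapping[c] = (
                pd.Series(members).mode().iloc[0] if len(members) else "I"
            )
        for i in np.where(ambiguous)[0]:
            labels[i] = mapping[km.labels_[i]]

    return pd.DataFrame(
        {"gene": significant, "cluster": labels, "ambiguous": ambiguous}
    ).set_index("gene", drop=False)
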