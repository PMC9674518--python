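"""Hub-gene network analysis.

A mutual-information (MI) co-expression network is seeded on subtype marker
genes ("hubs"): MI is estimated between every hub and every other gene (and
among retained neighbors) with an equal-frequency binned plug-in estimator,
weak edges are dropped against a permutation-null threshold, and indirect
edges are pruned with the data processing inequality (DPI): in any triangle
the weakest edge is removed when its MI falls below (1 - tolerance) times
the smaller of the other two.  Hubs are ranked by Maximal Clique Centrality
(MCC), pathways are attached to hubs via pre-ranked GSEA of each hub's
first-layer neighbors ranked by subtype fold-change, and the result is a
bipartite hub-pathway graph.

MI is reported in nats; downstream steps use it only ordinally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, rng_for

logger = logging.getLogger("thyrotype")

__all__ = [
    "MINetwork",
    "mutual_information",
    "build_aracne_network",
    "mcc_scores",
    "gsea_preranked",
    "HubPathwayGraph",
    "hub_pathway_graph",
]


# ---------------------------------------------------------------------------
# Mutual information


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning via interior quantile edges."""
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def default_bins(n: int) -> int:
    return min(10, max(2, math.ceil(math.sqrt(n))))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 0) -> float:
    """Plug-in MI (nats) between two expression vectors.

    Both variables are discretized into ``bins`` equal-frequency bins
    (default ceil(sqrt(n)) capped at 10), and MI = sum p(a,b) log(p(a,b) /
    (p(a) p(b))).  Symmetric and >= 0 by construction.  A constant vector
    collapses to a single bin, giving MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations for MI estimation")
    if bins <= 0:
        bins = default_bins(n)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("mutual_information: constant vector, MI = 0")
        return 0.0
    bx = _discretize(x, bins)
    by = _discretize(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)

    def _entropy(counts: np.ndarray) -> float:
        p = np.sort(counts[counts > 0].ravel()) / n
        return float(-(p * np.log(p)).sum())

    # H(x) + H(y) - H(x, y) with sorted-count summation: exactly symmetric
    mi = _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - _entropy(joint)
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# ARACNe-style network


@dataclass
class MINetwork:
    """MI co-expression network with DPI pruning flags and MCC scores."""

    graph: nx.Graph  # nodes carry is_hub; surviving edges carry mi
    hubs: list[str]
    mi_threshold: float
    all_edges: pd.DataFrame = field(default=None)  # gene_a, gene_b, mi, dpi_kept

    def edge_table(self) -> pd.DataFrame:
        return self.all_edges.copy()

    def node_table(self) -> pd.DataFrame:
        mcc = mcc_scores(self.graph)
        return pd.DataFrame(
            {
                "gene": list(self.graph.nodes),
                "mcc": [mcc[v] for v in self.graph.nodes],
                "is_hub": [self.graph.nodes[v].get("is_hub", False) for v in self.graph.nodes],
            }
        )


def _null_mi_threshold(
    values: np.ndarray,
    n_pairs_tested: int,
    bins: int,
    rng: np.random.Generator,
    n_permutations: int,
    alpha: float,
) -> float:
    """Pooled permutation null for the MI significance threshold.

    MI is computed between a permuted copy of one row and another random
    row, ``n_permutations`` times; the threshold is the Bonferroni-corrected
    (1 - alpha / n_pairs) quantile of the pooled null (the pool maximum when
    the corrected tail is finer than the pool resolves).
    """
    n_genes = values.shape[0]
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        i, j = rng.integers(0, n_genes, size=2)
        null[r] = mutual_information(rng.permutation(values[i]), values[j], bins)
    level = 1.0 - alpha / max(n_pairs_tested, 1)
    if level >= 1.0 - 1.0 / n_permutations:
        return float(null.max())
    return float(np.quantile(null, level))


def build_aracne_network(
    fm: ExpressionMatrix,
    hubs: list[str],
    dpi_tolerance: float = 0.0,
    mi_threshold: float | None = None,
    bins: int = 0,
    n_null_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> MINetwork:
    """MI network seeded on hub genes, thresholded and DPI-pruned.

    Edges are computed hub-vs-every-other-gene and then among the retained
    first-layer neighbors; edges with MI below the (permutation-null derived
    or explicit) threshold are dropped.  DPI then examines every triangle in
    deterministic sorted order and marks the weakest edge for removal when
    its MI < (1 - tolerance) * min(other two); marked edges are removed
    after the full scan, and the returned edge table records the survival
    flag for every thresholded edge.
    """
    missing = [h for h in hubs if h not in fm.data.index]
    if missing:
        raise ValueError(f"hub genes not in matrix: {missing[:5]}")
    genes = fm.genes
    values = fm.values
    idx = {g: i for i, g in enumerate(genes)}
    if bins <= 0:
        bins = default_bins(values.shape[1])
    rng = rng_for(seed, "build_aracne_network")

    hub_set = sorted(set(hubs))
    pairs: list[tuple[str, str]] = []
    seen = set()
    for h in hub_set:
        for g in genes:
            if g == h:
                continue
            key = (min(h, g), max(h, g))
            if key not in seen:
                seen.add(key)
                pairs.append(key)

    if mi_threshold is None:
        mi_threshold = _null_mi_threshold(
            values, len(pairs), bins, rng, n_null_permutations, alpha
        )

    mi_of: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        mi = mutual_information(values[idx[a]], values[idx[b]], bins)
        if mi >= mi_threshold:
            mi_of[(a, b)] = mi

    # second pass: MI among retained neighbors (non-hub nodes already linked)
    neighbors = sorted({g for pair in mi_of for g in pair if g not in hub_set})
    for i, a in enumerate(neighbors):
        for b in neighbors[i + 1 :]:
            key = (min(a, b), max(a, b))
            if key in seen or key in mi_of:
                continue
            mi = mutual_information(values[idx[a]], values[idx[b]], bins)
            if mi >= mi_threshold:
                mi_of[key] = mi

    graph = nx.Graph()
    for h in hub_set:
        graph.add_node(h, is_hub=True)
    for (a, b), mi in mi_of.items():
        graph.add_node(a, is_hub=a in hub_set)
        graph.add_node(b, is_hub=b in hub_set)
        graph.add_edge(a, b, mi=mi)
    if not mi_of:
        logger.warning("build_aracne_network: no edge survives the MI threshold")

    removed = _dpi_prune(graph, dpi_tolerance)
    table = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "mi": mi, "dpi_kept": (a, b) not in removed}
            for (a, b), mi in sorted(mi_of.items())
        ]
    )
    return MINetwork(graph=graph, hubs=hub_set, mi_threshold=float(mi_threshold), all_edges=table)


def _dpi_prune(graph: nx.Graph, tolerance: float) -> set[tuple[str, str]]:
    """Mark-and-remove DPI pass; returns the removed (sorted) edge keys."""
    to_remove: set[tuple[str, str]] = set()
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        common = sorted(set(graph[u]) & set(graph[v]))
        for w in common:
            tri = sorted([(graph[u][v]["mi"], (u, v)), (graph[u][w]["mi"], (u, w)), (graph[v][w]["mi"], (v, w))])
            weakest_mi, weakest_edge = tri[0]
            if weakest_mi < (1.0 - tolerance) * tri[1][0]:
                to_remove.add(tuple(sorted(weakest_edge)))
    for a, b in to_remove:
        if graph.has_edge(a, b):
            graph.remove_edge(a, b)
    return to_remove


# ---------------------------------------------------------------------------
# Maximal Clique Centrality


def mcc_scores(graph: nx.Graph) -> pd.Series:
    """MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.

    Maximal cliques are enumerated exactly (Bron-Kerbosch with pivoting via
    networkx).  Single-node "cliques" (isolated nodes) contribute nothing,
    so an isolated node scores 0 and a node whose only maximal cliques are
    edges scores its degree.
    """
    scores = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        contribution = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contribution
    return pd.Series(scores, dtype=float)


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


def _es_from_hits(scores: np.ndarray, hits: np.ndarray, p_weight: float) -> tuple[float, int]:
    """Max-deviation running-sum enrichment score; returns (ES, extremum index)."""
    weights = np.abs(scores) ** p_weight
    w_hit = np.where(hits, weights, 0.0)
    total_hit = w_hit.sum()
    n_miss = len(scores) - int(hits.sum())
    if total_hit == 0 or n_miss == 0:
        raise ValueError("set must hit and miss at least one ranked gene")
    running = np.cumsum(w_hit / total_hit - (~hits) / n_miss)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    p_weight: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene -> score ranking.

    Genes are ordered by descending score (ties broken by name).  The
    enrichment score (ES) is the maximum deviation of a running sum with
    hit increments |score|**p / sum(|score|**p) and miss decrements
    1/(N - |S|).  The null redraws the set's positions uniformly
    (gene-label permutation); NES = ES / mean(|null ES| of matching sign),
    and p is the matching-sign null tail with an add-one correction.
    Benjamini-Hochberg q-values are computed per sign family.  Sets with no
    overlap with the ranking are skipped with a warning.
    """
    if ranking.index.has_duplicates:
        raise ValueError("ranking has duplicate genes")
    ordered = ranking.sort_values(ascending=False, kind="mergesort")
    order_frame = pd.DataFrame({"gene": ordered.index, "score": ordered.to_numpy()})
    order_frame = order_frame.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    genes = order_frame["gene"].to_numpy()
    scores = order_frame["score"].to_numpy(dtype=float)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = rng_for(seed, "gsea_preranked")

    rows = []
    for name in sorted(gene_sets):
        members = [g for g in dict.fromkeys(gene_sets[name]) if g in pos]
        if not members or len(members) == n:
            logger.warning("gsea_preranked: set %r skipped (no usable overlap)", name)
            continue
        hits = np.zeros(n, dtype=bool)
        hits[[pos[g] for g in members]] = True
        es, extremum = _es_from_hits(scores, hits, p_weight)

        size = len(members)
        null = np.empty(n_permutations)
        for r in range(n_permutations):
            h = np.zeros(n, dtype=bool)
            h[rng.choice(n, size=size, replace=False)] = True
            null[r], _ = _es_from_hits(scores, h, p_weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            nes = es / max(np.abs(null).mean(), 1e-12)
            p = 1.0 / (n_permutations + 1.0)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1.0 + (np.abs(same_sign) >= abs(es)).sum()) / (1.0 + len(same_sign))

        if es >= 0:
            leading = [g for g in genes[: extremum + 1] if g in set(members)]
        else:
            leading = [g for g in genes[extremum:] if g in set(members)]
        rows.append(
            {
                "pathway": name,
                "size": size,
                "es": es,
                "nes": float(nes),
                "p_value": float(p),
                "leading_edge": ",".join(leading),
            }
        )

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q_value"] = np.nan
    for sign in (result["es"] >= 0, result["es"] < 0):
        if sign.any():
            _, q, _, _ = multipletests(result.loc[sign, "p_value"], method="fdr_bh")
            result.loc[sign, "q_value"] = q
    return result.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hub-pathway bipartite graph


@dataclass
class HubPathwayGraph:
    """Bipartite graph linking top hubs to their downstream pathways."""

    hub_nodes: pd.DataFrame  # gene, mcc, log2fc (relative expression)
    pathway_nodes: pd.DataFrame  # pathway, mean_nes, direction
    edges: pd.DataFrame  # hub, pathway, nes, q_value


def hub_pathway_graph(
    net: MINetwork,
    top_n: int,
    fm: ExpressionMatrix,
    assignments: pd.Series,
    focal_subtype: str,
    pathway_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> HubPathwayGraph:
    """Attach downstream pathways to the top MCC hubs of one subtype.

    The top ``top_n`` hub nodes by MCC (ties by name) are kept; each hub's
    first-layer neighbors are ranked by the difference in mean log2
    expression between the focal subtype and all other samples, and
    pre-ranked GSEA over ``pathway_sets`` yields one NES per (hub, pathway).
    The hub->pathway edge weight is that NES (one neighbor ranking per hub);
    a pathway node's summary is the mean NES across hubs.  Hubs with no
    surviving neighbors are excluded with a log message.
    """
    if top_n <= 0:
        empty = pd.DataFrame()
        return HubPathwayGraph(empty, empty, empty)
    mcc = mcc_scores(net.graph)
    hub_mcc = mcc[[h for h in net.hubs if h in mcc.index]]
    hub_frame = pd.DataFrame({"gene": hub_mcc.index, "mcc": hub_mcc.to_numpy()})
    hub_frame = hub_frame.sort_values(["mcc", "gene"], ascending=[False, True], kind="mergesort")
    top = list(hub_frame["gene"].iloc[:top_n])

    in_focal = assignments.loc[fm.samples] == focal_subtype
    if in_focal.sum() == 0 or (~in_focal).sum() == 0:
        raise ValueError(f"focal subtype {focal_subtype!r} must split samples into two groups")
    mean_focal = fm.data.loc[:, in_focal.to_numpy()].mean(axis=1)
    mean_other = fm.data.loc[:, (~in_focal).to_numpy()].mean(axis=1)
    log2fc = mean_focal - mean_other  # matrix already on log2 scale

    hub_rows, edge_rows = [], []
    for hub in top:
        neigh = sorted(net.graph[hub]) if hub in net.graph else []
        neigh = [g for g in neigh if g in log2fc.index]
        if not neigh:
            logger.info("hub_pathway_graph: hub %s has no neighbors, excluded", hub)
            continue
        ranking = log2fc.loc[neigh]
        enr = gsea_preranked(
            ranking, pathway_sets, n_permutations=n_permutations, seed=seed
        )
        hub_rows.append(
            {"gene": hub, "mcc": float(mcc[hub]), "log2fc": float(log2fc.get(hub, np.nan))}
        )
        for row in enr.itertuples(index=False):
            edge_rows.append(
                {"hub": hub, "pathway": row.pathway, "nes": row.nes, "q_value": row.q_value}
            )

    edges = pd.DataFrame(edge_rows)
    if edges.empty:
        return HubPathwayGraph(pd.DataFrame(hub_rows), pd.DataFrame(), edges)
    pathway_nodes = (
        edges.groupby("pathway")["nes"]
        .mean()
        .rename("mean_nes")
        .reset_index()
        .assign(direction=lambda df: np.where(df["mean_nes"] >= 0, "up", "down"))
    )
    return HubPathwayGraph(pd.DataFrame(hub_rows), pathway_nodes, edges)
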