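"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive re-implementations (brute force,
enumeration, direct accumulation) used to check the package's optimized
code paths; they must stay independent of the implementations they verify.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from thyrotype.core_io import ExpressionMatrix, log2_transform
from thyrotype.synthetic_data import (
    SimulationSpec,
    simulate_cohort,
    simulate_diagnosis_cohort,
    simulate_trajectory_cohort,
)


@pytest.fixture(scope="session")
def cohort7():
    """Default planted subtype cohort."""
    return simulate_cohort(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def nodules7(cohort7):
    """(linear matrix, sample table) restricted to nodule samples."""
    nod = cohort7.samples[cohort7.samples.tissue == "nodule"]
    return cohort7.expression.subset_samples(nod.sample_id.tolist()), nod


@pytest.fixture(scope="session")
def traj_cohort7():
    return simulate_trajectory_cohort(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def diagnosis7():
    return simulate_diagnosis_cohort(seed=7)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]}, index=["g1", "g2"])
    )


# ---------------------------------------------------------------------------
# Oracles


def exemplar_scores_bruteforce(w: np.ndarray, factor: int) -> np.ndarray:
    """Loading-margin score computed gene by gene with explicit loops."""
    n_genes, k = w.shape
    out = np.empty(n_genes)
    for g in range(n_genes):
        best_other = -np.inf
        for j in range(k):
            if j != factor and w[g, j] > best_other:
                best_other = w[g, j]
        out[g] = w[g, factor] - best_other
    return out


def mcc_bruteforce(graph: nx.Graph) -> dict:
    """MCC via exhaustive subset enumeration (feasible for <= 12 nodes)."""
    nodes = list(graph.nodes)
    scores = {v: 0 for v in nodes}
    adj = {v: set(graph[v]) for v in nodes}
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sset = set(subset)
            if not all(b in adj[a] for a, b in itertools.combinations(subset, 2)):
                continue
            # maximal: no outside node adjacent to every member
            if any(sset <= adj[v] for v in nodes if v not in sset):
                continue
            for v in subset:
                scores[v] += math.factorial(r - 1)
    return scores


def gsea_es_bruteforce(
    genes: list[str], scores: np.ndarray, members: set, p_weight: float = 1.0
) -> float:
    """Enrichment score by direct step-by-step accumulation."""
    weights = [abs(s) ** p_weight if g in members else 0.0 for g, s in zip(genes, scores)]
    total = sum(weights)
    n_miss = len(genes) - len([g for g in genes if g in members])
    running, best = 0.0, 0.0
    for g, w in zip(genes, weights):
        if g in members:
            running += w / total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def tds_bruteforce(linear: pd.DataFrame, genes: list[str]) -> dict:
    """Median-center-and-sum TDS computed with explicit loops."""
    log2m = np.log2(linear + 1.0)
    out = {s: 0.0 for s in linear.columns}
    for g in genes:
        med = float(np.median(log2m.loc[g].to_numpy()))
        for s in linear.columns:
            out[s] += float(log2m.loc[g, s]) - med
    return out


def fate_accuracy(inferred: np.ndarray, truth: np.ndarray) -> float:
    """Post-bifurcation fate agreement, maximized over the fate1/fate2 naming."""
    swapped = np.where(
        inferred == "fate1", "fate2", np.where(inferred == "fate2", "fate1", inferred)
    )
    return max(float((inferred == truth).mean()), float((swapped == truth).mean()))


def log2_nodule_matrix(expr: ExpressionMatrix) -> ExpressionMatrix:
    return log2_transform(expr)
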