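"""Synthetic cohorts with planted ground truth.

The generator emulates the structure of a paired nodule/adjacent thyroid
cohort: six latent expression programs (four malignant-like, two benign-like)
with disjoint subtype marker blocks, an immune-infiltration gradient
concentrated in one malignant subtype, a BRAF-mutation label enriched in
another, paired adjacent tissue drawn from the baseline program, a branching
benign-to-malignant trajectory, and variant-call candidate tables whose rows
straddle every post-filter threshold.

The model is log-normal: gene baselines are drawn in log2 space, subtype and
immune effects are additive log2 shifts, and the exported matrix is mapped
back to the linear RPKM-like scale via ``2**x - pseudocount`` clipped at zero.
Counts, library sizes and read-level artifacts are deliberately not modelled:
everything downstream consumes (log) RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSetCollection, rng_for

__all__ = [
    "SimulationSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_trajectory_cohort",
    "simulate_variant_tables",
]

#: subtype labels, in order; the first four are malignant (PTC-like), the
#: last two benign (BTN-like).  S2 carries the immune gradient, S3 the
#: enriched BRAF-mutation label.
SUBTYPE_NAMES = ("S1", "S2", "S3", "S4", "B1", "B2")
IMMUNE_SUBTYPE = "S2"
BRAF_SUBTYPE = "S3"


@dataclass
class SimulationSpec:
    """Parameters of the planted cohort.

    Defaults describe the study conditions every recovery test runs under:
    six subtypes of 20 nodule samples each (120 nodules + 120 paired
    adjacent), 1000 genes, a 2.0 log2 marker shift, log2 noise sd 0.5.
    """

    n_genes: int = 1000
    samples_per_subtype: int = 20
    markers_per_subtype: int = 30
    marker_effect: float = 2.0  # log2 shift of a marker in its own subtype
    baseline_mean: float = 3.0  # log2 RPKM
    baseline_sd: float = 1.5
    noise_sd: float = 0.5  # log2 residual sd
    n_immune_genes: int = 50
    immune_amplitude: float = 2.0  # log2 shift at immune level 1.0
    braf_fraction: float = 0.75  # P(braf label | BRAF-enriched subtype)
    braf_background: float = 0.05
    pseudocount: float = 1.0
    # trajectory cohort
    n_trajectory_samples: int = 200
    branch_time: float = 0.5
    genes_per_cluster: int = 60
    trajectory_amplitude: float = 5.0
    trajectory_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.samples_per_subtype, self.markers_per_subtype) <= 0:
            raise ValueError("counts must be positive")
        if self.marker_effect < 0 or self.immune_amplitude < 0:
            raise ValueError("effect sizes must be >= 0")
        demand = len(SUBTYPE_NAMES) * self.markers_per_subtype + self.n_immune_genes
        if demand > self.n_genes:
            raise ValueError(
                f"marker/immune demand ({demand} genes) exceeds n_genes ({self.n_genes})"
            )
        if not 0 < self.branch_time < 1:
            raise ValueError("branch_time must lie in (0, 1)")
        if 3 * self.genes_per_cluster > self.n_genes:
            raise ValueError("trajectory cluster demand exceeds n_genes")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix  # linear RPKM-like scale
    samples: pd.DataFrame  # sample table incl. truth columns
    marker_sets: GeneSetCollection
    immune_genes: list[str] = field(default_factory=list)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _to_linear(log2_values: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.clip(np.exp2(log2_values) - pseudocount, 0.0, None)


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate the paired nodule/adjacent cohort with planted subtypes.

    Each subtype owns a disjoint block of ``markers_per_subtype`` genes that
    are shifted up by ``marker_effect`` log2 units in that subtype's nodules.
    Immune-gradient genes are shifted by ``immune_amplitude`` times the
    sample's latent immune level (uniform on [0, 1]; shifted towards 1 in the
    immune-enriched subtype).  Adjacent samples are baseline-only and share a
    ``pair_id`` with their nodule.
    """
    rng = rng_for(spec.seed, "simulate_cohort")
    genes = _gene_names(spec.n_genes)
    n_sub = len(SUBTYPE_NAMES)
    m = spec.markers_per_subtype

    marker_sets = GeneSetCollection()
    for k, name in enumerate(SUBTYPE_NAMES):
        marker_sets.add(name, genes[k * m : (k + 1) * m], f"planted markers of {name}")
    immune_genes = genes[n_sub * m : n_sub * m + spec.n_immune_genes]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    baseline = np.clip(baseline, 0.0, None)

    rows = []
    log2_cols = {}
    for k, subtype in enumerate(SUBTYPE_NAMES):
        malignant = subtype.startswith("S")
        for j in range(spec.samples_per_subtype):
            pid = f"P{k * spec.samples_per_subtype + j + 1:03d}"
            immune_u = rng.uniform()
            if subtype == IMMUNE_SUBTYPE:
                immune_u = 0.5 + 0.5 * immune_u
            braf = bool(
                rng.uniform()
                < (spec.braf_fraction if subtype == BRAF_SUBTYPE else spec.braf_background)
            )
            shift = np.zeros(spec.n_genes)
            shift[k * m : (k + 1) * m] += spec.marker_effect
            idx0 = n_sub * m
            shift[idx0 : idx0 + spec.n_immune_genes] += spec.immune_amplitude * immune_u
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            log2_cols[f"{pid}_T"] = baseline + shift + noise
            rows.append(
                {
                    "sample_id": f"{pid}_T",
                    "tissue": "nodule",
                    "histology": "PTC" if malignant else "BTN",
                    "pair_id": pid,
                    "braf_mutant": braf,
                    "true_subtype": subtype,
                    "immune_level": immune_u,
                }
            )
            adj_noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            log2_cols[f"{pid}_N"] = baseline + adj_noise
            rows.append(
                {
                    "sample_id": f"{pid}_N",
                    "tissue": "adjacent",
                    "histology": "PTC" if malignant else "BTN",
                    "pair_id": pid,
                    "braf_mutant": False,
                    "true_subtype": "adjacent",
                    "immune_level": 0.0,
                }
            )

    log2_matrix = pd.DataFrame(log2_cols, index=genes)
    expr = ExpressionMatrix(
        pd.DataFrame(
            _to_linear(log2_matrix.to_numpy(), spec.pseudocount),
            index=genes,
            columns=log2_matrix.columns,
        )
    )
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return SimulatedCohort(expr, samples, marker_sets, list(immune_genes))


def simulate_trajectory_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate a branching benign-to-malignant trajectory cohort.

    Every sample gets a latent time ``t`` uniform on [0, 1] and a branch
    label: ``pre`` before ``branch_time``, else ``fate1`` or ``fate2`` with
    equal probability.  Three planted gene programs follow the canonical
    branch patterns: cluster-I genes decline in ``t`` on both fates,
    cluster-II genes rise after the branch point on fate 1 only, cluster-III
    genes rise on fate 2 only.  The 10% of samples with the smallest ``t``
    are flagged as adjacent tissue so trajectory fitting can root there.
    """
    rng = rng_for(spec.seed, "simulate_trajectory_cohort")
    genes = _gene_names(spec.n_genes)
    g = spec.genes_per_cluster
    cluster_sets = GeneSetCollection()
    cluster_sets.add("cluster_I", genes[:g], "declines along both fates")
    cluster_sets.add("cluster_II", genes[g : 2 * g], "rises on fate 1 only")
    cluster_sets.add("cluster_III", genes[2 * g : 3 * g], "rises on fate 2 only")

    baseline = np.clip(
        rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes), 0.0, None
    )

    n = spec.n_trajectory_samples
    t = np.sort(rng.uniform(0.0, 1.0, size=n))
    branches = np.where(
        t < spec.branch_time,
        "pre",
        np.where(rng.uniform(size=n) < 0.5, "fate1", "fate2"),
    )
    n_adjacent = max(2, n // 10)

    amp = spec.trajectory_amplitude
    tb = spec.branch_time
    rows = []
    log2_cols = {}
    for i in range(n):
        sid = f"T{i + 1:03d}"
        shift = np.zeros(spec.n_genes)
        # cluster I: monotone decline on every branch, amp -> 0 over [0, 1]
        shift[:g] += amp * (1.0 - t[i])
        post = max(0.0, t[i] - tb) / (1.0 - tb)
        if branches[i] == "fate1":
            shift[g : 2 * g] += amp * post
        elif branches[i] == "fate2":
            shift[2 * g : 3 * g] += amp * post
        noise = rng.normal(0.0, spec.trajectory_noise_sd, size=spec.n_genes)
        log2_cols[sid] = baseline + shift + noise
        rows.append(
            {
                "sample_id": sid,
                "tissue": "adjacent" if i < n_adjacent else "nodule",
                "histology": "BTN" if t[i] < tb else "PTC",
                "pair_id": sid,
                "braf_mutant": False,
                "true_time": float(t[i]),
                "true_branch": str(branches[i]),
            }
        )

    log2_matrix = pd.DataFrame(log2_cols, index=genes)
    expr = ExpressionMatrix(
        pd.DataFrame(
            _to_linear(log2_matrix.to_numpy(), spec.pseudocount),
            index=genes,
            columns=log2_matrix.columns,
        )
    )
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return SimulatedCohort(expr, samples, cluster_sets, [])


def simulate_diagnosis_cohort(
    n_genes: int = 100,
    n_informative: int = 5,
    n_per_class: int = 120,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    baseline_mean: float = 3.0,
    baseline_sd: float = 1.5,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series, list[str]]:
    """Two-class (PTC vs BTN) cohort with complementary informative genes.

    Mirrors a subtype-derived diagnostic panel: every malignant sample
    carries a fixed total marker budget of ``n_informative * effect`` log2
    units, spread sparsely over the informative genes by Dirichlet(0.3)
    weights (so the average per-marker shift is ``effect``).  Different
    tumors therefore express different markers — as subtypes do — making
    each marker individually weak but non-redundant, while the panel as a
    whole separates the classes nearly perfectly.  Everything else is
    baseline plus noise.  Returns (linear-scale matrix, histology labels,
    informative gene list).
    """
    if n_informative > n_genes:
        raise ValueError("n_informative cannot exceed n_genes")
    rng = rng_for(seed, "simulate_diagnosis_cohort")
    genes = _gene_names(n_genes)
    baseline = np.clip(rng.normal(baseline_mean, baseline_sd, size=n_genes), 0.0, None)
    cols, labels = {}, {}
    for cls, prefix in (("PTC", "D"), ("BTN", "B")):
        for j in range(n_per_class):
            sid = f"{prefix}{j + 1:03d}"
            shift = np.zeros(n_genes)
            if cls == "PTC":
                weights = rng.dirichlet(np.full(n_informative, 0.3))
                shift[:n_informative] += effect * n_informative * weights
            cols[sid] = baseline + shift + rng.normal(0.0, noise_sd, size=n_genes)
            labels[sid] = cls
    log2_matrix = pd.DataFrame(cols, index=genes)
    expr = ExpressionMatrix(
        pd.DataFrame(
            _to_linear(log2_matrix.to_numpy(), pseudocount),
            index=genes,
            columns=log2_matrix.columns,
        )
    )
    return expr, pd.Series(labels, name="histology"), genes[:n_informative]


# ---------------------------------------------------------------------------
# Variant-call fixtures


def simulate_variant_tables(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionMatrix]:
    """Candidate fusion/mutation tables probing every filter boundary.

    Rows are placed adversarially at +-1 (or one VAF step) around each
    threshold so that inclusive/strict boundary semantics are testable.  Each
    row carries a hand-assigned ``truth_keep`` label derived from the stated
    rules at construction time, independent of the filter implementation.
    Also returns the small expression matrix the fusion expression rule
    consults (FUS_LOW never reaches RPKM 1; all other partners do).
    """
    expr_genes = ["FUS_A", "FUS_B", "FUS_C", "FUS_D", "FUS_LOW", "FUS_E", "FUS_F"]
    expr = ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [5.0, 3.0, 2.0, 8.0, 0.4, 1.5, 2.5],
                "s2": [6.0, 2.0, 4.0, 7.0, 0.9, 1.2, 3.0],
            },
            index=expr_genes,
        )
    )

    fusion_rows = [
        # gene_a, gene_b, split, span, same_chr, distance, truth_keep
        ("FUS_A", "FUS_B", 5, 2, False, 0, True),   # passes everything
        ("FUS_A", "FUS_B", 4, 2, False, 0, False),  # split below "at least 5"
        ("FUS_A", "FUS_B", 5, 1, False, 0, False),  # spanning below "at least 2"
        ("FUS_C", "FUS_LOW", 10, 5, False, 0, False),  # partner max RPKM < 1
        ("FUS_E", "FUS_F", 5, 2, False, 0, True),   # partner max RPKM just >= 1
        ("FUS_C", "FUS_D", 10, 5, True, 9_000, False),   # read-through, < 10 kb
        ("FUS_C", "FUS_D", 10, 5, True, 11_000, True),   # same chr but >= 10 kb
        ("FUS_C", "FUS_D", 10, 5, True, 9_999, False),   # boundary: strict <
        ("FUS_C", "FUS_D", 10, 5, True, 10_000, True),   # boundary: 10 kb kept
        ("FUS_A", "UNMEASURED", 10, 5, False, 0, False),  # partner not in matrix
    ]
    fusions = pd.DataFrame(
        fusion_rows,
        columns=[
            "gene_a",
            "gene_b",
            "split_reads",
            "spanning_pairs",
            "same_chromosome",
            "distance_bp",
            "truth_keep",
        ],
    )

    mutation_rows = [
        # gene, pos, ref, alt, t_depth, t_alt, n_depth, n_alt, dbsnp, truth_keep
        ("TP53", 100, "C", "T", 100, 6, 100, 0, False, True),    # passes everything
        ("TP53", 101, "C", "T", 100, 4, 100, 0, False, False),   # VAF 0.04 < 5% and alt < 5
        ("TP53", 102, "C", "T", 100, 6, 100, 2, False, False),   # normal VAF 0.02 >= 1%
        ("TP53", 103, "C", "T", 100, 6, 200, 1, False, True),    # normal VAF 0.005 < 1%
        ("TP53", 104, "C", "T", 100, 5, 100, 0, False, True),    # boundary: VAF 0.05, alt 5
        ("TP53", 105, "C", "T", 100, 20, 100, 1, False, False),  # boundary: normal VAF 0.01 strict
        ("BRAF", 200, "T", "A", 9, 5, 100, 0, False, False),     # tumor depth 9 < 10x
        ("BRAF", 201, "T", "A", 10, 5, 100, 0, False, True),     # boundary: depth 10 kept
        ("BRAF", 202, "T", "A", 100, 6, 9, 0, False, False),     # normal depth 9 < 10x
        ("BRAF", 203, "T", "A", 100, 6, 10, 0, False, True),     # boundary: normal depth 10
        ("BRAF", 204, "T", "A", 100, 50, 100, 0, True, False),   # dbSNP135 site removed
        ("BRAF", 205, "T", "A", 100, 4, 80, 0, False, False),    # alt reads 4 < 5
        ("BRAF", 206, "T", "A", 0, 0, 100, 0, False, False),     # zero tumor depth
    ]
    mutations = pd.DataFrame(
        mutation_rows,
        columns=[
            "gene",
            "position",
            "ref",
            "alt",
            "tumor_depth",
            "tumor_alt",
            "normal_depth",
            "normal_alt",
            "dbsnp135",
            "truth_keep",
        ],
    )
    return fusions, mutations, expr
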