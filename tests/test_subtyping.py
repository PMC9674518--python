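import numpy as np
import pandas as pd
import pytest

from conftest import exemplar_scores_bruteforce
from thyrotype.core_io import ExpressionMatrix, log2_transform, rng_for
from thyrotype.subtyping import (
    NMFResult,
    filter_genes,
    fit_consensus_nmf,
    nmf_multiplicative,
    ntp_classify,
    rank_exemplar_genes,
    select_markers,
)


class TestFilterGenes:
    def _matrix(self, rows: dict) -> ExpressionMatrix:
        return ExpressionMatrix(pd.DataFrame(rows, index=["s1", "s2", "s3"]).T)

    def test_low_expression_rule(self):
        fm = filter_genes(self._matrix({"g": [0.5, 0.5, 2.0]}))
        assert fm.n_retained == 0 and fm.n_removed_low_expression == 1

    def test_low_cv_rule(self):
        fm = filter_genes(self._matrix({"g": [10.0, 10.0, 10.0]}))
        assert fm.n_retained == 0 and fm.n_removed_low_cv == 1

    def test_high_cv_gene_retained(self):
        values = np.array([1.0, 1.0, 5.0])
        cv = values.std(ddof=1) / values.mean()  # independent recomputation
        assert cv >= 0.8
        fm = filter_genes(self._matrix({"g": list(values)}))
        assert fm.matrix.genes == ["g"]

    def test_zero_mean_gene_removed(self):
        fm = filter_genes(self._matrix({"g": [0.0, 0.0, 0.0]}))
        assert fm.n_retained == 0

    def test_provenance_counts_sum(self, nodules7):
        expr, _ = nodules7
        fm = filter_genes(expr)
        assert (
            fm.n_retained + fm.n_removed_low_expression + fm.n_removed_low_cv
            == fm.n_input_genes
        )


class TestNMF:
    def test_rank_one_matrix_factorizes_exactly(self):
        rng = rng_for(0, "test_rank1")
        v = np.outer(rng.uniform(1, 2, 30), rng.uniform(1, 2, 10))
        w, h, obj = nmf_multiplicative(v, k=1, rng=rng, max_iter=5000, tol=1e-12)
        assert np.linalg.norm(v - w @ h) < 1e-6

    def test_objective_monotone_nonincreasing_every_iteration(self):
        rng = rng_for(1, "test_monotone")
        v = rng.uniform(0, 5, size=(40, 15))
        _, _, obj = nmf_multiplicative(v, k=4, rng=rng, max_iter=300, tol=0.0)
        assert all(b <= a + 1e-9 for a, b in zip(obj, obj[1:]))

    def test_block_diagonal_consensus_is_exact(self):
        blocks = np.zeros((30, 18))
        for b in range(3):
            blocks[b * 10 : (b + 1) * 10, b * 6 : (b + 1) * 6] = 5.0
        m = ExpressionMatrix(
            pd.DataFrame(
                blocks,
                index=[f"g{i}" for i in range(30)],
                columns=[f"s{j}" for j in range(18)],
            )
        )
        res = fit_consensus_nmf(m, k=3, restarts=10, seed=0)
        consensus = res.consensus.to_numpy()
        truth = np.repeat(np.arange(3), 6)
        expected = (truth[:, None] == truth[None, :]).astype(float)
        assert np.array_equal(consensus, expected)
        assert res.cophenetic == pytest.approx(1.0)

    def test_same_seed_identical_factors(self, nodules7):
        expr, _ = nodules7
        log2m = log2_transform(filter_genes(expr).matrix)
        a = fit_consensus_nmf(log2m, k=3, restarts=3, seed=5, max_iter=200)
        b = fit_consensus_nmf(log2m, k=3, restarts=3, seed=5, max_iter=200)
        pd.testing.assert_frame_equal(a.w, b.w)
        pd.testing.assert_frame_equal(a.h, b.h)

    def test_rank_exceeding_dimensions_rejected(self):
        rng = rng_for(2, "test_bad_k")
        with pytest.raises(ValueError, match="rank"):
            nmf_multiplicative(np.ones((4, 4)), k=5, rng=rng)

    def test_consensus_symmetric_unit_diagonal(self, nodules7):
        expr, _ = nodules7
        log2m = log2_transform(filter_genes(expr).matrix)
        res = fit_consensus_nmf(log2m, k=3, restarts=5, seed=1, max_iter=200)
        c = res.consensus.to_numpy()
        assert np.array_equal(c, c.T)
        assert np.all(np.diag(c) == 1.0)
        assert c.min() >= 0.0 and c.max() <= 1.0


class TestExemplarRanking:
    def _result(self, w: np.ndarray) -> NMFResult:
        genes = [f"g{i + 1}" for i in range(w.shape[0])]
        factors = [f"F{i + 1}" for i in range(w.shape[1])]
        return NMFResult(
            w=pd.DataFrame(w, index=genes, columns=factors),
            h=pd.DataFrame(np.ones((w.shape[1], 2)), index=factors),
            k=w.shape[1],
            objectives=[0.0],
            consensus=pd.DataFrame(np.eye(2)),
            cophenetic=1.0,
        )

    def test_margin_formula_orders_genes(self):
        res = self._result(np.array([[5.0, 1.0], [1.0, 5.0], [3.0, 3.0]]))
        first = rank_exemplar_genes(res, 0)
        assert first["gene"].tolist() == ["g1", "g3", "g2"]
        assert first["score"].tolist() == [4.0, 0.0, -4.0]
        second = rank_exemplar_genes(res, 1)
        assert second["gene"].tolist() == ["g2", "g3", "g1"]

    def test_matches_bruteforce_on_random_loadings(self):
        rng = rng_for(3, "test_exemplar_oracle")
        w = rng.uniform(0, 1, size=(50, 4))
        res = self._result(w)
        for factor in range(4):
            ranked = rank_exemplar_genes(res, factor)
            oracle = exemplar_scores_bruteforce(w, factor)
            expected = (
                pd.DataFrame({"gene": res.w.index, "score": oracle})
                .sort_values(["score", "gene"], ascending=[False, True])["gene"]
                .tolist()
            )
            assert ranked["gene"].tolist() == expected

    def test_single_factor_has_no_other_factor(self):
        res = self._result(np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            rank_exemplar_genes(res, 0)


class TestSelectMarkers:
    def test_planted_markers_recovered_with_controlled_fpr(self):
        from thyrotype.synthetic_data import SimulationSpec, simulate_cohort

        spec = SimulationSpec(seed=7, noise_sd=0.3, markers_per_subtype=5, n_genes=200)
        cohort = simulate_cohort(spec)
        nod = cohort.samples[cohort.samples.tissue == "nodule"]
        log2m = log2_transform(cohort.expression.subset_samples(nod.sample_id.tolist()))
        truth = cohort.marker_sets["S1"]
        inert = cohort.expression.genes[-20:]  # baseline-only genes
        table = select_markers(
            log2m, nod.true_subtype, "S1", truth + inert,
            n_permutations=99, seed=7, n_trees=60,
        )
        selected = set(table.loc[table.selected, "gene"])
        assert set(truth) <= selected  # every planted marker found
        fpr = len(selected - set(truth)) / len(inert)
        assert fpr <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(inert))
        # add-one permutation formula: beating all 99 nulls gives p = 0.01
        assert table.p_value.min() == pytest.approx(1.0 / 100.0)

    def test_constant_feature_never_selected(self):
        rng = rng_for(9, "test_const_feature")
        genes = ["flat", "signal"]
        n = 40
        y = np.repeat(["A", "B"], n // 2)
        # flat gene constant, signal gene separates the classes
        values = np.vstack(
            [np.ones(n), np.where(y == "A", 5.0, 1.0) + 0.05 * rng.uniform(size=n)]
        )
        m = ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=[f"s{i}" for i in range(n)])
        )
        labels = pd.Series(y, index=m.samples)
        table = select_markers(m, labels, "A", genes, n_permutations=30, seed=1, n_trees=30)
        flat = table.set_index("gene").loc["flat"]
        assert flat.p_value == 1.0 and not flat.selected


class TestNTP:
    def _cohort(self) -> ExpressionMatrix:
        # s1's standardized profile is exactly the A template direction
        return ExpressionMatrix(
            pd.DataFrame(
                {"s1": [2.0, 2.0, 1.0, 1.0], "s2": [1.0, 1.0, 1.0, 1.0], "s3": [0.0, 0.0, 1.0, 1.0]},
                index=["g1", "g2", "g3", "g4"],
            )
        )

    def test_template_match_has_zero_distance(self):
        res = ntp_classify(
            self._cohort(), {"A": ["g1", "g2"], "B": ["g3", "g4"]}, n_permutations=50, seed=0
        )
        assert res.loc["s1", "predicted"] == "A"
        assert res.loc["s1", "distance_A"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_sample_tie_flagged_low_confidence(self):
        res = ntp_classify(
            self._cohort(), {"A": ["g1", "g2"], "B": ["g3", "g4"]}, n_permutations=50, seed=0
        )
        # s2 sits at the cohort mean: all distances 1, tie broken by name order
        assert res.loc["s2", "predicted"] == "A"
        assert bool(res.loc["s2", "low_confidence"])

    def test_all_markers_missing_for_subtype_errors(self):
        with pytest.raises(ValueError, match="B"):
            ntp_classify(self._cohort(), {"A": ["g1"], "B": ["nope"]}, n_permutations=10)

    def test_heldout_cohort_agreement(self, cohort7, nodules7):
        from thyrotype.synthetic_data import SimulationSpec, simulate_cohort

        expr, nod = nodules7
        log2m = log2_transform(expr)
        markers = {s: cohort7.marker_sets[s] for s in cohort7.marker_sets.names()}
        held = simulate_cohort(SimulationSpec(seed=101))
        hnod = held.samples[held.samples.tissue == "nodule"]
        hexpr = log2_transform(held.expression.subset_samples(hnod.sample_id.tolist()))
        res = ntp_classify(hexpr, markers, n_permutations=100, seed=0)
        agreement = (
            res.loc[hnod.sample_id, "predicted"].to_numpy() == hnod.true_subtype.to_numpy()
        ).mean()
        assert agreement >= 0.9
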