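import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pinnet.interpret import (
    attribute_genes,
    attribute_pathway_nodes,
    balanced_reference,
    feature_selection_experiment,
    importance_scores,
    known_gene_test,
    size_importance_correlation,
)
from pinnet.model import PINNet, PINNetConfig
from pinnet.pathways import MaskMatrix, normalization_vector
from pinnet.train import TrainOptions


def make_attr(node_ids, C):
    from pinnet.interpret import AttributionResult

    C = np.asarray(C, dtype=float)
    return AttributionResult(node_ids, C, C.sum(axis=1), 0.0)


class TestBalancedReference:
    def test_equal_class_counts(self, toy_model):
        rng = np.random.default_rng(0)
        X = rng.random((100, 3))
        y = np.array([1] * 30 + [0] * 70)
        ref, _ = balanced_reference(toy_model, X, y, size=10, seed=1)
        assert ref.shape == (10, 3)
        # first half drawn from class 0 rows, second from class 1 rows
        assert all(any(np.array_equal(r, x) for x in X[y == 0]) for r in ref[:5])
        assert all(any(np.array_equal(r, x) for x in X[y == 1]) for r in ref[5:])

    def test_reference_output_matches_forward_mean(self, toy_model):
        rng = np.random.default_rng(1)
        X = rng.random((40, 3))
        y = np.array([0, 1] * 20)
        ref, ybar = balanced_reference(toy_model, X, y, size=8, seed=2)
        np.testing.assert_allclose(ybar, toy_model.forward(ref)[:, 1].mean())

    def test_same_seed_identical(self, toy_model):
        X = np.random.default_rng(2).random((30, 3))
        y = np.array([0, 1] * 15)
        r1, _ = balanced_reference(toy_model, X, y, size=6, seed=3)
        r2, _ = balanced_reference(toy_model, X, y, size=6, seed=3)
        np.testing.assert_array_equal(r1, r2)

    def test_oversized_request_rejected(self, toy_model):
        X = np.random.default_rng(3).random((10, 3))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            balanced_reference(toy_model, X, y, size=6)


class TestGeneAttribution:
    def test_summation_to_delta_exact(self, toy_model):
        rng = np.random.default_rng(4)
        X_eval, ref = rng.random((7, 3)), rng.random((9, 3))
        res = attribute_genes(toy_model, X_eval, ref)
        assert res.completeness_error().max() < 1e-10
        np.testing.assert_allclose(res.y, toy_model.forward(X_eval)[:, 1], atol=1e-12)

    def test_identical_eval_and_single_reference_gives_zero(self, toy_model):
        x = np.random.default_rng(5).random((1, 3))
        res = attribute_genes(toy_model, x, x)
        np.testing.assert_array_equal(res.C, np.zeros_like(res.C))

    def test_dead_input_gets_exact_zero(self):
        # gene g3 in no pathway and with its fully-connected column zeroed
        M = np.array([[1.0, 1.0, 0.0]])
        mask = MaskMatrix(M, ["P"], ["g1", "g2", "g3"],
                          normalization_vector(M, "inverse_sqrt"), "inverse_sqrt")
        model = PINNet(PINNetConfig(3, 1, n_fc_nodes=4, seed=6), mask)
        model.params["Wf"][:, 2] = 0.0
        rng = np.random.default_rng(7)
        res = attribute_genes(model, rng.random((5, 3)), rng.random((8, 3)))
        np.testing.assert_array_equal(res.C[:, 2], np.zeros(5))
        assert res.completeness_error().max() < 1e-10

    def test_near_linear_model_matches_jacobian_closed_form(self, toy_mask):
        """Shrinking all weights puts every nonlinearity in its linear regime,
        where the contribution of gene j must reduce to (dy/dx_j)(x_j - xbar_j)."""
        model = PINNet(PINNetConfig(3, 2, n_fc_nodes=4, n_hidden=5, seed=8), toy_mask)
        # branch weights shrunk below the layer-norm epsilon scale so the
        # normalization itself becomes an (approximately) fixed affine map
        model.params["Wp"] = model.params["Wp"] * 1e-6
        model.params["Wf"] = model.params["Wf"] * 1e-6
        model.params["Wh"] = model.params["Wh"] * 1e-3
        model.params["Wo"] = model.params["Wo"] * 1e-3
        rng = np.random.default_rng(9)
        x = rng.random((1, 3))
        xbar = rng.random((1, 3))
        res = attribute_genes(model, x, xbar)
        # closed-form linear map of the linearized network: tanh -> identity,
        # layer norm -> centering scaled by sqrt(eps), softmax -> slope 1/4
        from pinnet.model import LN_EPS

        p = model.params
        m, nfc = 2, 4

        def centering(k):
            return np.eye(k) - np.ones((k, k)) / k

        Bp = np.diag(p["ln_p_gamma"] / np.sqrt(LN_EPS)) @ centering(m) @ np.diag(model.u) @ (
            p["Wp"] * model.M
        )
        Bf = np.diag(p["ln_f_gamma"] / np.sqrt(LN_EPS)) @ centering(nfc) @ p["Wf"]
        a = 0.25 * (p["Wo"][1] - p["Wo"][0]) @ p["Wh"] @ np.vstack([Bp, Bf])
        np.testing.assert_allclose(res.C[0], a * (x - xbar)[0], rtol=1e-3)


class TestPathwayNodeAttribution:
    def test_completeness_over_concatenated_layer(self, toy_model):
        rng = np.random.default_rng(10)
        res = attribute_pathway_nodes(toy_model, rng.random((6, 3)), rng.random((10, 3)))
        assert res.completeness_error().max() < 1e-10
        assert res.n_primary == 2 and res.C.shape == (6, 6)

    def test_identical_eval_and_reference_zero(self, toy_model):
        x = np.random.default_rng(11).random((1, 3))
        res = attribute_pathway_nodes(toy_model, x, x)
        np.testing.assert_array_equal(res.C, np.zeros_like(res.C))

    def test_fully_disconnected_branch_gets_zero(self, toy_model):
        """Severing every pathway column of the hidden layer removes all
        influence of the pathway branch (including through its normalization
        statistics), so each pathway node's attribution is exactly zero."""
        m = toy_model.config.n_pathways
        toy_model.params["Wh"][:, :m] = 0.0
        rng = np.random.default_rng(12)
        res = attribute_pathway_nodes(toy_model, rng.random((4, 3)), rng.random((6, 3)))
        np.testing.assert_array_equal(res.C[:, :m], np.zeros((4, m)))
        assert res.completeness_error().max() < 1e-10

    def test_severed_node_keeps_only_normalization_coupling(self, toy_model):
        """A node severed from the head (its hidden-layer column zeroed) still
        shifts its branch's layer-norm statistics, so its attribution need not
        vanish -- but it must stay well below the connected nodes' share."""
        toy_model.params["Wh"][:, 0] = 0.0
        rng = np.random.default_rng(12)
        res = attribute_pathway_nodes(toy_model, rng.random((20, 3)), rng.random((6, 3)))
        assert res.completeness_error().max() < 1e-10
        severed = np.abs(res.C[:, 0]).mean()
        connected = np.abs(res.C[:, 1]).mean()
        assert severed < connected


class TestImportanceScores:
    def test_two_fold_arithmetic_oracle(self):
        # fold scores s = mean |C| per node; z = (s - mean)/sd; importance = mean z
        f1 = make_attr(["a", "b", "c"], [[1.0, -2.0, 3.0], [1.0, 2.0, -3.0]])
        f2 = make_attr(["a", "b", "c"], [[0.0, 4.0, 2.0]])
        table = importance_scores([f1, f2])
        for fold, res in zip(("fold_0", "fold_1"), (f1, f2)):
            s = np.abs(res.C).mean(axis=0)
            z = (s - s.mean()) / s.std()
            np.testing.assert_allclose(table[fold].to_numpy(), z)
        np.testing.assert_allclose(
            table["importance_score"], (table["fold_0"] + table["fold_1"]) / 2
        )

    def test_identical_folds_equal_single_fold_z(self):
        f = make_attr(["a", "b"], [[1.0, 5.0]])
        t1 = importance_scores([f])
        t3 = importance_scores([f, f, f])
        np.testing.assert_allclose(t1["importance_score"], t3["importance_score"])

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        C = rng.normal(size=(4, 6))
        ids = [f"n{i}" for i in range(6)]
        perm = rng.permutation(6)
        t = importance_scores([make_attr(ids, C)])
        tp = importance_scores([make_attr([ids[i] for i in perm], C[:, perm])])
        np.testing.assert_allclose(
            t["importance_score"].loc[ids], tp["importance_score"].loc[ids]
        )

    def test_constant_scores_rejected(self):
        f = make_attr(["a", "b"], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            importance_scores([f])


class TestKnownGeneTest:
    def test_extreme_separation_is_significant(self):
        table = pd.DataFrame(
            {"importance_score": [3.0, 3.1, 3.2, 3.3, 3.4] + [0.0] * 30},
            index=[f"g{i}" for i in range(35)],
        )
        res = known_gene_test(table, {f"g{i}" for i in range(5)})
        assert res.p_one_sided < 0.001
        assert res.direction == "known_higher"

    def test_u_statistic_matches_pair_counting(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=40)
        table = pd.DataFrame({"importance_score": scores},
                             index=[f"g{i}" for i in range(40)])
        known = {f"g{i}" for i in range(12)}
        res = known_gene_test(table, known)
        a, b = scores[:12], scores[12:]
        brute = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
        assert res.U == brute

    def test_null_pvalues_uniform(self):
        """With exchangeable scores the two-sided p-value should be uniform."""
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(1000):
            scores = rng.normal(size=40)
            table = pd.DataFrame({"importance_score": scores},
                                 index=[f"g{i}" for i in range(40)])
            pvals.append(known_gene_test(table, {f"g{i}" for i in range(10)}).p_two_sided)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"importance_score": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            known_gene_test(table, {"zzz"})


class TestSizeImportanceCorrelation:
    @staticmethod
    def random_mask(m, n, seed):
        rng = np.random.default_rng(seed)
        M = (rng.random((m, n)) < 0.2).astype(float)
        M[M.sum(axis=1) == 0, 0] = 1.0
        names = [f"P{i}" for i in range(m)]
        return MaskMatrix(M, names, [f"g{j}" for j in range(n)],
                          normalization_vector(M, "inverse_sqrt"), "inverse_sqrt")

    def test_proportional_importance_gives_r_one(self):
        mask = self.random_mask(20, 50, 16)
        table = pd.DataFrame({"importance_score": 2.0 * mask.sizes + 1.0},
                             index=mask.pathway_names)
        assert size_importance_correlation(mask, table) == pytest.approx(1.0)

    def test_independent_importance_gives_small_mean_abs_r(self):
        mask = self.random_mask(500, 100, 17)
        rng = np.random.default_rng(18)
        rs = []
        for _ in range(100):
            table = pd.DataFrame({"importance_score": rng.normal(size=500)},
                                 index=mask.pathway_names)
            rs.append(abs(size_importance_correlation(mask, table)))
        assert np.mean(rs) < 0.1

    def test_matches_textbook_formula_on_hand_example(self):
        M = np.zeros((5, 10))
        sizes = [2, 4, 5, 7, 9]
        for i, s in enumerate(sizes):
            M[i, :s] = 1.0
        mask = MaskMatrix(M, list("ABCDE"), [f"g{j}" for j in range(10)],
                          normalization_vector(M, "none"), "none")
        imp = np.array([1.0, 0.5, 2.0, 1.5, 3.0])
        table = pd.DataFrame({"importance_score": imp}, index=list("ABCDE"))
        x = np.array(sizes, dtype=float)
        manual = ((x - x.mean()) * (imp - imp.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((imp - imp.mean()) ** 2).sum()
        )
        assert size_importance_correlation(mask, table) == pytest.approx(manual)

    def test_too_few_pathways_rejected(self):
        mask = self.random_mask(2, 10, 19)
        table = pd.DataFrame({"importance_score": [1.0, 2.0]}, index=mask.pathway_names)
        with pytest.raises(ValueError):
            size_importance_correlation(mask, table)


class TestFeatureSelection:
    def test_full_fraction_reduces_to_all_genes(self, small_benchmark):
        dataset, mask, _, _ = small_benchmark
        df = feature_selection_experiment(
            dataset, mask, fraction=1.0, seed=0,
            opts=TrainOptions(max_epochs=15), n_repeats=3,
        )
        counts = df.pivot(index="repeat", columns="arm", values="n_genes")
        assert (counts["selected"] == dataset.n_genes).all()
        assert (counts["all"] == dataset.n_genes).all()

    def test_tiny_fraction_rejected(self, small_benchmark):
        dataset, mask, _, _ = small_benchmark
        with pytest.raises(ValueError):
            feature_selection_experiment(dataset, mask, fraction=0.001)

    def test_selected_genes_beat_random_on_planted_signal(self, small_benchmark):
        """Importance-ranked genes should outperform size-matched random gene
        sets in most repeats when a true signal is planted."""
        dataset, mask, _, _ = small_benchmark
        df = feature_selection_experiment(
            dataset, mask, fraction=0.10, seed=1,
            opts=TrainOptions(max_epochs=40), n_repeats=10,
        )
        wide = df.pivot(index="repeat", columns="arm", values="auc")
        wins = (wide["selected"] >= wide["random"]).sum()
        assert wins >= 7
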