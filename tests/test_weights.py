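import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import KFold

from vctwas.genotype_io import GenotypeMatrix
from vctwas.weights import (
    ExpressionVector,
    WeightSet,
    align_weights,
    filter_weights,
    fit_eb_dense_weights,
    fit_elastic_net_weights,
    fit_ridge_standin_weights,
    gene_passes_cv_filter,
    read_weight_file,
    ridge_lambda_grid,
    write_weight_file,
)

from conftest import make_genotype_matrix


# ---------------------------------------------------------------- elastic net


class TestElasticNet:
    def test_null_expression_mostly_zero_weights(self):
        # null-simulation oracle: expression independent of all SNPs
        rng = np.random.default_rng(5)
        geno = make_genotype_matrix(rng, 500, 100)
        zero_fracs, r2s = [], []
        for rep in range(50):
            e = ExpressionVector(list(geno.sample_ids), rng.standard_normal(500))
            ws = fit_elastic_net_weights(e, geno, seed=rep)
            zero_fracs.append(float((ws.weights == 0).mean()))
            r2s.append(ws.cv_r2)
        assert np.mean(zero_fracs) >= 0.95
        assert np.mean(r2s) <= 0.01
        both = [z >= 0.90 and r <= 0.02 for z, r in zip(zero_fracs, r2s)]
        assert sum(both) >= 45

    def test_single_causal_snp_recovered(self):
        rng = np.random.default_rng(6)
        geno = make_genotype_matrix(rng, 500, 50)
        hits = 0
        for rep in range(50):
            e_vals = geno.dosages[:, 3] * 1.0 + rng.normal(0, 0.5, 500)
            ws = fit_elastic_net_weights(
                ExpressionVector(list(geno.sample_ids), e_vals), geno, seed=rep
            )
            hits += ws.weights[3] > 0
        assert hits >= 48  # >= 95% of replicates

    def test_max_penalty_shrinks_everything(self, rng, small_geno, expression_for):
        e = expression_for(small_geno)
        ws = fit_elastic_net_weights(e, small_geno, alphas=np.array([1e6]))
        assert np.all(ws.weights == 0)

    def test_constant_expression_gives_zero_weights(self, small_geno):
        e = ExpressionVector(list(small_geno.sample_ids), np.ones(small_geno.n_samples))
        ws = fit_elastic_net_weights(e, small_geno)
        assert np.all(ws.weights == 0)
        assert ws.cv_r2 == 0.0

    def test_objective_not_worse_than_zero_vector(self, rng):
        geno = make_genotype_matrix(rng, 120, 20)
        w_true = np.zeros(20)
        w_true[[2, 7]] = (0.8, -0.5)
        e_vals = geno.dosages @ w_true + rng.normal(0, 0.5, 120)
        ws = fit_elastic_net_weights(
            ExpressionVector(list(geno.sample_ids), e_vals), geno, seed=0
        )
        gc = geno.centered_dosages()
        ec = e_vals - e_vals.mean()

        def loss(w):  # fitting objective at mixing 0.5 (penalty term >= 0)
            return 0.5 * np.sum((ec - gc @ w) ** 2) / len(ec)

        assert loss(ws.weights) <= loss(np.zeros(20))

    def test_misaligned_samples_raise(self, small_geno):
        e = ExpressionVector(["nope"] * small_geno.n_samples, np.zeros(small_geno.n_samples))
        with pytest.raises(ValueError):
            fit_elastic_net_weights(e, small_geno)

    def test_deterministic_given_seed(self, rng, small_geno, expression_for):
        e = expression_for(small_geno)
        w1 = fit_elastic_net_weights(e, small_geno, seed=3).weights
        w2 = fit_elastic_net_weights(e, small_geno, seed=3).weights
        np.testing.assert_array_equal(w1, w2)


# ---------------------------------------------------------------- ridge stand-in


class TestRidgeStandin:
    def test_orthogonal_design_shrinks_towards_zero(self):
        # closed-form ridge on an orthogonal design: w_j between 0 and OLS_j
        n = 8
        base = np.array([[1, 1, 1, 1, -1, -1, -1, -1], [1, 1, -1, -1, 1, 1, -1, -1]]).T
        dos = (base + 1.0) / 2.0 * 2.0  # map to [0, 2]
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(n)], ["1:1:A:G", "1:2:A:G"], [1, 2], dos
        )
        rng = np.random.default_rng(1)
        e_vals = dos @ np.array([0.7, -0.4]) + rng.normal(0, 0.3, n)
        ws = fit_ridge_standin_weights(
            ExpressionVector(list(geno.sample_ids), e_vals), geno, folds=2
        )
        gc = geno.centered_dosages()
        ec = e_vals - e_vals.mean()
        ols = gc.T @ ec / (gc**2).sum(axis=0)
        for w, b in zip(ws.weights, ols):
            assert np.sign(w) == np.sign(b)
            assert 0 < abs(w) < abs(b)

    def test_null_weights_smaller_than_causal(self):
        rng = np.random.default_rng(2)
        geno = make_genotype_matrix(rng, 300, 50)
        ratio_num, ratio_den = [], []
        for rep in range(5):
            e_null = rng.standard_normal(300)
            e_causal = geno.dosages[:, 0] * 1.0 + rng.normal(0, 0.5, 300)
            w_null = fit_ridge_standin_weights(
                ExpressionVector(list(geno.sample_ids), e_null), geno, seed=rep
            ).weights
            w_causal = fit_ridge_standin_weights(
                ExpressionVector(list(geno.sample_ids), e_causal), geno, seed=rep
            ).weights
            ratio_num.append(np.abs(w_null).max())
            ratio_den.append(np.abs(w_causal).max())
        assert np.mean(ratio_den) >= 5 * np.mean(ratio_num)

    def test_single_snp_matches_hand_computed_shrinkage(self):
        # independent re-implementation of the grid + CV selection at m=1
        rng = np.random.default_rng(3)
        n = 40
        g = rng.binomial(2, 0.4, n).astype(float)
        e = 0.6 * g + rng.normal(0, 0.5, n)
        geno = GenotypeMatrix([f"s{i}" for i in range(n)], ["1:1:A:G"], [1], g[:, None])
        ws = fit_ridge_standin_weights(
            ExpressionVector(list(geno.sample_ids), e), geno, seed=9
        )

        gc = (g - g.mean())[:, None]
        grid = ridge_lambda_grid(gc)
        mse = np.zeros(len(grid))
        for tr, te in KFold(5, shuffle=True, random_state=9).split(gc):
            mu_g, mu_e = g[tr].mean(), e[tr].mean()
            gtr, etr = g[tr] - mu_g, e[tr] - mu_e
            for i, lam in enumerate(grid):
                w = (gtr @ etr) / (gtr @ gtr + lam)
                mse[i] += np.sum((e[te] - (mu_e + (g[te] - mu_g) * w)) ** 2)
        lam_star = grid[np.argmin(mse)]
        ec = e - e.mean()
        w_hand = float(gc[:, 0] @ ec) / (float(gc[:, 0] @ gc[:, 0]) + lam_star)
        assert ws.weights[0] == pytest.approx(w_hand, rel=1e-10)

    def test_dense_output(self, rng, small_geno, expression_for):
        e = expression_for(small_geno, weights=[0.5] + [0.0] * (small_geno.m_snps - 1))
        ws = fit_ridge_standin_weights(e, small_geno)
        assert ws.method_tag == "ridge_standin"
        assert np.all(ws.weights != 0)


class TestEBDense:
    def test_dense_and_heavy_tailed(self):
        rng = np.random.default_rng(4)
        geno = make_genotype_matrix(rng, 400, 200)
        w_true = np.zeros(200)
        w_true[rng.choice(200, 20, replace=False)] = rng.normal(0, 0.3, 20)
        e_vals = geno.dosages @ w_true + rng.standard_normal(400)
        ws = fit_eb_dense_weights(
            ExpressionVector(list(geno.sample_ids), e_vals), geno
        )
        aw = np.abs(ws.weights)
        assert np.all(aw > 0)  # dense: every SNP weighted
        assert np.quantile(aw, 0.99) > 5 * np.median(aw)  # most shrunk near zero

    def test_deterministic(self, small_geno, expression_for):
        e = expression_for(small_geno)
        w1 = fit_eb_dense_weights(e, small_geno).weights
        w2 = fit_eb_dense_weights(e, small_geno).weights
        np.testing.assert_array_equal(w1, w2)

    def test_constant_expression(self, small_geno):
        e = ExpressionVector(list(small_geno.sample_ids), np.full(small_geno.n_samples, 2.0))
        ws = fit_eb_dense_weights(e, small_geno)
        assert np.all(ws.weights == 0) and ws.cv_r2 == 0.0


# ---------------------------------------------------------------- filtering


def _ws(weights, gene="G1"):
    w = np.asarray(weights, dtype=float)
    return WeightSet(gene, [f"1:{i + 1}:A:G" for i in range(len(w))], w)


class TestFilterWeights:
    def test_magnitude_threshold(self):
        out = filter_weights(_ws([2e-4, 5e-5, 1e-3, 0.0]), "magnitude_threshold", 1e-4)
        assert out.snp_ids == ["1:1:A:G", "1:3:A:G"]
        np.testing.assert_array_equal(out.weights, [2e-4, 1e-3])

    def test_per_gene_median(self):
        out = filter_weights(_ws([1.0, 2.0, 3.0, 4.0]), "per_gene_median")
        np.testing.assert_array_equal(out.weights, [3.0, 4.0])

    def test_median_keeps_about_half_of_dense_weights(self):
        rng = np.random.default_rng(0)
        ws = _ws(rng.normal(0, 1, 501))
        out = filter_weights(ws, "per_gene_median")
        assert out.m_snps / ws.m_snps == pytest.approx(0.5, abs=0.01)

    def test_median_uses_magnitudes(self):
        out = filter_weights(_ws([-5.0, -0.1, 0.2, 4.0]), "per_gene_median")
        np.testing.assert_array_equal(out.weights, [-5.0, 4.0])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_weights(_ws([1.0]), "magnitude_threshold", -1.0)

    def test_empty_weight_set_rejected(self):
        with pytest.raises(ValueError):
            filter_weights(_ws([]), "per_gene_median")

    def test_empty_result_allowed(self):
        out = filter_weights(_ws([0.1, 0.2]), "magnitude_threshold", 1.0)
        assert out.m_snps == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30))
    def test_median_filter_idempotent_and_bounded(self, weights):
        ws = _ws(weights)
        once = filter_weights(ws, "per_gene_median")
        assert once.m_snps <= int(np.ceil(ws.m_snps / 2))
        if once.m_snps:
            twice = filter_weights(once, "per_gene_median")
            # retained weights unchanged; re-filter of a filtered set applies
            # the *new* median, so idempotence is asserted for the threshold mode
        thr = filter_weights(ws, "magnitude_threshold", 0.5)
        if thr.m_snps:
            again = filter_weights(thr, "magnitude_threshold", 0.5)
            np.testing.assert_array_equal(thr.weights, again.weights)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
           st.floats(0, 2))
    def test_threshold_filter_preserves_retained_values(self, weights, thr):
        ws = _ws(weights)
        out = filter_weights(ws, "magnitude_threshold", thr)
        kept = {s: w for s, w in zip(out.snp_ids, out.weights)}
        for s, w in zip(ws.snp_ids, ws.weights):
            if abs(w) > thr:
                assert kept[s] == w
            else:
                assert s not in kept


class TestCvFilter:
    def test_examples(self):
        make = lambda r2: WeightSet("g", [], [], cv_r2=r2)
        assert gene_passes_cv_filter(make(0.006)) is True
        assert gene_passes_cv_filter(make(0.005)) is False  # strict inequality
        assert gene_passes_cv_filter(make(-0.02), make(0.2)) is True
        assert gene_passes_cv_filter(make(-0.02), make(0.001)) is False


# ---------------------------------------------------------------- IO & matching


class TestWeightIO:
    def test_round_trip(self, tmp_path):
        ws = WeightSet("GENE1", ["1:100:A:G", "1:200:C:T"], [0.25, -1e-7],
                       method_tag="elastic_net", cv_r2=0.031)
        path = tmp_path / "w.tsv"
        write_weight_file(ws, path)
        back = read_weight_file(path)["GENE1"]
        assert back.snp_ids == ws.snp_ids
        np.testing.assert_allclose(back.weights, ws.weights, atol=1e-12)
        assert back.cv_r2 == pytest.approx(ws.cv_r2, abs=1e-12)

    def test_multi_gene_file(self, tmp_path):
        sets = [
            WeightSet("A", ["1:1:A:G"], [0.1]),
            WeightSet("B", ["1:2:C:T", "1:3:A:C"], [0.2, 0.3]),
        ]
        path = tmp_path / "w.tsv"
        write_weight_file(sets, path)
        back = read_weight_file(path)
        assert list(back) == ["A", "B"]
        assert back["B"].m_snps == 2

    def test_align_flips_sign_on_swapped_alleles(self, rng):
        geno = make_genotype_matrix(rng, 10, 3)  # snps at 1000,2000,3000 A/G
        ws = WeightSet("G", ["1:1000:G:A", "1:2000:A:G", "1:3000:C:T"], [0.5, 0.2, 0.9])
        matched, idx = align_weights(ws, geno)
        assert matched.snp_ids == ["1:1000:A:G", "1:2000:A:G"]
        np.testing.assert_allclose(matched.weights, [-0.5, 0.2])  # flip, keep
        np.testing.assert_array_equal(idx, [0, 1])  # allele mismatch dropped
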