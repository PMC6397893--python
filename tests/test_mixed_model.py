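import numpy as np
import pytest

import omicblup as ob
from omicblup import mixed_model as mm
from omicblup.types import KernelMatrix

import oracles


def _panel(n_lines, n_markers=200, n_genes=40, seed=0, **shares):
    cfg = ob.SimulationConfig(n_lines=n_lines, n_markers=n_markers,
                              n_genes=n_genes, seed=seed, **shares)
    ds, truth = ob.simulate_dataset(cfg)
    return ds, truth


class TestRemlFit:
    def test_pure_noise_gives_near_zero_genetic_ratio(self):
        ds, _ = _panel(500, n_markers=400,
                       additive_share=0.0, mediated_share=0.0,
                       residual_share=1.0, seed=21)
        y, _ = ds.phenotype("trait")
        [G] = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gblup"))
        fit = mm.reml_fit(y, [G])
        sg = fit.varcomp.components["G"]
        assert sg / (sg + fit.varcomp.residual) < 0.05

    def test_attains_grid_oracle_maximum(self):
        ds, _ = _panel(30, n_markers=120, n_genes=10, seed=0,
                       additive_share=0.5, mediated_share=0.0,
                       residual_share=0.5)
        y, _ = ds.phenotype("trait")
        [G] = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gblup"))
        fit = mm.reml_fit(y, [G])
        ll_grid, _ = oracles.grid_maximize(y, G.values)
        assert fit.loglik >= ll_grid - 1e-4

    def test_constant_phenotype_rejected(self):
        K = KernelMatrix(np.eye(12), [f"l{i}" for i in range(12)], "G")
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            mm.reml_fit(np.ones(12), [K])

    def test_identical_kernels_identify_only_the_sum(self):
        ds, _ = _panel(80, seed=13)
        y, _ = ds.phenotype("trait")
        [G] = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gblup"))
        G2 = KernelMatrix(G.values.copy(), list(G.line_ids), "E")
        single = mm.reml_fit(y, [G])
        double = mm.reml_fit(y, [G, G2])
        assert double.converged
        s_sum = sum(double.varcomp.components.values())
        assert s_sum == pytest.approx(single.varcomp.components["G"], abs=1e-4)

    def test_loglik_invariant_to_kernel_order(self):
        ds, _ = _panel(70, seed=17)
        y, _ = ds.phenotype("trait")
        ks = mm.build_model_kernels(ds, mm.ModelSpec.from_name("grblup"))
        f1 = mm.reml_fit(y, ks)
        f2 = mm.reml_fit(y, ks[::-1])
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)

    def test_blups_lie_in_kernel_column_space(self):
        ds, _ = _panel(50, seed=19)
        y, _ = ds.phenotype("trait")
        [G] = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gblup"))
        fit = mm.reml_fit(y, [G])
        g_hat = fit.blups["G"]
        # solve G x = g_hat; residual should vanish within lstsq tolerance
        x, res, *_ = np.linalg.lstsq(G.values, g_hat, rcond=None)
        assert np.max(np.abs(G.values @ x - g_hat)) < 1e-8


class TestRidgeDuality:
    def test_tblup_blups_equal_ridge_predictions(self):
        ds, _ = _panel(60, seed=23)
        y, _ = ds.phenotype("trait")
        r = ob.standardize_expression(ds.expression)
        E = ob.linear_expression_kernel(r)
        fit = mm.reml_fit(y, [E])
        lam = fit.varcomp.residual / fit.varcomp.components["E"]
        beta = oracles.ridge_effects(r.values, y - fit.mu, lam)
        assert np.max(np.abs(fit.blups["E"] - r.values @ beta)) < 1e-6

    def test_gblup_blups_equal_ridge_with_vanraden_denominator(self):
        ds, _ = _panel(60, seed=29)
        y, _ = ds.phenotype("trait")
        g = ob.impute_mean(ds.genotypes)
        z = ob.center_genotypes(g)
        G = ob.vanraden_g(z)
        fit = mm.reml_fit(y, [G])
        denom = G.metadata["denominator"]
        lam = fit.varcomp.residual / fit.varcomp.components["G"] * denom
        beta = oracles.ridge_effects(z.Z, y - fit.mu, lam)
        assert np.max(np.abs(fit.blups["G"] - z.Z @ beta)) < 1e-6


class TestBlupPredict:
    def test_matches_henderson_mme_oracle(self):
        ds, _ = _panel(25, n_markers=150, seed=31)
        y, ids = ds.phenotype("trait")
        r = ob.standardize_expression(ds.expression)
        # moderate bandwidth keeps K positive definite AND well conditioned,
        # since the oracle must invert the full kernel explicitly
        K = ob.gaussian_kernel(r, h=0.3 * ob.mean_squared_distance(r))
        train = np.arange(20)
        test = np.arange(20, 25)
        fit = mm.reml_fit(y[train], [K.subset(train)])
        pred = mm.blup_predict(fit, [K], train, test)
        oracle = oracles.mme_predict(
            y[train], K.values, train, test,
            sigma_u=fit.varcomp.components["K"], sigma_e=fit.varcomp.residual)
        assert np.max(np.abs(pred - oracle)) < 1e-8

    def test_zero_components_predict_the_mean(self):
        rng = np.random.default_rng(0)
        n = 15
        K = KernelMatrix(np.eye(n), [f"l{i}" for i in range(n)], "G")
        y = rng.normal(size=10)
        fit = mm.FitResult(
            mu=2.5,
            varcomp=mm.VarianceComponents({"G": 0.0}, 1.0),
            blups={"G": np.zeros(10)}, loglik=0.0, iterations=0,
            converged=True, boundary={}, kernel_labels=("G",),
            line_ids=[f"l{i}" for i in range(10)], y=y)
        pred = mm.blup_predict(fit, [K], np.arange(10), np.arange(10, 15))
        assert np.allclose(pred, 2.5)

    def test_duplicated_line_limit_of_vanishing_noise(self):
        # test line identical to train line 0; sigma_e -> 0 makes the
        # prediction converge to that line's phenotype deviation plus mu
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(11, 6))
        vals[10] = vals[0]
        r = ob.StandardizedExpression(
            values=vals, line_ids=[f"l{i}" for i in range(11)],
            gene_ids=[f"g{j}" for j in range(6)],
            means=np.zeros(6), sds=np.ones(6))
        K = ob.gaussian_kernel(r, h=10.0)
        y = rng.normal(size=10)
        mu = y.mean()
        fit = mm.FitResult(
            mu=mu, varcomp=mm.VarianceComponents({"K": 1.0}, 1e-10),
            blups={"K": np.zeros(10)}, loglik=0.0, iterations=0,
            converged=True, boundary={}, kernel_labels=("K",),
            line_ids=[f"l{i}" for i in range(10)], y=y)
        pred = mm.blup_predict(fit, [K], np.arange(10), np.array([10]))
        assert pred[0] == pytest.approx(y[0], abs=1e-5)


class TestHeritability:
    def _fit(self, comps, resid, labels):
        return mm.FitResult(
            mu=0.0, varcomp=mm.VarianceComponents(comps, resid),
            blups={}, loglik=0.0, iterations=1, converged=True,
            boundary={}, kernel_labels=labels, line_ids=[], y=None)

    def test_gt_arithmetic(self):
        fit = self._fit({"G": 1.0, "E": 1.0}, 2.0, ("G", "E"))
        est = mm.heritability(fit)
        assert est.kind == "HGT2"
        assert est.value == pytest.approx(0.5)

    def test_omics_zero_reduces_to_narrow_sense(self):
        fit_g = self._fit({"G": 0.7}, 0.3, ("G",))
        h_narrow = mm.heritability(fit_g)
        h_omics = mm.heritability(fit_g, kind="Ho2")
        assert h_narrow.kind == "hG2"
        assert h_omics.value == h_narrow.value

    def test_zero_residual_boundary_is_one(self):
        fit = self._fit({"G": 0.5, "K": 0.2}, 0.0, ("G", "K"))
        assert mm.heritability(fit).value == 1.0
        assert mm.heritability(fit).kind == "HGR2"

    def test_all_zero_components_error(self):
        fit = self._fit({"G": 0.0}, 0.0, ("G",))
        with pytest.raises(ValueError, match="undefined"):
            mm.heritability(fit)


class TestScaleEquivariance:
    def test_components_scale_and_heritability_invariant(self):
        ds, _ = _panel(60, seed=37)
        y, _ = ds.phenotype("trait")
        ks = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gtblup"))
        f1 = mm.reml_fit(y, ks)
        f3 = mm.reml_fit(3.0 * y, ks)
        for lab in f1.varcomp.components:
            assert f3.varcomp.components[lab] == pytest.approx(
                9.0 * f1.varcomp.components[lab], rel=1e-6, abs=1e-10)
        assert mm.heritability(f3).value == pytest.approx(
            mm.heritability(f1).value, abs=1e-8)


class TestParameterRecoverySmall:
    def test_two_kernel_generative_model_recovered(self):
        """Draw y ~ N(1mu, sg G + sv K + se I) and recover the components.

        The generative bandwidth is half the mean squared distance: the
        Gaussian kernel then has enough spectral spread that all three
        components are identifiable (at much larger h it degenerates toward
        the constant matrix, at much smaller h toward the identity, and the
        K component is confounded with the intercept or the residual).
        """
        ds, _ = _panel(200, n_markers=500, n_genes=120, seed=41)
        r = ob.standardize_expression(ds.expression)
        G = mm.build_model_kernels(ds, mm.ModelSpec.from_name("gblup"))[0]
        Kk = ob.gaussian_kernel(r, 0.5 * ob.mean_squared_distance(r))
        ks = [G, Kk]
        G, K = (k.values for k in ks)
        true = {"G": 0.5, "K": 0.3, "e": 0.2}
        n = 200
        V = true["G"] * G + true["K"] * K + true["e"] * np.eye(n)
        L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(10):
            y = L @ rng.normal(size=n)
            fit = mm.reml_fit(y, ks)
            ests.append([fit.varcomp.components["G"],
                         fit.varcomp.components["K"],
                         fit.varcomp.residual])
        mean = np.mean(ests, axis=0)
        for est, tr in zip(mean, [true["G"], true["K"], true["e"]]):
            assert abs(est - tr) / tr < 0.35   # small-replicate smoke check
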