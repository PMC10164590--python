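"""Inverse-free solving: the phi system, projection, BLUEs, predictions
and marker-effect back-solving."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vblup as vb
from vblup.phenotypes import PhenotypeTable
from vblup.reml import VarianceComponents, build_V, component_names
from vblup.solve import estimate_fixed, project, solve_phi
from tests.conftest import random_instance, random_kernel


class TestSolvePhi:
    def test_identity_V_returns_inputs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        phi1, phi2, iters = solve_phi(np.eye(10), X, y, backend="pcg")
        np.testing.assert_allclose(phi1, X, atol=1e-10)
        np.testing.assert_allclose(phi2, y, atol=1e-10)
        assert iters <= 2

    def test_diagonal_V_is_elementwise_division(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.5, 2.0, size=12)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        phi1, phi2, _ = solve_phi(np.diag(d), X, y, backend="chol")
        np.testing.assert_allclose(phi1, X / d[:, None], atol=1e-12)
        np.testing.assert_allclose(phi2, y / d, atol=1e-12)

    @pytest.mark.parametrize("backend", ["lu", "pcg"])
    def test_backends_match_cholesky(self, backend):
        rng = np.random.default_rng(2)
        B = rng.normal(size=(30, 30))
        V = B @ B.T / 30 + 0.5 * np.eye(30)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        ref1, ref2, _ = solve_phi(V, X, y, backend="chol")
        alt1, alt2, _ = solve_phi(V, X, y, backend=backend, tol=1e-12)
        np.testing.assert_allclose(alt1, ref1, atol=1e-7)
        np.testing.assert_allclose(alt2, ref2, atol=1e-7)

    def test_pcg_iterations_bounded_by_dimension(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(40, 40))
        V = B @ B.T / 40 + 0.2 * np.eye(40)
        _, _, iters = solve_phi(V, rng.normal(size=(40, 2)),
                                rng.normal(size=40), backend="pcg")
        assert iters <= int(1.1 * 40)


class TestProjection:
    def test_intercept_identity_V_centres_y(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=15)
        X = np.ones((15, 1))
        Py = project(X, y, X)
        np.testing.assert_allclose(Py, y - y.mean(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_projection_matrix(self, seed):
        model, vc = random_instance(100 + seed, n=15)
        V = build_V(model, vc)
        X, y = model.X, model.y
        phi1, phi2, _ = solve_phi(V, X, y)
        Py = project(phi1, phi2, X)
        Vinv = np.linalg.inv(V)
        P = Vinv - Vinv @ X @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        np.testing.assert_allclose(Py, P @ y, atol=1e-10)

    def test_orthogonality_over_many_instances(self):
        for seed in range(100):
            model, vc = random_instance(200 + seed, n=10, with_env=False)
            V = build_V(model, vc)
            phi1, phi2, _ = solve_phi(V, model.X, model.y)
            Py = project(phi1, phi2, model.X)
            assert np.abs(model.X.T @ Py).max() < 1e-9


class TestFixedEffects:
    def test_identity_V_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fe = estimate_fixed(X, y, X)
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fe.estimates, ols, atol=1e-10)

    def test_wald_pvalues_uniform_under_null(self):
        """Covariate with zero effect: p-values pass a KS uniformity test."""
        rng = np.random.default_rng(6)
        n = 60
        pvals = []
        X_base = np.ones((n, 1))
        for rep in range(200):
            r = np.random.default_rng(3000 + rep)
            x = r.normal(size=n)
            X = np.column_stack([X_base, x])
            y = r.normal(size=n)  # x has zero true effect
            fe = estimate_fixed(X, y, X)
            pvals.append(fe.pvalues[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_joint_factor_test_reported(self):
        model, vc = random_instance(7, n=30)
        sol = vb.solve_mixed_model(model, vc)
        assert "sex" in sol.fixed.group_tests
        chi2, df, p = sol.fixed.group_tests["sex"]
        assert df == 1 and 0.0 <= p <= 1.0


class TestPredictions:
    def test_zero_variance_gives_zero_prediction(self):
        model, vc = random_instance(8, n=15)
        theta = vc.values_single()
        theta[-2] = 0.0  # genetic term
        vc0 = VarianceComponents.from_values(list(vc.names), theta)
        sol = vb.solve_mixed_model(model, vc0)
        np.testing.assert_allclose(
            sol.random_effects[model.components[-1].name], 0.0, atol=1e-12
        )

    def test_residual_identity_holds(self):
        model, vc = random_instance(9, n=20)
        sol = vb.solve_mixed_model(model, vc)
        t, n = model.n_traits, model.n_records
        fitted = (model.X @ sol.fixed.estimates).reshape(t, n)
        for comp in model.components:
            fitted += sol.random_effects[comp.name][comp.level_index].T
        np.testing.assert_allclose(
            sol.residuals, model.y.reshape(t, n) - fitted, atol=1e-10
        )

    def test_backend_invariance_of_predictions(self):
        model, vc = random_instance(10, n=25)
        a = vb.solve_mixed_model(model, vc, backend="chol")
        b = vb.solve_mixed_model(model, vc, backend="pcg", tol=1e-12)
        for comp in model.components:
            np.testing.assert_allclose(
                a.random_effects[comp.name], b.random_effects[comp.name],
                atol=1e-6,
            )

    def test_ebv_accuracy_increases_with_heritability(self):
        """corr(EBV, TBV) > 0 and increasing over h2 in {0.1, 0.4, 0.7}."""
        accs = []
        for h2 in (0.1, 0.4, 0.7):
            cfg = vb.SimConfig(
                seed=900, n_base_male=125, n_base_female=125,
                n_generations=1, n_markers=1000, n_qtl=80, h2=(h2,),
                genetic_correlation=0.0, env_variance=(), env_levels=(),
                fixed_levels=(2,),
            )
            sim = vb.simulate(cfg)
            G = vb.make_grm(sim.genotypes)
            model = vb.build_model(sim.phenotypes, {"g": G},
                                   traits=["trait1"])
            vc = VarianceComponents.from_values(
                component_names(model), [h2, 1 - h2]
            )
            sol = vb.solve_mixed_model(model, vc)
            acc = np.corrcoef(sol.ebv()[:, 0],
                              sim.truth.breeding_values[:, 0])[0, 1]
            accs.append(acc)
        assert accs[0] > 0
        assert accs[0] < accs[1] < accs[2]

    def test_non_phenotyped_individuals_receive_ebvs(self):
        rng = np.random.default_rng(11)
        ids = [f"i{k}" for k in range(12)]
        K = vb.RelationshipMatrix(random_kernel(rng, 12), ids, kind="G")
        df = pd.DataFrame({"id": ids[:8], "y": rng.normal(size=8)})
        tab = PhenotypeTable(df, id_column="id", traits=["y"])
        model = vb.build_model(tab, {"g": K})
        vc = VarianceComponents.from_values(component_names(model),
                                            [0.5, 0.5])
        sol = vb.solve_mixed_model(model, vc)
        u = sol.ebv()[:, 0]
        assert u.shape == (12,)
        assert np.abs(u[8:]).max() > 0  # predicted through K columns

    def test_single_precision_storage_changes_little(self, tmp_path):
        """Kernels stored in float32 shift EBVs by < 1e-4 relative."""
        model, vc = random_instance(12, n=30)
        comp = model.components[-1]
        sol = vb.solve_mixed_model(model, vc)
        vb.write_relationship(comp.kernel, tmp_path / "k.bin",
                              precision="single")
        K32 = vb.read_relationship(tmp_path / "k.bin", kind="G")
        comp._S = None
        old_kernel = comp.kernel
        try:
            comp.kernel = K32
            sol32 = vb.solve_mixed_model(model, vc)
        finally:
            comp.kernel = old_kernel
            comp._S = None
        u, u32 = sol.ebv(), sol32.ebv()
        rel = np.abs(u - u32).max() / np.abs(u).max()
        assert rel < 1e-4


class TestSnpEffects:
    def test_zero_ebvs_give_zero_effects(self, tiny_sim):
        G = vb.make_grm(tiny_sim.genotypes)
        alpha = vb.snp_effects(tiny_sim.genotypes, G,
                               np.zeros(G.n))
        np.testing.assert_allclose(alpha, 0.0)

    def test_reconstruction_of_ebvs(self, tiny_sim):
        G = vb.make_grm(tiny_sim.genotypes)
        model = vb.build_model(tiny_sim.phenotypes, {"g": G},
                               traits=["trait1"])
        res = vb.run_reml(model, method="AI")
        sol = res.solve()
        alpha = sol.snp_effects(tiny_sim.genotypes)
        p = G.meta["freqs"]
        Zc = tiny_sim.genotypes.codes - 2 * p
        np.testing.assert_allclose(Zc @ alpha, sol.ebv()[:, 0], atol=1e-6)

    def test_monomorphic_marker_gets_zero_effect(self):
        rng = np.random.default_rng(13)
        codes = rng.integers(0, 3, size=(10, 20), dtype=np.int8)
        codes[:, 7] = 0  # monomorphic
        markers = pd.DataFrame(
            {"chrom": "1", "id": [f"M{j}" for j in range(20)],
             "pos": np.arange(20) + 1, "allele1": "A", "allele2": "B"}
        )
        geno = vb.GenotypeMatrix(codes, [f"i{k}" for k in range(10)], markers)
        G = vb.make_grm(geno)
        u = rng.normal(size=10)
        u = G.values @ u  # ensure u in range(G)
        alpha = vb.snp_effects(geno, G, u)
        assert alpha[7] == 0.0

    def test_foreign_matrix_rejected(self, tiny_sim):
        K = vb.RelationshipMatrix(
            np.eye(tiny_sim.genotypes.n_individuals),
            list(tiny_sim.genotypes.individual_ids),
        )
        with pytest.raises(ValueError, match="metadata"):
            vb.snp_effects(tiny_sim.genotypes, K, np.zeros(K.n))
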