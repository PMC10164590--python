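"""V-based REML: likelihood, derivatives, EM updates and schedules."""

import numpy as np
import pandas as pd
import pytest

import vblup as vb
from vblup.phenotypes import PhenotypeTable
from vblup.reml import (
    REMLState,
    VarianceComponents,
    build_V,
    component_names,
    default_start,
)
from tests.conftest import random_instance, random_kernel


class TestBuildV:
    def test_residual_only(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"id": [f"i{k}" for k in range(8)],
                           "y": rng.normal(size=8)})
        tab = PhenotypeTable(df, id_column="id", traits=["y"])
        model = vb.build_model(tab, {})
        vc = VarianceComponents.from_values(["residual"], [0.7])
        np.testing.assert_allclose(build_V(model, vc), 0.7 * np.eye(8))

    def test_identity_kernel_adds_to_residual(self):
        rng = np.random.default_rng(1)
        ids = [f"i{k}" for k in range(6)]
        K = vb.RelationshipMatrix(np.eye(6), ids, kind="G")
        df = pd.DataFrame({"id": ids, "y": rng.normal(size=6)})
        tab = PhenotypeTable(df, id_column="id", traits=["y"])
        model = vb.build_model(tab, {"g": K})
        vc = VarianceComponents.from_values(["g", "residual"], [0.3, 0.5])
        np.testing.assert_allclose(build_V(model, vc), 0.8 * np.eye(6))

    def test_matches_naive_term_summation(self):
        model, vc = random_instance(2, n=15)
        V = build_V(model, vc)
        naive = vc.matrices[-1][0, 0] * np.eye(15)
        for comp, sig in zip(model.components, vc.matrices[:-1]):
            Z = comp.incidence()
            Kfull = (
                comp.kernel.values if comp.kind == "genetic"
                else np.eye(comp.n_levels)
            )
            naive += sig[0, 0] * Z @ Kfull @ Z.T
        np.testing.assert_allclose(V, naive, atol=1e-14)


class TestLoglik:
    def test_residual_only_closed_form(self):
        rng = np.random.default_rng(3)
        n = 12
        df = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "y": rng.normal(size=n),
             "sex": rng.choice(["m", "f"], size=n)}
        )
        tab = PhenotypeTable(df, id_column="id", traits=["y"], fixed=["sex"])
        model = vb.build_model(tab, {})
        sig = 0.9
        vc = VarianceComponents.from_values(["residual"], [sig])
        X, y = model.X, model.y
        Q = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        nb = X.shape[1]
        # ln|V| + ln|X'V^-1 X| = (n - nb) ln s2 + ln|X'X| for V = s2 I
        expected = -0.5 * (
            (n - nb) * np.log(sig)
            + np.linalg.slogdet(X.T @ X)[1]
            + y @ Q @ y / sig
        )
        assert vb.reml_loglik(model, vc) == pytest.approx(expected, abs=1e-10)

    def test_scale_equivariance(self):
        """y -> c y with theta -> c^2 theta shifts lnL by -(n-nb) ln c."""
        model, vc = random_instance(4, n=14)
        c = 1.7
        base = vb.reml_loglik(model, vc)
        model2 = vb.MixedModelData(
            y=c * model.y, X=model.X, components=model.components,
            n_records=model.n_records, n_traits=1,
            record_ids=model.record_ids, trait_names=model.trait_names,
            x_names=model.x_names, x_groups=model.x_groups,
        )
        vc2 = VarianceComponents.from_values(
            list(vc.names), c**2 * vc.values_single()
        )
        shifted = vb.reml_loglik(model2, vc2)
        expected = base - (model.n_records - model.n_fixed) * np.log(c)
        assert shifted == pytest.approx(expected, abs=1e-8)


class TestDerivatives:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_gradient_matches_finite_differences(self, seed):
        model, vc = random_instance(seed, n=12)
        g = vb.gradient(model, vc)
        vec = vc.as_vector()
        for p in range(len(vec)):
            e = 1e-5
            vp, vm = vec.copy(), vec.copy()
            vp[p] += e
            vm[p] -= e
            fd = (
                vb.reml_loglik(model, VarianceComponents.from_vector(
                    list(vc.names), vp, 1))
                - vb.reml_loglik(model, VarianceComponents.from_vector(
                    list(vc.names), vm, 1))
            ) / (2 * e)
            assert g[p] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_ai_single_component_brute_force(self):
        model, _ = random_instance(13, n=10, with_env=False)
        # strip fixed effects to bare intercept via the model as built
        vc = VarianceComponents.from_values(
            component_names(model), [0.6, 0.8]
        )
        st = REMLState(model, vc)
        AI = st.ai_matrix()
        V = build_V(model, vc)
        Vinv = np.linalg.inv(V)
        X = model.X
        P = Vinv - Vinv @ X @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        S = model.components[0].structure()
        derivs = [S, np.eye(model.n_records)]
        y = model.y
        for i in range(2):
            for j in range(2):
                brute = 0.5 * y @ P @ derivs[i] @ P @ derivs[j] @ P @ y
                assert AI[i, j] == pytest.approx(brute, rel=1e-10)
        assert np.allclose(AI, AI.T)

    def test_ai_positive_semidefinite(self):
        model, vc = random_instance(14, n=16, n_genetic=2)
        AI = vb.ai_matrix(model, vc)
        assert np.linalg.eigvalsh(AI).min() >= -1e-10

    def test_hutchinson_traces_approximate_dense(self):
        model, vc = random_instance(15, n=20)
        dense = REMLState(model, vc)
        probed = REMLState(model, vc, trace_cap=5, trace_probes=4000,
                           probe_seed=99)
        tr_d = dense.trace_P_dV()
        tr_p = probed.trace_P_dV()
        assert probed.trace_mc_error is not None
        np.testing.assert_allclose(
            tr_p, tr_d, atol=6 * probed.trace_mc_error + 1e-8
        )


class TestEMStep:
    def test_stationary_point_is_fixed_point(self):
        # seed chosen so the REML optimum is interior (no floored component)
        model, vc = random_instance(24, n=14)
        res = vb.run_reml(model, method="AI", tol=1e-12, max_iter=200)
        assert not res.floored
        after = vb.em_step(model, res.vc)
        np.testing.assert_allclose(
            after.as_vector(), res.vc.as_vector(), atol=1e-7
        )

    def test_loglik_increases_from_overestimate(self):
        model, vc = random_instance(21, n=15)
        bad = VarianceComponents.from_values(
            list(vc.names),
            np.concatenate([vc.values_single()[:-1],
                            [10 * vc.values_single()[-1]]]),
        )
        llfs = [vb.reml_loglik(model, bad)]
        cur = bad
        for _ in range(5):
            cur = vb.em_step(model, cur)
            llfs.append(vb.reml_loglik(model, cur))
        assert np.all(np.diff(llfs) > 0)

    def test_residual_only_converges_to_quadratic_form(self):
        rng = np.random.default_rng(22)
        n = 20
        df = pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "y": rng.normal(size=n)}
        )
        tab = PhenotypeTable(df, id_column="id", traits=["y"])
        model = vb.build_model(tab, {})
        X, y = model.X, model.y
        Q = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        target = y @ Q @ y / (n - X.shape[1])
        cur = VarianceComponents.from_values(["residual"], [5.0])
        for _ in range(200):
            cur = vb.em_step(model, cur)
        assert cur.values_single()[0] == pytest.approx(target, rel=1e-6)


class TestSchedules:
    def test_parameter_recovery_single_kernel(self):
        """Mean estimate over replicates within 2 MC SE of the truth."""
        rng = np.random.default_rng(30)
        n = 400
        ids = [f"i{k}" for k in range(n)]
        K = random_kernel(rng, n)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        sig_g, sig_e = 0.6, 0.4
        ests = []
        for rep in range(20):
            rng_rep = np.random.default_rng(1000 + rep)
            y = (
                np.sqrt(sig_g) * L @ rng_rep.normal(size=n)
                + np.sqrt(sig_e) * rng_rep.normal(size=n)
            )
            df = pd.DataFrame({"id": ids, "y": y})
            tab = PhenotypeTable(df, id_column="id", traits=["y"])
            model = vb.build_model(
                tab, {"g": vb.RelationshipMatrix(K, ids, kind="G")}
            )
            res = vb.run_reml(model, method="AI")
            ests.append(res.vc.values_single()[0])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - sig_g) < 2 * se + 1e-12

    def test_ai_and_emai_reach_same_optimum(self):
        model, _ = random_instance(31, n=40)
        r1 = vb.run_reml(model, method="AI")
        r2 = vb.run_reml(model, method="EMAI")
        assert r1.converged and r2.converged
        assert abs(r1.llf - r2.llf) < 1e-6

    def test_hi_uses_he_start_and_converges(self):
        model, _ = random_instance(32, n=40)
        r_hi = vb.run_reml(model, method="HI")
        r_ai = vb.run_reml(model, method="AI")
        assert r_hi.converged
        assert abs(r_hi.llf - r_ai.llf) < 1e-5

    def test_zero_variance_component_pinned_and_flagged(self):
        """A kernel absent from the generating process hits the floor."""
        rng = np.random.default_rng(33)
        n = 60
        ids = [f"i{k}" for k in range(n)]
        K = random_kernel(rng, n)
        y = rng.normal(size=n)  # pure residual: sigma_g truly 0
        df = pd.DataFrame({"id": ids, "y": y})
        tab = PhenotypeTable(df, id_column="id", traits=["y"])
        model = vb.build_model(
            tab, {"g": vb.RelationshipMatrix(K, ids, kind="G")}
        )
        res = vb.run_reml(model, method="AI")
        if res.floored:
            assert "g" in res.floored
            floor = 1e-6 * np.var(model.y, ddof=1)
            assert res.vc["g"][0, 0] <= floor * (1 + 1e-8)
        else:  # a small positive estimate is statistically legitimate
            assert res.vc["g"][0, 0] < 0.25

    def test_converged_flag_implies_small_gradient(self):
        model, _ = random_instance(34, n=30)
        res = vb.run_reml(model, method="AI")
        if res.converged and not res.floored:
            assert res.gradient_norm < 1e-4

    def test_nonconvergence_flagged_not_raised(self):
        model, _ = random_instance(35, n=25)
        res = vb.run_reml(model, method="EM", max_iter=2, tol=1e-12)
        assert not res.converged
        assert res.n_iter == 2

    def test_default_start_splits_phenotypic_variance(self):
        model, _ = random_instance(36, n=20)
        start = default_start(model)
        vary = np.var(model.y, ddof=1)
        vals = start.values_single()
        assert vals[-1] == pytest.approx(0.5 * vary)
        assert vals.sum() == pytest.approx(vary)

    def test_summary_contains_estimates(self):
        model, _ = random_instance(37, n=30)
        res = vb.run_reml(model, method="AI")
        text = res.summary()
        assert "REML variance component estimates" in text
        assert "h2(" in text
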