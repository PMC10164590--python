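"""Inverse-free mixed-model solving.

Given variance components, everything flows through one linear system

    V [phi1 phi2] = [X y],

solved by Cholesky, LU, or Jacobi-preconditioned conjugate gradients.  The
projection of y, the fixed-effect BLUEs with Wald tests, environmental
effect predictions, EBVs u_i = sigma_i^2 K_i Z_i' P y over every kernel ID
(phenotyped or not) and the marker-effect back-solve all derive from
[phi1 phi2] without inverting V or any relationship matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import RelationshipMatrix
from .model import MixedModelData
from .reml import VarianceComponents, build_V

logger = logging.getLogger(__name__)


class PCGError(RuntimeError):
    pass


def solve_phi(
    V: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    backend: str = "chol",
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve V [phi1 phi2] = [X y]; returns (phi1, phi2, pcg_iterations).

    ``chol`` falls back to LU automatically (with a log message) if V is not
    numerically positive definite.  ``pcg`` runs one conjugate-gradient
    solve per right-hand side with the diagonal (Jacobi) preconditioner,
    converging at relative residual norm < tol.
    """
    if backend not in ("chol", "lu", "pcg"):
        raise ValueError(f"unknown backend {backend!r}")
    rhs = np.column_stack([X, y])
    iters = 0
    if backend == "chol":
        try:
            cho = scipy.linalg.cho_factor(V, lower=True)
            sol = scipy.linalg.cho_solve(cho, rhs)
        except scipy.linalg.LinAlgError:
            logger.warning("Cholesky failed on V; retrying with LU")
            backend = "lu"
    if backend == "lu":
        lu = scipy.linalg.lu_factor(V)
        sol = scipy.linalg.lu_solve(lu, rhs)
    if backend == "pcg":
        if tol <= 0:
            raise ValueError("pcg tolerance must be positive")
        diag = np.diag(V).copy()
        if np.any(diag <= 0):
            raise PCGError("V has non-positive diagonal; cannot precondition")
        M = scipy.sparse.linalg.LinearOperator(
            V.shape, matvec=lambda v: v / diag
        )
        cols = []
        maxiter = max_iter or 10 * V.shape[0]
        for j in range(rhs.shape[1]):
            count = [0]

            def cb(_xk):
                count[0] += 1

            x, info = scipy.sparse.linalg.cg(
                V, rhs[:, j], rtol=tol, atol=0.0, maxiter=maxiter, M=M,
                callback=cb,
            )
            if info != 0:
                res = np.linalg.norm(V @ x - rhs[:, j])
                raise PCGError(
                    f"PCG did not converge on RHS {j} "
                    f"(info={info}, residual norm {res:.3e})"
                )
            iters = max(iters, count[0])
            cols.append(x)
        sol = np.column_stack(cols)
    phi1, phi2 = sol[:, :-1], sol[:, -1]
    return phi1, phi2, iters


def project(phi1: np.ndarray, phi2: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Py = phi2 - phi1 (X'phi1)^-1 X'phi2 (X'Py = 0 by construction)."""
    XtP1 = X.T @ phi1
    try:
        coef = scipy.linalg.solve(XtP1, X.T @ phi2)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"X'phi1 singular -- X not full column rank: {err}"
        )
    return phi2 - phi1 @ coef


@dataclass
class FixedEffects:
    """BLUEs with standard errors, Wald z tests and joint factor tests."""

    names: list[str]
    estimates: np.ndarray
    cov: np.ndarray
    group_tests: dict[str, tuple[float, int, float]] = field(
        default_factory=dict
    )

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.estimates / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> str:
        lines = [f"{'term':<24}{'estimate':>12}{'se':>10}{'z':>9}{'p':>11}"]
        for nm, b, s, z, p in zip(
            self.names, self.estimates, self.se, self.z, self.pvalues
        ):
            lines.append(f"{nm:<24}{b:>12.5f}{s:>10.5f}{z:>9.3f}{p:>11.3e}")
        for g, (chi2, df, p) in self.group_tests.items():
            lines.append(f"joint {g}: chi2({df}) = {chi2:.3f}, p = {p:.3e}")
        return "\n".join(lines)


def estimate_fixed(
    phi1: np.ndarray,
    phi2: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    groups: dict[str, list[int]] | None = None,
) -> FixedEffects:
    """GLS fixed effects b = (X'phi1)^-1 X'phi2 with cov (X'V^-1 X)^-1."""
    XtP1 = X.T @ phi1
    XtP1 = 0.5 * (XtP1 + XtP1.T)
    cov = scipy.linalg.inv(XtP1)
    b = cov @ (X.T @ phi2)
    names = names or [f"b{j}" for j in range(X.shape[1])]
    tests: dict[str, tuple[float, int, float]] = {}
    for g, idx in (groups or {}).items():
        bj = b[idx]
        cj = cov[np.ix_(idx, idx)]
        chi2 = float(bj @ scipy.linalg.solve(cj, bj, assume_a="pos"))
        df = len(idx)
        tests[g] = (chi2, df, float(stats.chi2.sf(chi2, df)))
    return FixedEffects(names=names, estimates=b, cov=cov, group_tests=tests)


def predict_random(
    model: MixedModelData, vc: VarianceComponents, Py: np.ndarray
) -> dict[str, np.ndarray]:
    """Random-effect predictions per component, shape (n_levels, t).

    Genetic terms: u_i = sigma_i^2 K_i Z_i' P y, computed over all kernel
    IDs so non-phenotyped individuals are predicted through the columns of
    K.  Environmental terms: r = sigma_r^2 R' P y.  Multi-trait versions
    use the t x t component covariance in place of the scalar.
    """
    t, n = model.n_traits, model.n_records
    Pyb = Py.reshape(t, n)
    out: dict[str, np.ndarray] = {}
    for comp in model.components:
        sig = vc[comp.name]
        # Z' Py per trait: sum record contributions into levels
        ZtPy = np.zeros((t, comp.n_levels))
        for a in range(t):
            np.add.at(ZtPy[a], comp.level_index, Pyb[a])
        if comp.kind == "genetic":
            base = comp.kernel.values @ ZtPy.T  # (n_levels, t)
        else:
            base = ZtPy.T
        out[comp.name] = base @ sig.T
    return out


def snp_effects(
    geno: GenotypeMatrix,
    G: RelationshipMatrix,
    u: np.ndarray,
) -> np.ndarray:
    """Back-solve marker effects from genomic EBVs.

    alpha = Zc' G^- u / c with Zc the centred genotype matrix and c the
    GRM denominator recorded in G's metadata.  G^- u is computed by a
    minimum-norm (SVD) solve because the sample-frequency GRM is rank
    deficient by construction; since EBVs lie in the range of G the
    reconstruction Zc alpha still equals u.  Monomorphic markers get
    effect 0.
    """
    if "denominator" not in G.meta or "freqs" not in G.meta:
        raise ValueError(
            "G carries no construction metadata; marker effects require a "
            "GRM built by make_grm from the same genotypes"
        )
    if list(geno.individual_ids) != list(G.ids):
        raise ValueError("genotype and GRM individual orders differ")
    c = G.meta["denominator"]
    p = np.asarray(G.meta["freqs"], dtype=np.float64)
    w, *_ = scipy.linalg.lstsq(G.values, u, cond=1e-10)
    codes = geno.codes.astype(np.float64)
    Zc = codes - 2.0 * np.where(np.isnan(p), 0.0, p)
    Zc[geno.codes < 0] = 0.0
    Zc[:, np.isnan(p)] = 0.0
    mono = np.nan_to_num(2.0 * p * (1.0 - p)) <= 0
    alpha = Zc.T @ w / c
    alpha[mono] = 0.0
    return alpha


@dataclass
class BLUPResults:
    """Joint solution of the mixed model at fixed variance components."""

    model: MixedModelData
    vc: VarianceComponents
    fixed: FixedEffects
    random_effects: dict[str, np.ndarray]
    residuals: np.ndarray  # (t, n)
    Py: np.ndarray
    backend: str
    pcg_iterations: int = 0

    def ebv(self, component: str | None = None) -> np.ndarray:
        """EBVs of a genetic component, shape (n_levels, t)."""
        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            if len(genetic) != 1:
                raise ValueError("specify the component name explicitly")
            component = genetic[0]
        return self.random_effects[component]

    def ebv_ids(self, component: str | None = None) -> list[str]:
        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            component = genetic[0]
        comp = next(c for c in self.model.components if c.name == component)
        return comp.level_ids

    def snp_effects(self, geno: GenotypeMatrix,
                    component: str | None = None) -> np.ndarray:
        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            if len(genetic) != 1:
                raise ValueError("specify the component name explicitly")
            component = genetic[0]
        comp = next(c for c in self.model.components if c.name == component)
        u = self.random_effects[component]
        u1 = u[:, 0] if u.ndim == 2 and u.shape[1] == 1 else u
        return snp_effects(geno, comp.kernel, u1)


def solve_mixed_model(
    model: MixedModelData,
    vc: VarianceComponents,
    backend: str = "chol",
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> BLUPResults:
    """Full inverse-free solve: phi system, BLUEs, predictions, residuals."""
    V = build_V(model, vc)
    phi1, phi2, iters = solve_phi(V, model.X, model.y, backend=backend,
                                  tol=tol, max_iter=max_iter)
    Py = project(phi1, phi2, model.X)
    fixed = estimate_fixed(phi1, phi2, model.X, names=model.x_names,
                           groups=model.x_groups)
    rand = predict_random(model, vc, Py)

    t, n = model.n_traits, model.n_records
    fitted = (model.X @ fixed.estimates).reshape(t, n)
    for comp in model.components:
        eff = rand[comp.name]  # (n_levels, t)
        fitted += eff[comp.level_index].T
    residuals = model.y.reshape(t, n) - fitted
    return BLUPResults(
        model=model,
        vc=vc,
        fixed=fixed,
        random_effects=rand,
        residuals=residuals,
        Py=Py,
        backend=backend,
        pcg_iterations=iters,
    )
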