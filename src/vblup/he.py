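"""Haseman-Elston regression: variance components by OLS on pairwise
phenotype similarities versus pairwise relationship entries.

After adjusting phenotypes for fixed effects, the product y_i * y_j of the
standardised adjusted phenotypes of a pair (i < j) has expectation
mu + sum_c (S_c)_ij h_c^2, so the variance ratios fall out of one ordinary
least-squares regression over all pairs -- no iteration and no matrix
inversion beyond a (k+1) x (k+1) normal-equation solve.  The squared
pair difference is supported as an alternative response (its coefficients
estimate -2 h_c^2 and are rescaled before reporting).

For a two-trait model the per-trait regressions give variances and the
regression of ordered cross-trait products gives the covariances, hence the
genetic correlation.  The normal equations are accumulated with whole-matrix
algebra over the relationship structures, so the pair enumeration is never
materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import MixedModelData

RESIDUAL = "residual"


class HECollinearityError(ValueError):
    pass


def adjust_phenotype(model: MixedModelData) -> np.ndarray:
    """OLS-adjusted phenotypes y - X (X'X)^-1 X'y, shape (t, n)."""
    y, X = model.y, model.X
    beta, *_ = scipy.linalg.lstsq(X, y)
    resid = y - X @ beta
    return resid.reshape(model.n_traits, model.n_records)


def _pair_sum(M: np.ndarray) -> float:
    """sum over unordered pairs i < j of M_ij, for symmetric M."""
    return 0.5 * (float(M.sum()) - float(np.trace(M)))


def _he_normal_equations(
    structs: list[np.ndarray | None], n: int, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normal equations of the pairwise OLS with intercept.

    ``Y`` is the symmetric response matrix (outer product of adjusted
    phenotypes, or the squared-difference matrix); diagonal entries are
    ignored (pairs with i = j are excluded).
    """
    k = len(structs)
    G = np.empty((k + 1, k + 1))
    rhs = np.empty(k + 1)
    n_pairs = n * (n - 1) / 2.0
    G[0, 0] = n_pairs
    rhs[0] = _pair_sum(Y)
    dense = [np.eye(n) if S is None else S for S in structs]
    for c, Sc in enumerate(dense):
        G[0, c + 1] = G[c + 1, 0] = _pair_sum(Sc)
        rhs[c + 1] = _pair_sum(Sc * Y)
        for d, Sd in enumerate(dense[: c + 1]):
            G[c + 1, d + 1] = G[d + 1, c + 1] = _pair_sum(Sc * Sd)
    return G, rhs


def _solve_pair_ols(
    model: MixedModelData, structs, names, Y: np.ndarray
) -> tuple[float, np.ndarray]:
    n = model.n_records
    G, rhs = _he_normal_equations(structs, n, Y)
    if np.linalg.matrix_rank(G, hermitian=True) < G.shape[0]:
        # name the offending kernel: one whose off-diagonal is constant
        for name, S in zip(names, structs):
            if S is None:
                continue
            off = S[~np.eye(n, dtype=bool)]
            if off.size and np.ptp(off) < 1e-12:
                raise HECollinearityError(
                    f"kernel {name!r} has constant off-diagonal entries; "
                    "its HE regressor is collinear with the intercept"
                )
        raise HECollinearityError("HE regressors are collinear")
    sol = scipy.linalg.solve(G, rhs, assume_a="sym")
    return float(sol[0]), sol[1:]


@dataclass
class HEResults:
    """Haseman-Elston estimates.

    ``coefficients`` holds the variance-ratio estimates per component and
    trait (h_c^2); ``vc`` the implied variance components on the phenotypic
    scale, including the residual (and, for two traits, the covariances).
    """

    model: MixedModelData
    form: str
    intercepts: np.ndarray  # per trait (+ cross for 2 traits)
    coefficients: np.ndarray  # (t, k) variance ratios per trait
    vc: "object"  # VarianceComponents
    n_pairs: int = 0
    component_names_: list[str] = field(default_factory=list)

    def heritability(self, component: str | None = None) -> np.ndarray:
        from .reml import VarianceComponents  # noqa: F401

        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            if len(genetic) != 1:
                raise ValueError("specify the component name explicitly")
            component = genetic[0]
        tot = np.diag(sum(self.vc.matrices))
        return np.diag(self.vc[component]) / tot

    def genetic_correlation(self, component: str | None = None) -> float:
        if self.model.n_traits != 2:
            raise ValueError("genetic correlation requires a two-trait model")
        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            if len(genetic) != 1:
                raise ValueError("specify the component name explicitly")
            component = genetic[0]
        m = self.vc[component]
        return float(m[0, 1] / np.sqrt(m[0, 0] * m[1, 1]))

    def summary(self) -> str:
        lines = [
            "Haseman-Elston regression",
            "=" * 48,
            f"form: {self.form}   pairs used: {self.n_pairs}",
        ]
        for i, tr in enumerate(self.model.trait_names):
            lines.append(f"trait {tr}: intercept {self.intercepts[i]:+.6f}")
            for j, name in enumerate(self.component_names_):
                lines.append(
                    f"  h2({name}) = {self.coefficients[i, j]:.4f}"
                )
        if self.model.n_traits == 2:
            lines.append(
                f"genetic correlation = {self.genetic_correlation():.4f}"
            )
        return "\n".join(lines)


def he_regression(model: MixedModelData, form: str = "cross_product") -> HEResults:
    """Single- or two-trait Haseman-Elston regression (pairs with i < j).

    The adjusted phenotypes are standardised per trait before forming pair
    responses, so the regression coefficients are variance ratios; implied
    variances are var(yhat) * beta (covariances cov(yhat1, yhat2) * beta).
    """
    from .reml import VarianceComponents

    if form not in ("cross_product", "squared_difference"):
        raise ValueError("form must be cross_product or squared_difference")
    n, t = model.n_records, model.n_traits
    if n < 2:
        raise ValueError("HE regression needs at least two records")
    structs = [c.structure() for c in model.components]
    names = [c.name for c in model.components]
    k = len(structs)
    if k == 0:
        raise ValueError("HE regression needs at least one random component")

    yhat = adjust_phenotype(model)
    sd = yhat.std(axis=1, ddof=1)
    # a phenotype (numerically) fully explained by X carries no signal:
    # keep it unscaled so its pair products, hence coefficients, are ~0
    raw_sd = model.y.reshape(t, n).std(axis=1, ddof=1)
    degenerate = sd <= 1e-10 * np.maximum(raw_sd, 1.0)
    yhat[degenerate] = 0.0
    sd = np.where(degenerate, 0.0, sd)
    z = yhat / np.where(degenerate, 1.0, sd)[:, None]

    intercepts = []
    coefs = np.empty((t, k))
    for a in range(t):
        if form == "cross_product":
            Y = np.outer(z[a], z[a])
        else:
            Y = (z[a][:, None] - z[a][None, :]) ** 2
        mu, beta = _solve_pair_ols(model, structs, names, Y)
        if form == "squared_difference":
            beta = -0.5 * beta
        intercepts.append(mu)
        coefs[a] = beta

    varhat = sd**2
    if t == 1:
        mats = [np.array([[varhat[0] * coefs[0, j]]]) for j in range(k)]
        resid = np.array([[varhat[0] * (1.0 - coefs[0].sum())]])
        vc = VarianceComponents(names + [RESIDUAL], mats + [resid], 1)
    elif t == 2:
        # cross-trait products over ordered pairs i != j; with symmetric
        # regressors this equals the unordered regression on the
        # symmetrised response.
        covhat = float(np.cov(yhat[0], yhat[1], ddof=1)[0, 1])
        Yx = 0.5 * (np.outer(z[0], z[1]) + np.outer(z[1], z[0]))
        mu_x, beta_x = _solve_pair_ols(model, structs, names, Yx)
        intercepts.append(mu_x)
        scale_x = float(sd[0] * sd[1])
        cov_c = scale_x * beta_x
        mats = []
        for j in range(k):
            m = np.array(
                [
                    [varhat[0] * coefs[0, j], cov_c[j]],
                    [cov_c[j], varhat[1] * coefs[1, j]],
                ]
            )
            mats.append(m)
        resid = np.array(
            [
                [varhat[0] * (1 - coefs[0].sum()), covhat - cov_c.sum()],
                [covhat - cov_c.sum(), varhat[1] * (1 - coefs[1].sum())],
            ]
        )
        vc = VarianceComponents(names + [RESIDUAL], mats + [resid], 2)
    else:
        raise ValueError("HE regression supports one or two traits")

    return HEResults(
        model=model,
        form=form,
        intercepts=np.array(intercepts),
        coefficients=coefs,
        vc=vc,
        n_pairs=n * (n - 1) // 2,
        component_names_=names,
    )


def he_start(model: MixedModelData, floor: float):
    """HE estimates floored/PD-projected for use as REML start values."""
    from .reml import _apply_floor

    he = he_regression(model)
    vc, _ = _apply_floor(he.vc, floor)
    return vc
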