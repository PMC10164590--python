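"""V-based REML: restricted likelihood, average-information matrix,
gradients, EM updates and the AI/EM/AIEM/EMAI/HI iteration schedules.

The engine works on the phenotypic covariance

    V = sum_c Sigma0_c (x) S_c,

where S_c is the n x n structure of component c (R R' for an environmental
factor, Z K Z' for a genetic kernel, I for the residual) and Sigma0_c its
t x t trait covariance (a scalar when t = 1).  Everything -- likelihood,
gradients, AI matrix, EM updates, BLUP solving -- is expressed through
V^-1 applied to [X y] and the projection P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,
so no relationship matrix is ever inverted.

Parameters are flattened component-by-component in vech order
((0,0), (1,0), (1,1), ...); with one trait this reduces to the classical
theta = [sigma_r^2, sigma_1^2, ..., sigma_k^2, sigma_e^2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import MixedModelData

logger = logging.getLogger(__name__)

RESIDUAL = "residual"

#: Components whose variance falls below FLOOR_FRACTION * var(y) are pinned.
FLOOR_FRACTION = 1e-6

#: Above this system dimension n*t, traces switch from the explicit dense
#: projection matrix to seeded Hutchinson probes.
DEFAULT_TRACE_CAP = 25_000
DEFAULT_TRACE_PROBES = 64


class IndefiniteVError(np.linalg.LinAlgError):
    """V was not positive definite at the requested variance components."""

    def __init__(self, theta, msg: str = ""):
        super().__init__(f"V indefinite at theta={theta}: {msg}")
        self.theta = theta


@dataclass
class VarianceComponents:
    """Ordered variance components: environmental, genetic, then residual.

    ``matrices[c]`` is the t x t trait covariance of component c (1x1 for a
    single trait).
    """

    names: list[str]
    matrices: list[np.ndarray]
    n_traits: int = 1

    def __post_init__(self) -> None:
        self.matrices = [
            np.atleast_2d(np.asarray(m, dtype=np.float64)) for m in self.matrices
        ]
        t = self.n_traits
        for name, m in zip(self.names, self.matrices):
            if m.shape != (t, t):
                raise ValueError(f"component {name}: expected {t}x{t} matrix")
            if not np.allclose(m, m.T):
                raise ValueError(f"component {name}: matrix not symmetric")

    @classmethod
    def from_values(
        cls, names: list[str], values, n_traits: int = 1
    ) -> "VarianceComponents":
        """Single-trait convenience: one scalar per component."""
        if n_traits != 1:
            raise ValueError("from_values is single-trait only")
        return cls(names, [np.array([[float(v)]]) for v in values], 1)

    def as_vector(self) -> np.ndarray:
        """Flatten in vech order per component."""
        t = self.n_traits
        out = []
        for m in self.matrices:
            for a in range(t):
                for b in range(a + 1):
                    out.append(m[a, b])
        return np.array(out)

    @classmethod
    def from_vector(
        cls, names: list[str], vec: np.ndarray, n_traits: int
    ) -> "VarianceComponents":
        t = n_traits
        per = t * (t + 1) // 2
        mats = []
        k = 0
        for _ in names:
            m = np.zeros((t, t))
            for a in range(t):
                for b in range(a + 1):
                    m[a, b] = m[b, a] = vec[k]
                    k += 1
            mats.append(m)
        assert k == len(vec) == per * len(names)
        return cls(names, mats, t)

    def values_single(self) -> np.ndarray:
        """The classical theta vector; only valid for one trait."""
        if self.n_traits != 1:
            raise ValueError("values_single is single-trait only")
        return np.array([m[0, 0] for m in self.matrices])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrices[self.names.index(name)]

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            list(self.names), [m.copy() for m in self.matrices], self.n_traits
        )


def component_names(model: MixedModelData) -> list[str]:
    return [c.name for c in model.components] + [RESIDUAL]


def _structures(model: MixedModelData) -> list[np.ndarray | None]:
    """Per-component n x n structures; None stands for the identity."""
    return [c.structure() for c in model.components] + [None]


def _param_index(model: MixedModelData) -> list[tuple[int, int, int]]:
    """Flattened parameter list: (component, trait_a, trait_b) with a >= b."""
    t = model.n_traits
    out = []
    for c in range(len(model.components) + 1):
        for a in range(t):
            for b in range(a + 1):
                out.append((c, a, b))
    return out


def build_V(model: MixedModelData, vc: VarianceComponents) -> np.ndarray:
    """Phenotypic covariance V = sum_c Sigma0_c (x) S_c  (n*t square)."""
    if vc.n_traits != model.n_traits or len(vc.names) != len(model.components) + 1:
        raise ValueError("variance components do not match the model")
    n, t = model.n_records, model.n_traits
    structs = _structures(model)
    V = np.zeros((n * t, n * t))
    eye = np.eye(n)
    for sig, S in zip(vc.matrices, structs):
        base = eye if S is None else S
        if t == 1:
            V += sig[0, 0] * base
        else:
            V += np.kron(sig, base)
    return V


class REMLState:
    """All quantities the REML iteration needs at a fixed theta.

    Factorises V once; derives log-likelihood, Py, the gradient, the AI
    matrix and the EM update from that single factorisation.
    """

    def __init__(
        self,
        model: MixedModelData,
        vc: VarianceComponents,
        trace_cap: int = DEFAULT_TRACE_CAP,
        trace_probes: int = DEFAULT_TRACE_PROBES,
        probe_seed: int = 20240,
    ):
        self.model = model
        self.vc = vc
        n, t = model.n_records, model.n_traits
        self.n, self.t = n, t
        self.nt = n * t
        self.structs = _structures(model)
        self.params = _param_index(model)
        X, y = model.X, model.y

        V = build_V(model, vc)
        try:
            self.chol = scipy.linalg.cho_factor(V, lower=True)
        except scipy.linalg.LinAlgError as err:
            raise IndefiniteVError(vc.as_vector(), str(err))
        self.logdetV = 2.0 * float(np.sum(np.log(np.diag(self.chol[0]))))

        self.dense_traces = self.nt <= trace_cap
        if self.dense_traces:
            # dpotri inverts from the Cholesky factor in place (half the
            # cost of triangular solves against the identity)
            inv, info = scipy.linalg.lapack.dpotri(self.chol[0], lower=True)
            if info != 0:
                raise IndefiniteVError(vc.as_vector(), f"dpotri info={info}")
            self.Vinv = np.tril(inv) + np.tril(inv, -1).T
            self.phi1 = self.Vinv @ X
            self.phi2 = self.Vinv @ y
        else:
            self.Vinv = None
            self.phi1 = scipy.linalg.cho_solve(self.chol, X)
            self.phi2 = scipy.linalg.cho_solve(self.chol, y)
        XtVX = X.T @ self.phi1
        self.xtvx_chol = scipy.linalg.cho_factor(0.5 * (XtVX + XtVX.T))
        self.logdetXtVX = 2.0 * float(
            np.sum(np.log(np.diag(self.xtvx_chol[0])))
        )
        self.Py = self.phi2 - self.phi1 @ scipy.linalg.cho_solve(
            self.xtvx_chol, X.T @ self.phi2
        )
        self.yPy = float(y @ self.Py)
        self.llf = -0.5 * (self.logdetV + self.logdetXtVX + self.yPy)

        self._P = None
        self._probe_seed = probe_seed
        self._trace_probes = trace_probes
        self.trace_mc_error: float | None = None

    # -- projection -----------------------------------------------------
    def apply_P(self, Z: np.ndarray) -> np.ndarray:
        """P @ Z for a vector or matrix of columns."""
        VinvZ = (
            self.Vinv @ Z
            if self.Vinv is not None
            else scipy.linalg.cho_solve(self.chol, Z)
        )
        return VinvZ - self.phi1 @ scipy.linalg.cho_solve(
            self.xtvx_chol, self.phi1.T @ Z
        )

    @property
    def P(self) -> np.ndarray:
        if self._P is None:
            if self.Vinv is None:
                raise RuntimeError("explicit P unavailable above the trace cap")
            corr = self.phi1 @ scipy.linalg.cho_solve(
                self.xtvx_chol, self.phi1.T
            )
            self._P = self.Vinv - corr
        return self._P

    # -- dV applications -------------------------------------------------
    def _block(self, M: np.ndarray, a: int, b: int) -> np.ndarray:
        n = self.n
        return M[a * n : (a + 1) * n, b * n : (b + 1) * n]

    def apply_dV(self, p: int, Z: np.ndarray) -> np.ndarray:
        """dV/dtheta_p @ Z, where dV = sym(E_ab) (x) S_c."""
        c, a, b = self.params[p]
        S = self.structs[c]
        n = self.n
        Z2 = Z.reshape(self.t, n, -1)
        out = np.zeros_like(Z2)
        Sa = Z2[b] if S is None else np.einsum("ij,jk->ik", S, Z2[b])
        out[a] += Sa
        if a != b:
            Sb = Z2[a] if S is None else np.einsum("ij,jk->ik", S, Z2[a])
            out[b] += Sb
        return out.reshape(Z.shape)

    def _trace_P_dV_dense(self) -> np.ndarray:
        P = self.P
        n = self.n
        tr = np.empty(len(self.params))
        for p, (c, a, b) in enumerate(self.params):
            S = self.structs[c]
            Pab = self._block(P, a, b)
            val = float(np.trace(Pab)) if S is None else float(np.sum(Pab * S))
            tr[p] = 2.0 * val if a != b else val
        return tr

    def _trace_P_dV_hutchinson(self) -> np.ndarray:
        rng = np.random.default_rng(self._probe_seed)
        m = self._trace_probes
        Z = rng.choice([-1.0, 1.0], size=(self.nt, m))
        PZ = self.apply_P(Z)
        tr = np.empty(len(self.params))
        errs = np.empty(len(self.params))
        for p in range(len(self.params)):
            vals = np.einsum("ij,ij->j", Z, self.apply_dV(p, PZ))
            tr[p] = vals.mean()
            errs[p] = vals.std(ddof=1) / np.sqrt(m)
        self.trace_mc_error = float(errs.max())
        return tr

    def trace_P_dV(self) -> np.ndarray:
        if self.dense_traces:
            return self._trace_P_dV_dense()
        return self._trace_P_dV_hutchinson()

    # -- derivatives -----------------------------------------------------
    def gradient(self) -> np.ndarray:
        """dlnL/dtheta_p = -1/2 [tr(P dV_p) - y'P dV_p P y]."""
        traces = self.trace_P_dV()
        g = np.empty(len(self.params))
        for p in range(len(self.params)):
            quad = float(self.Py @ self.apply_dV(p, self.Py))
            g[p] = -0.5 * (traces[p] - quad)
        return g

    def ai_matrix(self) -> np.ndarray:
        """(AI)_pq = 1/2 y'P dV_p P dV_q P y, symmetric PSD."""
        k = len(self.params)
        Vp = np.column_stack([self.apply_dV(p, self.Py) for p in range(k)])
        W = self.apply_P(Vp)
        AI = 0.5 * (Vp.T @ W)
        return 0.5 * (AI + AI.T)

    def em_update(self) -> VarianceComponents:
        """One EM step: Sigma_c+ = Sigma_c + (1/q_c) Sigma_c M_c Sigma_c with
        (M_c)_ab = y'P (E_ab (x) S_c) P y - tr(P (E_ab (x) S_c))."""
        t, n = self.t, self.n
        Pyb = self.Py.reshape(t, n)
        qs = [c.n_levels for c in self.model.components] + [n]
        new = []
        if self.dense_traces:
            P = self.P
        for c, (sig, S, q) in enumerate(
            zip(self.vc.matrices, self.structs, qs)
        ):
            M = np.empty((t, t))
            for a in range(t):
                for b in range(a + 1):
                    quad = float(
                        Pyb[a] @ (Pyb[b] if S is None else S @ Pyb[b])
                    )
                    if self.dense_traces:
                        Pab = self._block(P, a, b)
                        tr = (
                            float(np.trace(Pab))
                            if S is None
                            else float(np.sum(Pab * S))
                        )
                    else:
                        tr = self._hutchinson_single(a, b, S)
                    M[a, b] = M[b, a] = quad - tr
            new.append(sig + (sig @ M @ sig) / q)
        return VarianceComponents(list(self.vc.names), new, t)

    def _hutchinson_single(self, a: int, b: int, S) -> float:
        rng = np.random.default_rng(self._probe_seed + 7)
        m = self._trace_probes
        Z = rng.choice([-1.0, 1.0], size=(self.nt, m))
        PZ = self.apply_P(Z).reshape(self.t, self.n, m)
        Za = Z.reshape(self.t, self.n, m)[a]
        right = PZ[b] if S is None else S @ PZ[b]
        return float(np.einsum("im,im->m", Za, right).mean())


# ---------------------------------------------------------------------------
# public single-call wrappers (thin views over REMLState)
# ---------------------------------------------------------------------------

def reml_loglik(model: MixedModelData, vc: VarianceComponents) -> float:
    """Restricted log-likelihood -1/2 (ln|V| + ln|X'V^-1 X| + y'Py)."""
    return REMLState(model, vc).llf


def gradient(model: MixedModelData, vc: VarianceComponents) -> np.ndarray:
    return REMLState(model, vc).gradient()


def ai_matrix(model: MixedModelData, vc: VarianceComponents) -> np.ndarray:
    return REMLState(model, vc).ai_matrix()


def em_step(model: MixedModelData, vc: VarianceComponents) -> VarianceComponents:
    return REMLState(model, vc).em_update()


# ---------------------------------------------------------------------------
# iteration schedules
# ---------------------------------------------------------------------------

@dataclass
class REMLResults:
    """REML estimates with asymptotic uncertainty and fit diagnostics.

    ``ai`` is the average-information matrix at the optimum; its inverse is
    the asymptotic covariance of the flattened parameter vector, and ``se``
    the corresponding standard errors.
    """

    model: MixedModelData
    vc: VarianceComponents
    llf: float
    converged: bool
    n_iter: int
    method: str
    trajectory: list[dict] = field(default_factory=list)
    ai: np.ndarray | None = None
    se: np.ndarray | None = None
    floored: list[str] = field(default_factory=list)
    gradient_norm: float | None = None

    @property
    def theta(self) -> np.ndarray:
        return self.vc.as_vector()

    def param_labels(self) -> list[str]:
        t = self.model.n_traits
        labels = []
        traits = self.model.trait_names
        for name in self.vc.names:
            for a in range(t):
                for b in range(a + 1):
                    if t == 1:
                        labels.append(f"V({name})")
                    elif a == b:
                        labels.append(f"V({name}:{traits[a]})")
                    else:
                        labels.append(
                            f"C({name}:{traits[a]},{traits[b]})"
                        )
        return labels

    def phenotypic_variance(self) -> np.ndarray:
        """Total variance per trait: sum of all component matrices."""
        return np.diag(sum(self.vc.matrices))

    def heritability(self, component: str | None = None) -> np.ndarray:
        """Variance ratio sigma_c^2 / sigma_total^2 per trait.

        ``component=None`` uses the single genetic component if unambiguous.
        """
        if component is None:
            genetic = [c.name for c in self.model.components
                       if c.kind == "genetic"]
            if len(genetic) != 1:
                raise ValueError("specify the component name explicitly")
            component = genetic[0]
        num = np.diag(self.vc[component])
        return num / self.phenotypic_variance()

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

    def solve(self, backend: str = "chol", tol: float = 1e-8,
              max_iter: int | None = None):
        """BLUEs, environmental effects and EBVs at the estimated theta."""
        from .solve import solve_mixed_model

        return solve_mixed_model(self.model, self.vc, backend=backend,
                                 tol=tol, max_iter=max_iter)

    def summary(self) -> str:
        lines = [
            "REML variance component estimates",
            "=" * 54,
            f"method: {self.method}   converged: {self.converged}   "
            f"iterations: {self.n_iter}",
            f"records: {self.model.n_records}  traits: {self.model.n_traits}  "
            f"fixed columns: {self.model.n_fixed}",
            f"log restricted likelihood: {self.llf:.6f}",
            "-" * 54,
            f"{'parameter':<28}{'estimate':>12}{'std err':>12}",
        ]
        se = self.se if self.se is not None else [np.nan] * len(self.theta)
        for label, val, s in zip(self.param_labels(), self.theta, se):
            lines.append(f"{label:<28}{val:>12.6f}{s:>12.6f}")
        lines.append("-" * 54)
        for i, tr in enumerate(self.model.trait_names):
            try:
                h2 = self.heritability()[i]
                lines.append(f"h2({tr}) = {h2:.4f}")
            except ValueError:
                break
        if self.model.n_traits == 2:
            try:
                lines.append(
                    f"genetic correlation = {self.genetic_correlation():.4f}"
                )
            except ValueError:
                pass
        if self.floored:
            lines.append(f"components pinned at floor: {self.floored}")
        return "\n".join(lines)


def default_start(model: MixedModelData) -> VarianceComponents:
    """Half the phenotypic variance to the residual, the rest split equally.

    Multi-trait starts are diagonal (zero starting covariances).
    """
    n, t = model.n_records, model.n_traits
    names = component_names(model)
    k = len(names) - 1
    y = model.y.reshape(t, n)
    vary = np.var(y, axis=1, ddof=1)
    mats = []
    for name in names:
        share = 0.5 if name == RESIDUAL else 0.5 / max(k, 1)
        mats.append(np.diag(vary * share))
    return VarianceComponents(names, mats, t)


def _floor_value(model: MixedModelData) -> float:
    y = model.y.reshape(model.n_traits, model.n_records)
    return FLOOR_FRACTION * float(np.var(y, axis=1, ddof=1).mean())


def _project_pd(mat: np.ndarray, floor: float) -> np.ndarray:
    """Nearest symmetric matrix with eigenvalues clipped at the floor."""
    if mat.shape == (1, 1):
        return np.array([[max(mat[0, 0], floor)]])
    w, Q = np.linalg.eigh(0.5 * (mat + mat.T))
    return (Q * np.maximum(w, floor)) @ Q.T


def _apply_floor(
    vc: VarianceComponents, floor: float
) -> tuple[VarianceComponents, list[str]]:
    mats, hit = [], []
    for name, m in zip(vc.names, vc.matrices):
        fixed = _project_pd(m, floor)
        if not np.allclose(fixed, m):
            hit.append(name)
        mats.append(fixed)
    return VarianceComponents(list(vc.names), mats, vc.n_traits), hit


def _coerce_start(model: MixedModelData, start) -> VarianceComponents:
    names = component_names(model)
    if start is None:
        return default_start(model)
    if isinstance(start, VarianceComponents):
        return start.copy()
    return VarianceComponents.from_values(names, list(start), model.n_traits)


def run_reml(
    model: MixedModelData,
    method: str = "AI",
    start=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    em_warmup: int = 3,
    max_halvings: int = 5,
) -> REMLResults:
    """Iterate theta to the REML optimum under the chosen schedule.

    AI / AIEM: average-information updates with step halving and an EM
    fallback whenever a step is rejected (decreasing lnL, a component below
    the floor, or a singular AI matrix).  EM: pure expectation-maximisation.
    EMAI: ``em_warmup`` EM steps, then AI.  HI: AI started from
    Haseman-Elston regression estimates.  Convergence requires both the
    largest relative parameter change and |delta lnL| below ``tol``.
    """
    method = method.upper()
    if method not in ("AI", "EM", "AIEM", "EMAI", "HI"):
        raise ValueError(f"unknown REML schedule {method!r}")
    if tol <= 0:
        raise ValueError("tol must be positive")

    floor = _floor_value(model)
    if method == "HI":
        from .he import he_start

        vc = he_start(model, floor=floor) if start is None else _coerce_start(
            model, start
        )
    else:
        vc = _coerce_start(model, start)
    vc, floored = _apply_floor(vc, floor)

    state = REMLState(model, vc)
    trajectory = [{"iter": 0, "llf": state.llf,
                   "theta": vc.as_vector().tolist()}]
    converged = False
    names = component_names(model)
    params = _param_index(model)
    frozen: set[int] = set()  # component indices pinned at the boundary
    pin_trigger = 10.0 * floor

    def free_mask() -> np.ndarray:
        return np.array([c not in frozen for c, _, _ in params])

    def pin_boundary(
        cand: VarianceComponents, prev: VarianceComponents
    ) -> tuple[VarianceComponents, bool]:
        """Freeze components collapsing towards zero variance."""
        mats = []
        changed = False
        for c, (m, m0) in enumerate(zip(cand.matrices, prev.matrices)):
            d, d0 = np.diag(m), np.diag(m0)
            if c not in frozen and np.any(
                (d < pin_trigger) & (d0 < pin_trigger)
            ):
                frozen.add(c)
                changed = True
                if cand.names[c] not in floored:
                    floored.append(cand.names[c])
                logger.info("component %s pinned at the variance floor",
                            cand.names[c])
                m = _project_pd(m, floor)
            mats.append(m)
        return VarianceComponents(list(cand.names), mats, cand.n_traits), changed

    it = 0
    for it in range(1, max_iter + 1):
        pure_em = method == "EM" or (method == "EMAI" and it <= em_warmup)
        new_vc = None
        used_em = False
        mask = free_mask()
        if not pure_em and mask.any():
            g = state.gradient()[mask]
            AI = state.ai_matrix()[np.ix_(mask, mask)]
            try:
                step_free = scipy.linalg.solve(AI, g, assume_a="pos")
            except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
                logger.info("AI matrix singular at iteration %d; EM step", it)
                step_free = None
            if step_free is not None:
                step = np.zeros(len(params))
                step[mask] = step_free
                scale = 1.0
                for _ in range(max_halvings + 1):
                    cand_vec = state.vc.as_vector() + scale * step
                    cand = VarianceComponents.from_vector(
                        list(state.vc.names), cand_vec, model.n_traits
                    )
                    # clamp boundary violations rather than rejecting the
                    # whole step; the pin rule freezes persistent offenders
                    cand, _ = _apply_floor(cand, floor)
                    try:
                        cand_state = REMLState(model, cand)
                    except IndefiniteVError:
                        scale *= 0.5
                        continue
                    if cand_state.llf >= state.llf - 1e-10:
                        new_vc, new_state = cand, cand_state
                        break
                    scale *= 0.5
        if new_vc is None:  # EM step (pure EM or fallback)
            used_em = True
            cand = state.em_update()
            mats = [
                (state.vc.matrices[c] if c in frozen else m)
                for c, m in enumerate(cand.matrices)
            ]
            cand = VarianceComponents(list(cand.names), mats, cand.n_traits)
            cand, hit = _apply_floor(cand, floor)
            floored = sorted(set(floored) | set(hit))
            new_vc = cand
            new_state = REMLState(model, cand)
            if method == "EM" and new_state.llf < state.llf - 1e-8:
                logger.warning(
                    "EM log-likelihood decreased by %g at iteration %d",
                    state.llf - new_state.llf, it,
                )

        old = state.vc.as_vector()
        new_vc, pinned_now = pin_boundary(new_vc, state.vc)
        if pinned_now:
            new_state = REMLState(model, new_vc)
        new = new_vc.as_vector()
        denom = np.maximum(np.abs(old), floor)
        mask = free_mask()
        rel_change = float(
            np.max((np.abs(new - old) / denom)[mask]) if mask.any() else 0.0
        )
        dllf = abs(new_state.llf - state.llf)
        state = new_state
        trajectory.append(
            {"iter": it, "llf": state.llf, "theta": new.tolist(),
             "em": used_em}
        )
        if rel_change < tol and dllf < tol:
            converged = True
            break

    AI_opt = state.ai_matrix()
    se = None
    try:
        cov = scipy.linalg.inv(AI_opt)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        pass
    grad_norm = float(np.linalg.norm(state.gradient()))
    return REMLResults(
        model=model,
        vc=state.vc,
        llf=state.llf,
        converged=converged,
        n_iter=it,
        method=method,
        trajectory=trajectory,
        ai=AI_opt,
        se=se,
        floored=floored,
        gradient_norm=grad_norm,
    )
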