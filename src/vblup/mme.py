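"""Dense Henderson mixed-model-equation reference engine.

This is the classical route to the same estimator the V-based engine
computes: assemble the coefficient matrix C with kernel-inverse shifts,
solve C s = F for BLUEs and BLUPs, and form the restricted likelihood and
its derivatives from C, its inverse blocks and the residuals.  It exists as
an independent cross-check (every quantity here must match its V-based
twin) and as a didactic second path; it is deliberately dense, single-trait
and size-capped, not a production solver.

Notes on conventions: the likelihood's genetic count term uses n_i (the
number of levels of effect i), which makes the MME form identical to the
V-based -1/2 (ln|V| + ln|X'V^-1X| + y'Py); and the trace terms of the
first derivatives carry the sigma_e^2 factor that arises because C as
assembled here is the residual-unscaled system (its inverse is the
prediction-error variance divided by sigma_e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kinship import invert_relationship
from .model import MixedModelData
from .reml import VarianceComponents

SIZE_CAP = 2000


class MMEError(ValueError):
    pass


@dataclass
class MMESystem:
    """Assembled mixed-model equations C s = F with block bookkeeping."""

    C: np.ndarray
    F: np.ndarray
    W: np.ndarray  # [X R_1.. Z_1..]
    blocks: dict[str, slice]
    kernel_inverses: dict[str, np.ndarray]
    model: MixedModelData
    vc: VarianceComponents
    solution: np.ndarray | None = None
    Cinv: np.ndarray | None = None
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.C.shape[0]


def build_mme(
    model: MixedModelData,
    vc: VarianceComponents,
    kernel_inverses: dict[str, np.ndarray] | None = None,
) -> MMESystem:
    """Assemble C and F exactly as in Henderson's equations.

    C = W'W with the diagonal shifts (sigma_e^2/sigma_r^2) I per
    environmental block and (sigma_e^2/sigma_i^2) K_i^-1 per genetic block.
    """
    if model.n_traits != 1:
        raise MMEError("the MME reference engine is single-trait only")
    theta = vc.values_single()
    sig_e = theta[-1]
    n_total = model.n_fixed + sum(c.n_levels for c in model.components)
    if n_total > SIZE_CAP:
        raise MMEError(
            f"MME dimension {n_total} exceeds the reference cap {SIZE_CAP}"
        )
    mats = [model.X]
    blocks = {"fixed": slice(0, model.n_fixed)}
    pos = model.n_fixed
    for comp in model.components:
        mats.append(comp.incidence())
        blocks[comp.name] = slice(pos, pos + comp.n_levels)
        pos += comp.n_levels
    W = np.column_stack(mats)
    C = W.T @ W
    kern_inv: dict[str, np.ndarray] = {}
    for comp, sig in zip(model.components, theta[:-1]):
        sl = blocks[comp.name]
        if comp.kind == "env":
            C[sl, sl] += (sig_e / sig) * np.eye(comp.n_levels)
        else:
            if kernel_inverses and comp.name in kernel_inverses:
                Kinv = kernel_inverses[comp.name]
            else:
                Kinv = invert_relationship(comp.kernel).values
            kern_inv[comp.name] = Kinv
            C[sl, sl] += (sig_e / sig) * Kinv
    F = W.T @ model.y
    return MMESystem(
        C=C, F=F, W=W, blocks=blocks, kernel_inverses=kern_inv,
        model=model, vc=vc,
    )


def solve_mme(sys: MMESystem) -> MMESystem:
    """Dense solve; fills solutions, effects per block and C^-1."""
    try:
        sys.Cinv = scipy.linalg.inv(sys.C)
    except scipy.linalg.LinAlgError as err:
        raise MMEError(f"coefficient matrix singular: {err}")
    sys.solution = sys.Cinv @ sys.F
    for name, sl in sys.blocks.items():
        sys.effects[name] = sys.solution[sl]
    return sys


def _residuals(sys: MMESystem, y: np.ndarray) -> np.ndarray:
    return y - sys.W @ sys.solution


def mme_residuals(sys: MMESystem) -> np.ndarray:
    if sys.solution is None:
        solve_mme(sys)
    return _residuals(sys, sys.model.y)


def mme_loglik(sys: MMESystem) -> float:
    """Restricted log-likelihood from the MME pieces:

    -1/2 [ ln|C| + sum_r n_r ln s_r^2 + sum_i (n_i ln s_i^2 + ln|K_i|)
           + (n - n_b) ln s_e^2 + y'Py ],   y'Py = y'e / s_e^2.
    """
    if sys.solution is None:
        solve_mme(sys)
    model, vc = sys.model, sys.vc
    theta = vc.values_single()
    sig_e = theta[-1]
    n, nb = model.n_records, model.n_fixed
    sign, logdetC = np.linalg.slogdet(sys.C)
    if sign <= 0:
        raise MMEError("coefficient matrix not positive definite")
    # Residual count: C as assembled here is sigma_e^2 times the
    # residual-scaled system, so its determinant absorbs dim(C) factors of
    # sigma_e^2; the count n - n_b - n_r - sum(n_i) keeps this likelihood
    # identical to -1/2 (ln|V| + ln|X'V^-1X| + y'Py).
    n_random = sum(c.n_levels for c in model.components)
    acc = logdetC + (n - nb - n_random) * np.log(sig_e)
    for comp, sig in zip(model.components, theta[:-1]):
        acc += comp.n_levels * np.log(sig)
        if comp.kind == "genetic":
            _, logdetK = np.linalg.slogdet(comp.kernel.values)
            acc += logdetK
    e = _residuals(sys, model.y)
    acc += float(model.y @ e) / sig_e
    return -0.5 * acc


def run_reml_mme(
    model: MixedModelData,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 5,
):
    """AI-REML iterated entirely through the MME quantities.

    A debug/teaching path: same estimator as the V-based engine, computed
    from C, its inverse blocks and residuals.  Single-trait, dense,
    size-capped like the rest of this module.  Returns a REMLResults.
    """
    from .reml import (
        REMLResults,
        _apply_floor,
        _floor_value,
        default_start,
    )

    floor = _floor_value(model)
    vc = start.copy() if start is not None else default_start(model)
    vc, floored = _apply_floor(vc, floor)
    sys = solve_mme(build_mme(model, vc))
    llf = mme_loglik(sys)
    trajectory = [{"iter": 0, "llf": llf, "theta": vc.as_vector().tolist()}]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        AI, g = mme_reml_derivatives(sys)
        try:
            step = scipy.linalg.solve(AI, g, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            break
        old = vc.values_single()
        scale = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            cand = VarianceComponents.from_values(
                list(vc.names), np.maximum(old + scale * step, floor)
            )
            try:
                cand_sys = solve_mme(build_mme(model, cand))
                cand_llf = mme_loglik(cand_sys)
            except (MMEError, scipy.linalg.LinAlgError):
                scale *= 0.5
                continue
            if cand_llf >= llf - 1e-10:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        rel = float(np.max(np.abs(cand.values_single() - old)
                           / np.maximum(np.abs(old), floor)))
        dllf = abs(cand_llf - llf)
        vc, sys, llf = cand, cand_sys, cand_llf
        trajectory.append({"iter": it, "llf": llf,
                           "theta": vc.as_vector().tolist()})
        if rel < tol and dllf < tol:
            converged = True
            break
    AI_opt, g_opt = mme_reml_derivatives(sys)
    hit = [name for name, v in zip(vc.names, vc.values_single())
           if v <= floor * (1 + 1e-9)]
    return REMLResults(
        model=model, vc=vc, llf=llf, converged=converged, n_iter=it,
        method="AI(MME)", trajectory=trajectory, ai=AI_opt,
        se=np.sqrt(np.clip(np.diag(np.linalg.pinv(AI_opt)), 0, None)),
        floored=sorted(set(floored) | set(hit)),
        gradient_norm=float(np.linalg.norm(g_opt)),
    )


def _project_via_mme(sys: MMESystem, v: np.ndarray) -> np.ndarray:
    """P v computed by re-solving the MME with y replaced by v:
    P v = (v - W s_v) / sigma_e^2."""
    sig_e = sys.vc.values_single()[-1]
    s_v = sys.Cinv @ (sys.W.T @ v)
    return (v - sys.W @ s_v) / sig_e


def mme_reml_derivatives(
    sys: MMESystem,
) -> tuple[np.ndarray, np.ndarray]:
    """(AI matrix, gradient) in component order [env..., genetic..., residual].

    AI entries are (1/2) w_p' P w_q with the working vectors
    w_r = R rhat / s_r^2, w_i = Z_i uhat_i / s_i^2, w_e = e / s_e^2, and
    P w from repeated MME solves.  Gradients use tr(C^rr), tr(K^-1 C^uu)
    and the residuals, with the residual-scaling noted in the module
    docstring.
    """
    if sys.Cinv is None:
        solve_mme(sys)
    model, vc = sys.model, sys.vc
    theta = vc.values_single()
    sig_e = theta[-1]
    n, nb = model.n_records, model.n_fixed
    e = _residuals(sys, model.y)

    working: list[np.ndarray] = []
    for comp, sig in zip(model.components, theta[:-1]):
        eff = sys.effects[comp.name]
        working.append(comp.incidence() @ eff / sig)
    working.append(e / sig_e)

    k = len(working)
    Pw = [ _project_via_mme(sys, w) for w in working ]
    AI = np.empty((k, k))
    for p in range(k):
        for q in range(k):
            AI[p, q] = 0.5 * float(working[p] @ Pw[q])
    AI = 0.5 * (AI + AI.T)

    grad = np.empty(k)
    resid_acc = 0.0
    for j, (comp, sig) in enumerate(zip(model.components, theta[:-1])):
        sl = sys.blocks[comp.name]
        Cblk = sys.Cinv[sl, sl]
        if comp.kind == "env":
            tr = float(np.trace(Cblk))
        else:
            tr = float(np.sum(sys.kernel_inverses[comp.name] * Cblk.T))
        q_levels = comp.n_levels
        data_term = float((e / sig_e) @ working[j])
        grad[j] = -0.5 * (
            q_levels / sig - sig_e * tr / sig**2 - data_term
        )
        resid_acc += (q_levels - sig_e * tr / sig)
    grad[-1] = -0.5 * (
        (n - nb) / sig_e
        - resid_acc / sig_e
        - float(e @ e) / sig_e**2
    )
    return AI, grad
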