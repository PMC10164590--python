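"""Model construction: from a phenotype table plus relationship kernels to
the matrices of the linear mixed model

    y = X b + R r + sum_i Z_i u_i + e,

with r ~ N(0, I sigma_r^2) per environmental factor, u_i ~ N(0, K_i sigma_i^2)
and e ~ N(0, I sigma_e^2).  ``MixedModel`` is the user-facing entry point in
the statsmodels tradition: construct from data, then ``fit()`` (REML) or
``fit_he()`` (Haseman-Elston) to obtain a results object.

Multi-trait systems stack records trait-major; each variance component then
carries a t x t covariance matrix on a shared relationship structure, so
V = sum_c Sigma0_c (x) S_c with (x) the Kronecker product.  Version 1
requires complete records across traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kinship import RelationshipMatrix
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class VarComponent:
    """One random-effect term of the model.

    ``structure()`` returns the n x n phenotype-level covariance structure
    (R R' for an environmental factor, Z K Z' for a genetic kernel);
    ``n_levels`` is the number of effect levels (n_r, or the kernel
    dimension n_i -- every kernel ID is a level, phenotyped or not).
    """

    name: str
    kind: str  # "env" | "genetic"
    n_levels: int
    level_index: np.ndarray  # record -> level position (length n)
    kernel: RelationshipMatrix | None = None  # genetic terms only
    level_ids: list[str] = field(default_factory=list)
    _S: np.ndarray | None = None

    def structure(self) -> np.ndarray:
        if self._S is None:
            if self.kind == "env":
                eq = self.level_index[:, None] == self.level_index[None, :]
                self._S = eq.astype(np.float64)
            else:
                self._S = self.kernel.values[
                    np.ix_(self.level_index, self.level_index)
                ].copy()
        return self._S

    def incidence(self) -> np.ndarray:
        """Dense 0/1 incidence matrix (n x n_levels)."""
        Z = np.zeros((self.level_index.size, self.n_levels))
        Z[np.arange(self.level_index.size), self.level_index] = 1.0
        return Z


@dataclass
class MixedModelData:
    """Design matrices of the mixed model, single- or multi-trait stacked."""

    y: np.ndarray  # (n * t,)
    X: np.ndarray  # (n * t, p)
    components: list[VarComponent]
    n_records: int  # records per trait
    n_traits: int
    record_ids: list[str]
    trait_names: list[str]
    x_names: list[str] = field(default_factory=list)
    x_groups: dict[str, list[int]] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)
    dropped_records: int = 0

    def __post_init__(self) -> None:
        nt = self.n_records * self.n_traits
        if self.y.shape != (nt,):
            raise ModelError("y has wrong length")
        if self.X.shape[0] != nt:
            raise ModelError("X row count does not match y")
        if nt <= self.X.shape[1]:
            raise ModelError("more fixed-effect columns than records")

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def _design_matrix(
    pheno: PhenotypeTable, rows: np.ndarray
) -> tuple[np.ndarray, list[str], dict[str, list[int]], list[str]]:
    """Intercept + reference-coded factors + covariates, with rank repair."""
    df = pheno.data.iloc[rows]
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    groups: dict[str, list[int]] = {}
    dropped: list[str] = []
    seen_factor_signatures: dict[tuple, str] = {}
    for fac in pheno.fixed:
        levels = sorted(df[fac].unique())
        if len(levels) < 2:
            logger.warning("fixed factor %s has a single level; dropped", fac)
            dropped.append(fac)
            continue
        sig = tuple(df[fac].tolist())
        if sig in seen_factor_signatures:
            logger.warning(
                "fixed factor %s duplicates %s; dropped",
                fac, seen_factor_signatures[sig],
            )
            dropped.append(fac)
            continue
        seen_factor_signatures[sig] = fac
        groups[fac] = []
        for lvl in levels[1:]:  # first level is the reference
            groups[fac].append(len(names))
            names.append(f"{fac}[{lvl}]")
            cols.append((df[fac] == lvl).to_numpy(dtype=np.float64))
    for cov in pheno.covariates:
        groups[cov] = [len(names)]
        names.append(cov)
        cols.append(df[cov].to_numpy(dtype=np.float64))
    X = np.column_stack(cols)

    # numerical rank repair: drop dependent columns (never the intercept)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        if 0 not in keep:  # keep intercept, drop its pivot partner instead
            keep = sorted({0, *keep[1:]})
        gone = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("rank-deficient design; dropping columns %s", gone)
        dropped.extend(gone)
        remap = {old: new for new, old in enumerate(keep)}
        X = X[:, keep]
        names = [names[j] for j in keep]
        groups = {
            g: [remap[j] for j in idx if j in remap]
            for g, idx in groups.items()
        }
        groups = {g: idx for g, idx in groups.items() if idx}
    return X, names, groups, dropped


def build_model(
    pheno: PhenotypeTable,
    kernels: dict[str, RelationshipMatrix],
    traits: list[str] | None = None,
) -> MixedModelData:
    """Assemble MixedModelData for the selected trait(s).

    Records with a missing value in any selected trait are removed
    (complete-records rule); records whose individual is absent from any
    kernel are dropped with a logged count.
    """
    traits = list(traits or pheno.traits[:1])
    for t in traits:
        if t not in pheno.traits:
            raise ModelError(f"{t!r} is not a trait column of the table")
    if not kernels and not pheno.random:
        logger.info("model has no random terms besides the residual")

    df = pheno.data
    ok = ~df[traits].isna().any(axis=1)
    kernel_index: dict[str, dict[str, int]] = {
        name: {iid: i for i, iid in enumerate(K.ids)}
        for name, K in kernels.items()
    }
    ids = df[pheno.id_column]
    for name, idx in kernel_index.items():
        ok &= ids.isin(idx).to_numpy()
    rows = np.flatnonzero(ok.to_numpy())
    dropped_records = len(df) - rows.size
    if dropped_records:
        logger.warning(
            "dropped %d records (missing trait or not in a kernel)",
            dropped_records,
        )
    if rows.size == 0:
        raise ModelError("no usable records after filtering")

    record_ids = ids.iloc[rows].tolist()
    X1, names, groups, dropped_cols = _design_matrix(pheno, rows)
    y1 = np.column_stack([df[t].to_numpy(dtype=np.float64)[rows] for t in traits])

    components: list[VarComponent] = []
    for fac in pheno.random:
        vals = df[fac].iloc[rows]
        levels = sorted(vals.unique())
        lut = {lvl: i for i, lvl in enumerate(levels)}
        components.append(
            VarComponent(
                name=fac,
                kind="env",
                n_levels=len(levels),
                level_index=vals.map(lut).to_numpy(dtype=np.int64),
                level_ids=levels,
            )
        )
    for name, K in kernels.items():
        idx = kernel_index[name]
        components.append(
            VarComponent(
                name=name,
                kind="genetic",
                n_levels=K.n,
                level_index=np.array([idx[i] for i in record_ids]),
                kernel=K,
                level_ids=list(K.ids),
            )
        )

    t = len(traits)
    n = rows.size
    if t == 1:
        y = y1[:, 0]
        X = X1
    else:
        y = y1.T.reshape(-1)  # trait-major stack
        X = np.kron(np.eye(t), X1)
        names = [f"{tr}:{nm}" for tr in traits for nm in names]
        groups = {
            f"{tr}:{g}": [k * X1.shape[1] + j for j in idx]
            for k, tr in enumerate(traits)
            for g, idx in groups.items()
        }
    return MixedModelData(
        y=y,
        X=X,
        components=components,
        n_records=n,
        n_traits=t,
        record_ids=record_ids,
        trait_names=traits,
        x_names=names,
        x_groups=groups,
        dropped_columns=dropped_cols,
        dropped_records=dropped_records,
    )


class MixedModel:
    """Linear mixed model for genetic evaluation.

    Parameters
    ----------
    data : MixedModelData
        Assembled design; use :meth:`from_phenotypes` for the common path.

    Examples
    --------
    >>> model = MixedModel.from_phenotypes(pheno, {"additive": G})
    >>> res = model.fit(method="AI")      # doctest: +SKIP
    >>> print(res.summary())              # doctest: +SKIP
    """

    def __init__(self, data: MixedModelData):
        self.data = data

    @classmethod
    def from_phenotypes(
        cls,
        pheno: PhenotypeTable,
        kernels: dict[str, RelationshipMatrix],
        traits: list[str] | None = None,
    ) -> "MixedModel":
        return cls(build_model(pheno, kernels, traits))

    def fit(
        self,
        method: str = "AI",
        start=None,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        """Estimate variance components by REML; returns REMLResults."""
        from .reml import run_reml

        return run_reml(self.data, method=method, start=start, tol=tol,
                        max_iter=max_iter)

    def fit_he(self, form: str = "cross_product"):
        """Haseman-Elston regression; returns HEResults."""
        from .he import he_regression

        return he_regression(self.data, form=form)
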