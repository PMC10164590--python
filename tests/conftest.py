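"""Shared fixtures: randomized small mixed-model instances and tiny
simulated datasets, all generated programmatically under fixed seeds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vblup as vb
from vblup.phenotypes import PhenotypeTable
from vblup.reml import VarianceComponents, component_names


def random_kernel(rng: np.random.Generator, n: int,
                  ridge: float = 0.3) -> np.ndarray:
    """Well-conditioned random PSD kernel with unit-scale diagonal."""
    B = rng.normal(size=(n, n))
    K = B @ B.T / n + ridge * np.eye(n)
    return K / np.mean(np.diag(K))


def random_instance(
    seed: int,
    n: int = 15,
    n_genetic: int = 1,
    with_env: bool = True,
    n_extra_kernel_ids: int = 3,
):
    """A random single-trait model with known-PD kernels plus true-ish theta.

    Returns (model, vc) where vc holds strictly positive variance
    components at which V is comfortably positive definite.
    """
    rng = np.random.default_rng(seed)
    nk = n + n_extra_kernel_ids
    kernels = {}
    for g in range(n_genetic):
        ids = [f"I{i}" for i in range(nk)]
        kernels[f"g{g + 1}"] = vb.RelationshipMatrix(
            random_kernel(rng, nk), ids, kind="G"
        )
    cols = {
        "id": [f"I{i}" for i in range(n)],
        "y": rng.normal(size=n),
        "sex": rng.choice(["m", "f"], size=n),
        "x1": rng.normal(size=n),
    }
    fixed, covs, random = ["sex"], ["x1"], []
    if with_env:
        cols["grp"] = rng.choice([f"b{j}" for j in range(3)], size=n)
        random = ["grp"]
    tab = PhenotypeTable(
        pd.DataFrame(cols), id_column="id", traits=["y"], fixed=fixed,
        covariates=covs, random=random,
    )
    model = vb.build_model(tab, kernels)
    k = len(model.components)
    theta = rng.uniform(0.3, 1.2, size=k + 1)
    vc = VarianceComponents.from_values(component_names(model), theta)
    return model, vc


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated population: 20 individuals, 60 markers, 1 trait."""
    cfg = vb.SimConfig(
        seed=404, n_base_male=5, n_base_female=5, n_generations=1,
        n_markers=60, n_qtl=8, h2=(0.4,), genetic_correlation=0.0,
        env_variance=(0.1,), env_levels=(4,), fixed_levels=(2,),
    )
    return vb.simulate(cfg)


@pytest.fixture(scope="session")
def gblup_sim():
    """Medium single-trait population for solver/EBV checks (n=300)."""
    cfg = vb.SimConfig(
        seed=77, n_base_male=75, n_base_female=75, n_generations=1,
        n_markers=1200, n_qtl=60, h2=(0.4,), genetic_correlation=0.0,
        env_variance=(0.1,), env_levels=(10,), fixed_levels=(2,),
    )
    return vb.simulate(cfg)
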