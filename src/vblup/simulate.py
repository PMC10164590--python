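"""Population and phenotype simulator for validating the estimators by
parameter recovery.

The design mirrors a classical breeding-evaluation benchmark: a base
generation of unrelated individuals (half males, half females) drawn
marker-wise from Hardy-Weinberg proportions at uniform allele frequencies,
followed by discrete generations of random male-female pairing restricted
to the immediately preceding generation (no backcrossing), each pair
leaving a fixed-size litter (one male and one female at the default litter
of two).  Markers segregate independently (no linkage map).

Two genetically correlated traits share a randomly chosen QTL set; effects
are bivariate normal with zero mean and unit variance at the configured
effect correlation.  Per trait, true breeding values are rescaled so the
realised genetic fraction of the (unit) phenotypic variance equals the
configured heritability; environmental random effects (uniformly assigned
levels) and residual noise fill the remaining budget, and fixed-factor
constants are added on top.  Every output is a pure function of the
configuration, including its mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .phenotypes import PhenotypeTable


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation design.  Defaults follow the benchmark design:
    500 + 500 base individuals, nine generations of random mating with
    litter size two, 100 000 markers, 600 shared QTL, heritabilities 0.1
    and 0.3, genetic correlation 0.3, two fixed factors and two
    environmental random effects."""

    seed: int
    n_base_male: int = 500
    n_base_female: int = 500
    n_generations: int = 9
    litter_size: int = 2
    n_markers: int = 100_000
    n_qtl: int = 600
    h2: tuple[float, ...] = (0.1, 0.3)
    genetic_correlation: float = 0.3
    env_variance: tuple[float, ...] = (0.1, 0.1)
    env_levels: tuple[int, ...] = (20, 20)
    fixed_levels: tuple[int, ...] = (2, 4)
    fixed_effect_scale: float = 0.5
    freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        for h in self.h2:
            if not 0.0 <= h < 1.0:
                raise SimulationError("heritabilities must lie in [0, 1)")
        if abs(self.genetic_correlation) > 1.0:
            raise SimulationError("|genetic correlation| must be <= 1")
        if self.n_qtl > self.n_markers:
            raise SimulationError("n_qtl cannot exceed n_markers")
        if len(self.env_variance) != len(self.env_levels):
            raise SimulationError("env_variance and env_levels differ in length")
        for h in self.h2:
            if h + sum(self.env_variance) >= 1.0:
                raise SimulationError(
                    "variance budget exceeded: h2 + environmental "
                    "proportions must stay below 1"
                )

    @classmethod
    def reduced(cls, seed: int, **overrides) -> "SimConfig":
        """Scaled-down design for routine testing: 200 + 200 base
        individuals, three generations, 5 000 markers, 120 QTL."""
        base = dict(
            n_base_male=200,
            n_base_female=200,
            n_generations=3,
            n_markers=5_000,
            n_qtl=120,
        )
        base.update(overrides)
        return cls(seed=seed, **base)


@dataclass
class SimTruth:
    """Generating quantities needed to audit any estimate."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # (n_qtl, t), on the rescaled phenotype scale
    breeding_values: np.ndarray  # (n_individuals, t)
    genetic_variance: np.ndarray  # realised var of TBV per trait
    env_variance: np.ndarray
    residual_variance: np.ndarray
    realized_h2: np.ndarray
    realized_genetic_correlation: float
    fixed_values: list[np.ndarray]


@dataclass
class SimOutput:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: SimTruth
    sex: np.ndarray = field(default=None)  # "M"/"F" per individual


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(cfg.seed)
    pop, phe = ss.spawn(2)
    return np.random.default_rng(pop), np.random.default_rng(phe)


def simulate_pedigree(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, np.ndarray, np.ndarray]:
    """Pedigree structure, sexes and generation numbers (cheap at any
    scale; genotype simulation is separate)."""
    rng = rng or _rngs(cfg)[0]
    if cfg.litter_size < 1:
        raise SimulationError("litter_size must be >= 1")
    ids: list[str] = []
    sires: list[int] = []
    dams: list[int] = []
    sexes: list[str] = []
    gens: list[int] = []

    def add(sex: str, s: int, d: int, g: int) -> int:
        idx = len(ids)
        ids.append(f"ID{idx + 1:06d}")
        sires.append(s)
        dams.append(d)
        sexes.append(sex)
        gens.append(g)
        return idx

    males = [add("M", -1, -1, 0) for _ in range(cfg.n_base_male)]
    females = [add("F", -1, -1, 0) for _ in range(cfg.n_base_female)]

    for g in range(1, cfg.n_generations + 1):
        if len(males) != len(females):
            raise SimulationError(
                f"cannot pair {len(males)} males with {len(females)} females"
            )
        order_m = rng.permutation(len(males))
        order_f = rng.permutation(len(females))
        new_m: list[int] = []
        new_f: list[int] = []
        for im, jf in zip(order_m, order_f):
            s, d = males[im], females[jf]
            for slot in range(cfg.litter_size):
                sex = "M" if slot % 2 == 0 else "F"
                idx = add(sex, s, d, g)
                (new_m if sex == "M" else new_f).append(idx)
        males, females = new_m, new_f

    ped = Pedigree(ids, np.array(sires), np.array(dams))
    return ped, np.array(sexes), np.array(gens)


def _mendelian_gametes(
    parent_codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted allele count per marker per offspring row."""
    het = parent_codes == 1
    gam = (parent_codes == 2).astype(np.int8)
    gam[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return gam


def simulate_population(cfg: SimConfig) -> tuple[Pedigree, GenotypeMatrix, np.ndarray]:
    """Pedigree plus genotypes; returns (pedigree, genotypes, sexes)."""
    rng, _ = _rngs(cfg)
    ped, sexes, gens = simulate_pedigree(cfg, rng)
    n, m = len(ped), cfg.n_markers

    lo, hi = cfg.freq_range
    freqs = rng.uniform(lo, hi, size=m)
    codes = np.empty((n, m), dtype=np.int8)
    n_base = cfg.n_base_male + cfg.n_base_female
    codes[:n_base] = rng.binomial(2, freqs, size=(n_base, m)).astype(np.int8)
    for g in range(1, cfg.n_generations + 1):
        idx = np.flatnonzero(gens == g)
        codes[idx] = _mendelian_gametes(
            codes[ped.sire[idx]], rng
        ) + _mendelian_gametes(codes[ped.dam[idx]], rng)

    markers = pd.DataFrame(
        {
            "chrom": "1",
            "id": [f"M{j + 1:06d}" for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "allele1": "A",
            "allele2": "B",
        }
    )
    geno = GenotypeMatrix(codes, list(ped.ids), markers)
    return ped, geno, sexes


def simulate_phenotypes(
    cfg: SimConfig,
    geno: GenotypeMatrix,
    sexes: np.ndarray | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes on a unit total-variance scale per trait.

    The first fixed factor reuses the recorded sexes when provided (its
    level count is then forced to 2); remaining factors get uniformly
    random levels.  Environmental and residual effects are drawn
    independently per trait (no environmental or residual correlation).
    """
    _, rng = _rngs(cfg)
    n = geno.n_individuals
    t = len(cfg.h2)

    qtl = np.sort(
        rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
    )
    rho = cfg.genetic_correlation
    corr = np.full((t, t), rho) + (1.0 - rho) * np.eye(t)
    effects = rng.multivariate_normal(
        np.zeros(t), corr, size=cfg.n_qtl
    )  # unit variance, correlated across traits

    dose = geno.codes[:, qtl].astype(np.float64)
    tbv = dose @ effects  # (n, t)
    tbv -= tbv.mean(axis=0)
    h2 = np.array(cfg.h2)
    raw_sd = tbv.std(axis=0, ddof=1)
    scale = np.sqrt(h2) / raw_sd
    tbv *= scale
    effects = effects * scale

    env_cols: dict[str, np.ndarray] = {}
    env_contrib = np.zeros((n, t))
    for j, (prop, nlev) in enumerate(zip(cfg.env_variance, cfg.env_levels)):
        lev = rng.integers(0, nlev, size=n)
        vals = rng.normal(0.0, np.sqrt(prop), size=(nlev, t))
        env_contrib += vals[lev]
        env_cols[f"env{j + 1}"] = lev

    resid_var = 1.0 - h2 - sum(cfg.env_variance)
    resid = rng.normal(0.0, np.sqrt(resid_var), size=(n, t))

    fixed_cols: dict[str, np.ndarray] = {}
    fixed_contrib = np.zeros((n, t))
    fixed_values: list[np.ndarray] = []
    for j, nlev in enumerate(cfg.fixed_levels):
        name = f"factor{j + 1}"
        if j == 0 and sexes is not None:
            lev = (sexes == "F").astype(int)
            nlev = 2
        else:
            lev = rng.integers(0, nlev, size=n)
        vals = cfg.fixed_effect_scale * np.arange(nlev) / max(nlev - 1, 1)
        fixed_values.append(vals)
        fixed_contrib += vals[lev][:, None]
        fixed_cols[name] = lev

    pheno = fixed_contrib + env_contrib + tbv + resid

    data = {"id": list(geno.individual_ids)}
    for i in range(t):
        data[f"trait{i + 1}"] = pheno[:, i]
    for name, lev in fixed_cols.items():
        data[name] = [f"L{v + 1}" for v in lev]
    for name, lev in env_cols.items():
        data[name] = [f"E{v + 1}" for v in lev]
    table = PhenotypeTable(
        pd.DataFrame(data),
        id_column="id",
        traits=[f"trait{i + 1}" for i in range(t)],
        fixed=list(fixed_cols),
        random=list(env_cols),
    )

    gvar = tbv.var(axis=0, ddof=1)
    # variance on the model scale: fixed-effect contributions are removed
    # by X in any analysis, so they do not belong in the h2 denominator
    pvar = (pheno - fixed_contrib).var(axis=0, ddof=1)
    if t >= 2 and tbv[:, 0].std() > 0 and tbv[:, 1].std() > 0:
        realized_rg = float(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
    else:
        realized_rg = float("nan")
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=effects,
        breeding_values=tbv,
        genetic_variance=gvar,
        env_variance=np.array(cfg.env_variance),
        residual_variance=resid_var,
        realized_h2=gvar / pvar,
        realized_genetic_correlation=realized_rg,
        fixed_values=fixed_values,
    )
    return table, truth


def simulate(cfg: SimConfig) -> SimOutput:
    """Full run: pedigree, genotypes, phenotypes and the truth record."""
    ped, geno, sexes = simulate_population(cfg)
    table, truth = simulate_phenotypes(cfg, geno, sexes)
    return SimOutput(ped, geno, table, truth, sexes)


# ---------------------------------------------------------------------------
# deterministic hand-sized fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str) -> SimOutput | tuple:
    """Registered tiny datasets with hand-verifiable expected values."""
    if name == "trio":
        from .pedigree import pedigree_from_records

        ped = pedigree_from_records(
            [("A", None, None), ("B", None, None), ("C", "A", "B")]
        )
        return ped
    if name == "gblup8":
        cfg = SimConfig(
            seed=20_08,
            n_base_male=4,
            n_base_female=4,
            n_generations=0,
            n_markers=12,
            n_qtl=4,
            h2=(0.5,),
            genetic_correlation=0.0,
            env_variance=(),
            env_levels=(),
            fixed_levels=(2,),
        )
        return simulate(cfg)
    raise KeyError(f"unknown fixture {name!r}")
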