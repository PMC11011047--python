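"""Synthetic pedigrees and repeated ordinal phenotype records.

The generator produces data with exactly the covariance structure the
repeatability animal model assumes — breeding values follow
``N(0, A ⊗ Σu)`` via the downward Mendelian-sampling recursion, a
permanent environmental deviation is drawn once per animal, and each
record adds fixed-factor effects plus an independent residual.  True
parameters are carried alongside so estimators can be checked against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (
    PedigreeTable,
    compute_inbreeding,
    mendelian_variance_scale,
    validate_and_sort,
)

FACTORS = ("gender", "birth_period", "stud_criteria", "age_group", "appraiser")
FACTOR_LEVELS = {
    "gender": 2,
    "birth_period": 3,
    "stud_criteria": 4,
    "age_group": 2,
    "appraiser": 3,
}


class SimulationError(ValueError):
    pass


def _as_cov(mat, t: int, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(mat, dtype=float))
    if m.shape != (t, t):
        raise SimulationError(f"{name} must be {t}x{t}, got {m.shape}")
    if not np.allclose(m, m.T):
        raise SimulationError(f"{name} must be symmetric")
    return m


def _chol_psd(m: np.ndarray, name: str) -> np.ndarray:
    """Cholesky factor, accepting the exact-zero matrix as a degenerate case."""
    if not m.any():
        return np.zeros_like(m)
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise SimulationError(f"{name} is not positive definite") from None


@dataclass
class SimulationConfig:
    """Knobs for a study-shaped simulated dataset.

    Defaults approximate the target design: ~1000-animal pedigree over 3
    discrete generations, 500 evaluated animals averaging 2.2 records
    each, and the five fixed factors with 2/3/4/2/3 levels.
    """

    n_founders: int = 250
    n_generations: int = 3
    n_per_generation: int = 256
    # cap on breeding males/females per generation; None = all available.
    # Studbooks use few active sires; large half-sib families make the
    # genetic (co)variances much better identified.
    n_sires: int | None = None
    n_dams: int | None = None
    n_evaluated: int = 500
    mean_records: float = 2.2
    traits: tuple[str, ...] = ("trait1",)
    sigma_u: np.ndarray | float = 0.25
    sigma_pe: np.ndarray | float = 0.20
    sigma_e: np.ndarray | float = 0.55
    fixed_effects: dict[str, np.ndarray] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def cov(self, which: str) -> np.ndarray:
        return _as_cov(getattr(self, f"sigma_{which}"), self.n_traits, f"sigma_{which}")

    def effects(self, factor: str) -> np.ndarray:
        """Per-level effect table for one factor, (levels, traits)."""
        levels = FACTOR_LEVELS[factor]
        eff = self.fixed_effects.get(factor)
        if eff is None:
            return np.zeros((levels, self.n_traits))
        eff = np.atleast_2d(np.asarray(eff, dtype=float))
        if eff.shape == (1, levels) and self.n_traits == 1:
            eff = eff.T
        if eff.shape != (levels, self.n_traits):
            raise SimulationError(
                f"fixed_effects[{factor!r}] must be ({levels}, {self.n_traits})"
            )
        return eff

    def retention(self, trait: str) -> float:
        r = float(self.missingness.get(trait, 1.0))
        if not 0.0 < r <= 1.0:
            raise SimulationError(f"retention for {trait!r} must be in (0, 1]")
        return r


@dataclass
class SimulatedDataset:
    """Pedigree + records + the truth that generated them."""

    pedigree: PedigreeTable
    records: pd.DataFrame
    true_u: pd.DataFrame
    true_pe: pd.DataFrame
    config: SimulationConfig


def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> PedigreeTable:
    """Random-mating pedigree with non-overlapping generations.

    Generation ``g`` animals have both parents drawn uniformly from the
    males/females of generation ``g - 1``; sexes are assigned ~1:1.
    Birth years are ``2000 + g`` so the sort order is reproducible.
    """
    if cfg.n_founders < 2:
        raise SimulationError("need at least 2 founders")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    ids: list[str] = []
    sire: list[str] = []
    dam: list[str] = []
    year: list[int] = []
    sex: list[str] = []
    generation: list[int] = []

    def _add(gen: int, n: int, prev: list[int]) -> list[int]:
        start = len(ids)
        males = [i for i in prev if sex[i] == "male"]
        females = [i for i in prev if sex[i] == "female"]
        if cfg.n_sires is not None and len(males) > cfg.n_sires:
            males = [males[j] for j in rng.choice(len(males), cfg.n_sires, replace=False)]
        if cfg.n_dams is not None and len(females) > cfg.n_dams:
            females = [females[j] for j in rng.choice(len(females), cfg.n_dams, replace=False)]
        for k in range(n):
            ids.append(f"G{gen}_{k:04d}")
            year.append(2000 + gen)
            sex.append("male" if rng.random() < 0.5 else "female")
            generation.append(gen)
            if gen == 0:
                sire.append("")
                dam.append("")
            else:
                sire.append(ids[males[rng.integers(len(males))]])
                dam.append(ids[females[rng.integers(len(females))]])
        return list(range(start, len(ids)))

    prev = _add(0, cfg.n_founders, [])
    # guarantee both sexes among founders so mating is always possible
    if "male" not in {sex[i] for i in prev}:
        sex[prev[0]] = "male"
    if "female" not in {sex[i] for i in prev}:
        sex[prev[1]] = "female"
    for g in range(1, cfg.n_generations + 1):
        if "male" not in {sex[i] for i in prev}:
            sex[prev[0]] = "male"
        if "female" not in {sex[i] for i in prev}:
            sex[prev[-1]] = "female"
        prev = _add(g, cfg.n_per_generation, prev)

    frame = pd.DataFrame(
        {"animal": ids, "sire": sire, "dam": dam, "birth_year": year, "sex": sex}
    )
    ped = validate_and_sort(frame)
    gen_by_id = dict(zip(ids, generation))
    ped.meta["generation"] = np.array([gen_by_id[a] for a in ped.ids])
    return ped


def simulate_breeding_values(
    ped: PedigreeTable,
    sigma_u,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Breeding values ``u ~ N(0, A ⊗ Σu)`` by downward recursion.

    ``u_i = 0.5 u_s + 0.5 u_d + m_i`` with Mendelian term
    ``m_i ~ N(0, d_i Σu)``, ``d_i`` from the inbreeding of the parents;
    founders are drawn directly from ``N(0, Σu)``.
    """
    if not ped.is_sorted:
        raise SimulationError("pedigree must be sorted")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma_u = np.atleast_2d(np.asarray(sigma_u, dtype=float))
    t = sigma_u.shape[0]
    L = _chol_psd(_as_cov(sigma_u, t, "sigma_u"), "sigma_u")

    F = compute_inbreeding(ped)
    d = mendelian_variance_scale(ped, F)
    z = rng.standard_normal((ped.n, t))
    u = np.zeros((ped.n, t))
    for i in range(ped.n):
        mean = np.zeros(t)
        if ped.sire[i] >= 0:
            mean += 0.5 * u[ped.sire[i]]
        if ped.dam[i] >= 0:
            mean += 0.5 * u[ped.dam[i]]
        u[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return u


def simulate_records(
    ped: PedigreeTable,
    true_u: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    evaluated: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated evaluation records for a subset of animals.

    Returns ``(records, true_pe)``.  Gender, birth period and stud
    criterion are fixed per animal; appraiser and age group vary per
    record.  Trait columns hold latent Gaussian scores; per-trait
    missingness is applied as NaN, keeping at least one observed trait
    per record.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    t = cfg.n_traits
    if true_u.shape != (ped.n, t):
        raise SimulationError("true_u shape does not match pedigree/traits")

    if evaluated is None:
        gen = ped.meta.get("generation")
        candidates = np.arange(ped.n) if gen is None else np.where(gen > 0)[0]
        if len(candidates) < cfg.n_evaluated:
            candidates = np.arange(ped.n)
        evaluated = np.sort(rng.choice(candidates, size=cfg.n_evaluated, replace=False))
    else:
        evaluated = ped.index_of(evaluated)
    p = len(evaluated)

    L_pe = _chol_psd(cfg.cov("pe"), "sigma_pe")
    L_e = _chol_psd(cfg.cov("e"), "sigma_e")
    pe = rng.standard_normal((p, t)) @ L_pe.T

    # per-animal static factors
    sex = ped.sex[evaluated]
    gender = np.where(sex == "female", 2, 1)
    years = ped.birth_year[evaluated].astype(float)
    cuts = np.quantile(ped.birth_year.astype(float), [1 / 3, 2 / 3])
    birth_period = 1 + (years > cuts[0]).astype(int) + (years > cuts[1]).astype(int)
    stud = rng.integers(1, FACTOR_LEVELS["stud_criteria"] + 1, size=p)

    n_rec = 1 + rng.poisson(max(cfg.mean_records - 1.0, 0.0), size=p)
    rows = []
    eff = {f: cfg.effects(f) for f in FACTORS}
    pe_rows = []
    for k, (ai, nr) in enumerate(zip(evaluated, n_rec)):
        pe_rows.append((ped.ids[ai], *pe[k]))
        for _ in range(nr):
            appraiser = int(rng.integers(1, FACTOR_LEVELS["appraiser"] + 1))
            age_group = int(rng.integers(1, FACTOR_LEVELS["age_group"] + 1))
            fac = {
                "gender": int(gender[k]),
                "birth_period": int(birth_period[k]),
                "stud_criteria": int(stud[k]),
                "age_group": age_group,
                "appraiser": appraiser,
            }
            b = sum(eff[f][fac[f] - 1] for f in FACTORS)
            e = L_e @ rng.standard_normal(t)
            y = b + true_u[ai] + pe[k] + e
            rows.append((ped.ids[ai], *fac.values(), *y))

    records = pd.DataFrame(
        rows, columns=["animal", *FACTORS, *cfg.traits]
    )
    records.insert(0, "record_id", np.arange(len(records)))

    # per-trait missingness, never blanking a whole record
    for trait in cfg.traits:
        r = cfg.retention(trait)
        if r < 1.0:
            drop = rng.random(len(records)) > r
            records.loc[drop, trait] = np.nan
    all_missing = records[list(cfg.traits)].isna().all(axis=1)
    if all_missing.any():
        records = records.loc[~all_missing].reset_index(drop=True)

    true_pe = pd.DataFrame(pe_rows, columns=["animal", *cfg.traits])
    return records, true_pe


def discretize_to_classes(
    records: pd.DataFrame,
    thresholds: dict[str, tuple[float, float]],
    traits=None,
) -> pd.DataFrame:
    """Map latent scores to ordinal classes 0/1/2 by two cutpoints.

    ``score = 0`` below the first threshold, ``1`` between the two, ``2``
    at or above the second.  Missing values stay missing.
    """
    out = records.copy()
    traits = list(thresholds.keys()) if traits is None else list(traits)
    for trait in traits:
        t1, t2 = thresholds[trait]
        # (+inf, +inf) is allowed as the degenerate "everything class 0" case
        if t1 >= t2 and not t1 == t2 == np.inf:
            raise SimulationError(f"thresholds for {trait!r} must be strictly increasing")
        x = out[trait].to_numpy(dtype=float)
        score = np.where(x < t1, 0.0, np.where(x < t2, 1.0, 2.0))
        score = np.where(np.isnan(x), np.nan, score)
        out[trait] = score
    return out


def quantile_thresholds(values: np.ndarray, share0: float, share1: float) -> tuple[float, float]:
    """Cutpoints putting ~``share0`` of values in class 0 and ``share1`` in class 1."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return (float(np.quantile(v, share0)), float(np.quantile(v, share0 + share1)))


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """End-to-end generation: pedigree, breeding values, records, truth."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    u = simulate_breeding_values(ped, cfg.cov("u"), rng)
    records, true_pe = simulate_records(ped, u, cfg, rng)
    if cfg.thresholds:
        records = discretize_to_classes(records, cfg.thresholds, cfg.traits)
    true_u = pd.DataFrame(u, columns=list(cfg.traits))
    true_u.insert(0, "animal", ped.ids)
    return SimulatedDataset(
        pedigree=ped, records=records, true_u=true_u, true_pe=true_pe, config=cfg
    )
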