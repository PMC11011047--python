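"""Multi-trait repeatability animal model fitted by Gibbs sampling.

Model per record:  ``y = Xb + Zu + Wpe + e`` with
``u ~ N(0, A ⊗ Σu)``, ``pe ~ N(0, I ⊗ Σpe)`` (optionally pedigree-
structured) and ``e ~ N(0, I ⊗ Σe)``.  Fixed effects carry flat priors;
variance components carry flat (limiting inverse-Wishart) priors, so the
full conditionals are Gaussian for locations and inverse-Wishart for
(co)variance matrices.  Missing trait scores are handled by data
augmentation from their conditional normal given the record's observed
traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._kernels import update_fixed, update_random
from .pedigree import PedigreeTable, build_A_inverse, compute_inbreeding
from .simulate import FACTOR_LEVELS, FACTORS

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8


class DesignError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which traits and factors to fit, and how to run the chain."""

    traits: tuple[str, ...]
    fixed_factors: tuple[str, ...] = FACTORS
    n_iterations: int = 250_000
    burn_in: int = 50_000
    thin: int = 1
    seed: int = 0
    missing_handling: str = "augment"  # or "complete_cases"
    pe_covariance: str = "identity"  # or "pedigree"
    include_pe: bool = True
    store_location: bool = False

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.fixed_factors = tuple(self.fixed_factors)
        if not self.traits:
            raise DesignError("at least one trait is required")
        if not 0 <= self.burn_in < self.n_iterations:
            raise DesignError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise DesignError("thin must be >= 1")
        if self.missing_handling not in ("augment", "complete_cases"):
            raise DesignError(f"unknown missing_handling {self.missing_handling!r}")
        if self.pe_covariance not in ("identity", "pedigree"):
            raise DesignError(f"unknown pe_covariance {self.pe_covariance!r}")
        unknown = set(self.fixed_factors) - set(FACTORS)
        if unknown:
            raise DesignError(f"unknown fixed factors: {sorted(unknown)}")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_saved(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class MixedModelEquations:
    """Design matrices and bookkeeping for one Gibbs run."""

    X: np.ndarray
    x_names: list[str]
    y: np.ndarray  # (n, t) with NaN for missing
    rec_animal: np.ndarray  # record -> pedigree row
    rec_pe: np.ndarray  # record -> pe level
    n_pe: int
    A_inv: sparse.csr_matrix
    pe_prior: sparse.csr_matrix
    ped: PedigreeTable
    spec: ModelSpec
    # CSC view of X and per-level record lists, precomputed for the kernels
    col_indptr: np.ndarray = field(repr=False, default=None)
    col_rows: np.ndarray = field(repr=False, default=None)
    col_vals: np.ndarray = field(repr=False, default=None)
    col_sq: np.ndarray = field(repr=False, default=None)
    an_indptr: np.ndarray = field(repr=False, default=None)
    an_recs: np.ndarray = field(repr=False, default=None)
    pe_indptr: np.ndarray = field(repr=False, default=None)
    pe_recs: np.ndarray = field(repr=False, default=None)
    miss_patterns: list = field(repr=False, default_factory=list)

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]


def _level_record_csr(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(levels, kind="stable")
    counts = np.bincount(levels, minlength=n_levels)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order.astype(np.int64)


def build_design_matrices(
    records: pd.DataFrame, ped: PedigreeTable, spec: ModelSpec
) -> MixedModelEquations:
    """Assemble X, Z/W bookkeeping, response matrix and ``A^{-1}``.

    ``X`` uses reference-cell coding: an intercept plus, per factor, one
    indicator for every *observed* level beyond the first observed level.
    Records with all selected traits missing are dropped; with
    ``missing_handling='complete_cases'`` any record with a missing trait
    is dropped.
    """
    df = records.reset_index(drop=True)
    for trait in spec.traits:
        if trait not in df.columns:
            raise DesignError(f"trait column {trait!r} not in records")
    y_all = df[list(spec.traits)].to_numpy(dtype=float)
    if spec.missing_handling == "complete_cases":
        keep = ~np.isnan(y_all).any(axis=1)
    else:
        keep = ~np.isnan(y_all).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d records with no usable trait scores", dropped)
    df = df.loc[keep].reset_index(drop=True)
    y = y_all[keep]
    if df.empty:
        raise DesignError("no records left after missingness filtering")
    for j, trait in enumerate(spec.traits):
        if np.isnan(y[:, j]).all():
            raise DesignError(f"trait {trait!r} has no observed scores")

    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for factor in spec.fixed_factors:
        if factor not in df.columns:
            raise DesignError(f"factor column {factor!r} not in records")
        lev = df[factor].to_numpy()
        observed = np.unique(lev)
        declared = FACTOR_LEVELS[factor]
        bad = [v for v in observed if not (1 <= int(v) <= declared)]
        if bad:
            raise DesignError(f"unseen level(s) {bad} for factor {factor!r}")
        for v in observed[1:]:
            cols.append((lev == v).astype(float))
            names.append(f"{factor}_{int(v)}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("fixed-effect design X is rank deficient")

    rec_animal = ped.index_of(df["animal"].to_numpy())
    F = compute_inbreeding(ped)
    A_inv = build_A_inverse(ped, F)

    if spec.pe_covariance == "pedigree":
        rec_pe = rec_animal.copy()
        n_pe = ped.n
        pe_prior = A_inv
    else:
        uniq, rec_pe = np.unique(rec_animal, return_inverse=True)
        n_pe = len(uniq)
        pe_prior = sparse.identity(n_pe, format="csr")

    Xcsc = sparse.csc_matrix(X)
    an_indptr, an_recs = _level_record_csr(rec_animal, ped.n)
    pe_indptr, pe_recs = _level_record_csr(rec_pe, n_pe)

    # group records by missingness pattern for vectorized augmentation
    miss = np.isnan(y)
    patterns: list[tuple[np.ndarray, np.ndarray]] = []
    if miss.any():
        keys = [tuple(row) for row in miss]
        seen: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            if any(k):
                seen.setdefault(k, []).append(i)
        patterns = [
            (np.array(k, dtype=bool), np.array(v, dtype=np.int64))
            for k, v in seen.items()
        ]

    return MixedModelEquations(
        X=X,
        x_names=names,
        y=y,
        rec_animal=rec_animal,
        rec_pe=rec_pe.astype(np.int64),
        n_pe=n_pe,
        A_inv=A_inv,
        pe_prior=pe_prior,
        ped=ped,
        spec=spec,
        col_indptr=Xcsc.indptr.astype(np.int64),
        col_rows=Xcsc.indices.astype(np.int64),
        col_vals=Xcsc.data.astype(np.float64),
        col_sq=np.asarray((X**2).sum(axis=0)),
        an_indptr=an_indptr,
        an_recs=an_recs,
        pe_indptr=pe_indptr,
        pe_recs=pe_recs,
        miss_patterns=patterns,
    )


@dataclass
class GibbsState:
    """Current values of every block in the sampler."""

    b: np.ndarray
    u: np.ndarray
    pe: np.ndarray
    y: np.ndarray  # augmented (no NaN)
    e: np.ndarray  # y - Xb - Zu - Wpe
    sigma_u: np.ndarray
    sigma_pe: np.ndarray
    sigma_e: np.ndarray


def initialize_state(mme: MixedModelEquations) -> GibbsState:
    n, t = mme.y.shape
    y = mme.y.copy()
    for j in range(t):
        col = y[:, j]
        col[np.isnan(col)] = np.nanmean(mme.y[:, j])
    var0 = np.nanvar(mme.y, axis=0)
    var0 = np.maximum(var0, 1e-4)
    third = np.diag(var0 / 3.0)
    b = np.zeros((mme.X.shape[1], t))
    b[0] = y.mean(axis=0)
    u = np.zeros((mme.ped.n, t))
    pe = np.zeros((mme.n_pe, t))
    e = y - mme.X @ b
    return GibbsState(
        b=b,
        u=u,
        pe=pe,
        y=y,
        e=e,
        sigma_u=third.copy(),
        sigma_pe=third.copy(),
        sigma_e=third.copy(),
    )


def impute_missing_traits(
    state: GibbsState, mme: MixedModelEquations, rng: np.random.Generator
) -> None:
    """Draw missing trait scores from their conditional normal.

    For a record with observed set O and missing set M, the missing
    residual is ``N(Σe[M,O] Σe[O,O]^{-1} e_O, Schur complement)``; the
    linear predictor is recovered as ``y - e`` and observed entries are
    never touched.
    """
    for mask, rows in mme.miss_patterns:
        O = np.where(~mask)[0]
        M = np.where(mask)[0]
        Se = state.sigma_e
        if len(O):
            C = np.linalg.solve(Se[np.ix_(O, O)], Se[np.ix_(O, M)]).T
            schur = Se[np.ix_(M, M)] - C @ Se[np.ix_(O, M)]
            cond_mean = state.e[np.ix_(rows, O)] @ C.T
        else:  # pragma: no cover - all-missing records are dropped at build
            schur = Se[np.ix_(M, M)]
            cond_mean = np.zeros((len(rows), len(M)))
        Lc = np.linalg.cholesky(schur + VARIANCE_FLOOR * np.eye(len(M)))
        z = rng.standard_normal((len(rows), len(M)))
        new_e = cond_mean + z @ Lc.T
        mu = state.y[np.ix_(rows, M)] - state.e[np.ix_(rows, M)]
        state.y[np.ix_(rows, M)] = mu + new_e
        state.e[np.ix_(rows, M)] = new_e


def sample_location_effects(
    state: GibbsState, mme: MixedModelEquations, rng: np.random.Generator
) -> None:
    """One Gibbs pass over b, u and pe (single-site, all traits jointly)."""
    t = mme.n_traits
    try:
        Le = np.linalg.cholesky(state.sigma_e)
    except np.linalg.LinAlgError as exc:
        raise DesignError("residual covariance is singular") from exc
    Se_inv = np.linalg.inv(state.sigma_e)
    Su_inv = np.linalg.inv(state.sigma_u)

    zb = rng.standard_normal((mme.X.shape[1], t))
    update_fixed(
        state.e, mme.col_indptr, mme.col_rows, mme.col_vals, mme.col_sq, state.b, Le, zb
    )
    zu = rng.standard_normal((mme.ped.n, t))
    update_random(
        state.e,
        state.u,
        mme.an_indptr,
        mme.an_recs,
        mme.A_inv.indptr.astype(np.int64),
        mme.A_inv.indices.astype(np.int64),
        mme.A_inv.data,
        Se_inv,
        Su_inv,
        zu,
    )
    if mme.spec.include_pe:
        Spe_inv = np.linalg.inv(state.sigma_pe)
        zpe = rng.standard_normal((mme.n_pe, t))
        update_random(
            state.e,
            state.pe,
            mme.pe_indptr,
            mme.pe_recs,
            mme.pe_prior.indptr.astype(np.int64),
            mme.pe_prior.indices.astype(np.int64),
            mme.pe_prior.data,
            Se_inv,
            Spe_inv,
            zpe,
        )


def _draw_inverse_wishart(
    scale: np.ndarray, df: float, rng: np.random.Generator
) -> np.ndarray:
    t = scale.shape[0]
    if df <= t - 1:
        raise DesignError(
            f"not enough levels for {t} traits (inverse-Wishart df {df} <= {t - 1})"
        )
    scale = 0.5 * (scale + scale.T)
    if t == 1:
        draw = np.array([[scale[0, 0] / rng.chisquare(df)]])
    else:
        try:
            draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
        except np.linalg.LinAlgError:
            scale = scale + VARIANCE_FLOOR * np.eye(t)
            draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
        draw = np.atleast_2d(draw)
    # positivity floor to avoid absorbing states when a component collapses
    for k in range(t):
        if draw[k, k] < VARIANCE_FLOOR:
            draw[k, k] = VARIANCE_FLOOR
    return draw


def sample_variance_components(
    state: GibbsState, mme: MixedModelEquations, rng: np.random.Generator
) -> None:
    """Inverse-Wishart draws for Σu, Σpe, Σe under flat priors.

    Scales are ``u' A^{-1} u``, ``pe' P^{-1} pe`` and ``e' e`` with
    degrees of freedom (levels − t − 1), the flat-prior convention
    (prior df = −(t+1), zero prior scale).
    """
    t = mme.n_traits
    su_scale = state.u.T @ (mme.A_inv @ state.u) + VARIANCE_FLOOR * np.eye(t)
    state.sigma_u = _draw_inverse_wishart(su_scale, mme.ped.n - (t + 1), rng)
    if mme.spec.include_pe:
        pe_scale = state.pe.T @ (mme.pe_prior @ state.pe) + VARIANCE_FLOOR * np.eye(t)
        state.sigma_pe = _draw_inverse_wishart(pe_scale, mme.n_pe - (t + 1), rng)
    e_scale = state.e.T @ state.e + VARIANCE_FLOOR * np.eye(t)
    state.sigma_e = _draw_inverse_wishart(e_scale, mme.n_records - (t + 1), rng)


@dataclass
class PosteriorSamples:
    """Saved draws of the (co)variance components (and optionally b)."""

    traits: tuple[str, ...]
    sigma_u: np.ndarray  # (S, t, t)
    sigma_pe: np.ndarray
    sigma_e: np.ndarray
    b: np.ndarray | None
    x_names: list[str] | None
    spec: ModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def n_saved(self) -> int:
        return self.sigma_u.shape[0]

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in this run {self.traits}") from None


def run_gibbs(
    records: pd.DataFrame,
    ped: PedigreeTable,
    spec: ModelSpec,
    mme: MixedModelEquations | None = None,
) -> PosteriorSamples:
    """Run the full Gibbs sampler and collect post-burn-in draws.

    Per iteration: impute missing traits, update all location effects,
    then draw the three covariance matrices.  Fully deterministic given
    ``spec.seed``.
    """
    if mme is None:
        mme = build_design_matrices(records, ped, spec)
    t = spec.n_traits
    rng = np.random.default_rng(spec.seed)
    state = initialize_state(mme)

    S = spec.n_saved
    sigma_u = np.empty((S, t, t))
    sigma_pe = np.empty((S, t, t))
    sigma_e = np.empty((S, t, t))
    b_draws = np.empty((S, mme.X.shape[1], t)) if spec.store_location else None

    log_every = max(spec.n_iterations // 10, 1)
    saved = 0
    for it in range(1, spec.n_iterations + 1):
        if spec.missing_handling == "augment" and mme.miss_patterns:
            impute_missing_traits(state, mme, rng)
        sample_location_effects(state, mme, rng)
        sample_variance_components(state, mme, rng)
        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and saved < S:
            sigma_u[saved] = state.sigma_u
            sigma_pe[saved] = state.sigma_pe
            sigma_e[saved] = state.sigma_e
            if b_draws is not None:
                b_draws[saved] = state.b
            saved += 1
        if it % log_every == 0:
            h2 = state.sigma_u[0, 0] / (
                state.sigma_u[0, 0] + state.sigma_pe[0, 0] + state.sigma_e[0, 0]
            )
            log.info("iteration %d/%d  current h2[%s]=%.3f", it, spec.n_iterations,
                     spec.traits[0], h2)

    return PosteriorSamples(
        traits=spec.traits,
        sigma_u=sigma_u[:saved],
        sigma_pe=sigma_pe[:saved],
        sigma_e=sigma_e[:saved],
        b=b_draws[:saved] if b_draws is not None else None,
        x_names=mme.x_names,
        spec=spec,
        meta={
            "seed": spec.seed,
            "n_records": mme.n_records,
            "n_animals": mme.ped.n,
            "n_pe_levels": mme.n_pe,
        },
    )
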