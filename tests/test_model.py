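import numpy as np
import pandas as pd
import pytest

from pedgibbs.model import (
    DesignError,
    ModelSpec,
    build_design_matrices,
    impute_missing_traits,
    initialize_state,
    run_gibbs,
    sample_location_effects,
    sample_variance_components,
)
from pedgibbs.pedigree import validate_and_sort
from pedgibbs.posterior import mc_standard_error
from pedgibbs.simulate import SimulationConfig, simulate_dataset

from conftest import toy_records


def _founders(n, prefix="A"):
    return validate_and_sort(
        pd.DataFrame({"animal": [f"{prefix}{i:03d}" for i in range(n)], "sire": "", "dam": ""})
    )


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(DesignError):
            ModelSpec(traits=())
        with pytest.raises(DesignError):
            ModelSpec(traits=("t",), burn_in=10, n_iterations=10)
        with pytest.raises(DesignError):
            ModelSpec(traits=("t",), thin=0)
        with pytest.raises(DesignError):
            ModelSpec(traits=("t",), fixed_factors=("nope",))

    def test_saved_count(self):
        spec = ModelSpec(traits=("t",), n_iterations=1000, burn_in=300, thin=7)
        assert spec.n_saved == 100


class TestBuildDesign:
    def test_single_level_factors_collapse_to_intercept(self):
        ped = _founders(2)
        rec = toy_records(2, {"t": [1.0, 2.0]}, animals=["A000", "A001"])
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t",)))
        assert mme.X.shape == (2, 1)
        assert mme.x_names == ["intercept"]

    def test_study_shaped_has_ten_columns(self):
        ds = simulate_dataset(SimulationConfig(seed=1))
        mme = build_design_matrices(ds.records, ds.pedigree, ModelSpec(traits=("trait1",)))
        # 1 + (2-1)+(3-1)+(4-1)+(2-1)+(3-1)
        assert mme.X.shape[1] == 10

    def test_pe_column_counts_records(self):
        ped = _founders(3)
        rec = toy_records(
            5, {"t": [1.0] * 5}, animals=["A000", "A000", "A000", "A001", "A002"]
        )
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t",)))
        counts = np.diff(mme.pe_indptr)
        assert sorted(counts.tolist()) == [1, 1, 3]

    def test_unseen_level_rejected(self):
        ped = _founders(3)
        rec = toy_records(3, {"t": [1.0, 2.0, 1.5]}, animals=["A000", "A001", "A002"],
                          appraiser=np.array([1, 2, 9]))
        with pytest.raises(DesignError, match="appraiser"):
            build_design_matrices(rec, ped, ModelSpec(traits=("t",)))

    def test_empty_trait_rejected(self):
        ped = _founders(2)
        rec = toy_records(2, {"t": [1.0, 2.0], "t2": [np.nan, np.nan]},
                          animals=["A000", "A001"])
        with pytest.raises(DesignError, match="no records left|no observed"):
            build_design_matrices(rec, ped, ModelSpec(traits=("t2",)))

    def test_rank_deficient_rejected(self):
        ped = _founders(4)
        rec = toy_records(
            4, {"t": [1.0, 2.0, 3.0, 4.0]},
            animals=[f"A{i:03d}" for i in range(4)],
            gender=np.array([1, 1, 2, 2]), age_group=np.array([1, 1, 2, 2]),
        )
        with pytest.raises(DesignError, match="rank"):
            build_design_matrices(rec, ped, ModelSpec(traits=("t",)))

    def test_complete_cases_drops_partial_records(self):
        ped = _founders(4)
        rec = toy_records(
            4, {"t1": [1.0, np.nan, 2.0, 3.0], "t2": [1.0, 2.0, np.nan, 4.0]},
            animals=[f"A{i:03d}" for i in range(4)],
        )
        spec = ModelSpec(traits=("t1", "t2"), missing_handling="complete_cases")
        assert build_design_matrices(rec, ped, spec).n_records == 2
        spec = ModelSpec(traits=("t1", "t2"), missing_handling="augment")
        assert build_design_matrices(rec, ped, spec).n_records == 4


class TestLocationConditionals:
    def test_b_collapses_to_ols_when_random_variances_vanish(self):
        rng = np.random.default_rng(0)
        n = 50
        ped = _founders(n)
        gender = rng.integers(1, 3, n)
        appraiser = rng.integers(1, 4, n)
        y = 2.0 + 0.8 * (gender == 2) - 0.5 * (appraiser == 3) + rng.normal(0, 1, n)
        rec = toy_records(n, {"t": y}, animals=[f"A{i:03d}" for i in range(n)],
                          gender=gender, appraiser=appraiser)
        spec = ModelSpec(traits=("t",), fixed_factors=("gender", "appraiser"))
        mme = build_design_matrices(rec, ped, spec)
        state = initialize_state(mme)
        state.sigma_u = np.array([[1e-12]])
        state.sigma_pe = np.array([[1e-12]])
        state.sigma_e = np.array([[1.0]])
        state.e = state.y - mme.X @ state.b
        draws = np.empty((4000, mme.X.shape[1]))
        g = np.random.default_rng(1)
        for it in range(4000):
            sample_location_effects(state, mme, g)
            draws[it] = state.b[:, 0]
        ols, *_ = np.linalg.lstsq(mme.X, y, rcond=None)
        for j in range(mme.X.shape[1]):
            mcse = mc_standard_error(draws[500:, j])
            assert abs(draws[500:, j].mean() - ols[j]) < 3 * mcse + 1e-9

    def test_constant_data_centres_random_effects_at_zero(self):
        ped = _founders(30)
        rec = toy_records(30, {"t": np.full(30, 5.0)},
                          animals=[f"A{i:03d}" for i in range(30)])
        spec = ModelSpec(traits=("t",), n_iterations=500, burn_in=100, seed=0)
        s = run_gibbs(rec, ped, spec)
        assert s.sigma_u.mean() < 1e-4
        assert s.sigma_e.mean() < 1e-4


class TestVarianceConditionals:
    def test_univariate_inverse_chi_square(self):
        n = 200
        ped = _founders(n)
        rng = np.random.default_rng(2)
        e = rng.normal(0, 3, n)
        rec = toy_records(n, {"t": e}, animals=[f"A{i:03d}" for i in range(n)])
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t",)))
        state = initialize_state(mme)
        state.e = e.reshape(-1, 1).copy()
        state.u[:] = 0.0
        state.pe[:] = 0.0
        S = float(e @ e)
        g = np.random.default_rng(3)
        draws = np.empty(20_000)
        for it in range(20_000):
            sample_variance_components(state, mme, g)
            draws[it] = state.sigma_e[0, 0]
        assert draws.mean() == pytest.approx(S / (n - 4), rel=0.02)

    def test_bivariate_wishart_moment(self):
        q = 500
        ped = _founders(q)
        Su = np.array([[1.0, 0.7], [0.7, 1.0]])
        rng = np.random.default_rng(4)
        u = rng.multivariate_normal([0, 0], Su, size=q)
        rec = toy_records(q, {"t1": rng.normal(size=q), "t2": rng.normal(size=q)},
                          animals=[f"A{i:03d}" for i in range(q)])
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t1", "t2")))
        state = initialize_state(mme)
        state.u = u.copy()
        scale = u.T @ u
        g = np.random.default_rng(5)
        draws = np.zeros((3000, 2, 2))
        for it in range(3000):
            state.u = u.copy()
            sample_variance_components(state, mme, g)
            draws[it] = state.sigma_u
        mean = draws.mean(axis=0)
        np.testing.assert_allclose(mean, scale / q, rtol=0.05)

    def test_too_few_levels_rejected(self):
        ped = _founders(2)
        rec = toy_records(2, {"t1": [1.0, 2.0], "t2": [2.0, 1.0],
                              "t3": [0.5, 0.2]}, animals=["A000", "A001"])
        spec = ModelSpec(traits=("t1", "t2", "t3"))
        mme = build_design_matrices(rec, ped, spec)
        state = initialize_state(mme)
        with pytest.raises(DesignError, match="df"):
            # 2 records cannot support a 3-trait residual covariance
            sample_variance_components(state, mme, np.random.default_rng(0))


class TestImputation:
    def _bivariate_mme(self, sigma_e, n=400, seed=6):
        ped = _founders(n)
        rng = np.random.default_rng(seed)
        t1 = rng.normal(size=n)
        t2 = np.where(np.arange(n) % 2 == 0, np.nan, rng.normal(size=n))
        rec = toy_records(n, {"t1": t1, "t2": t2}, animals=[f"A{i:03d}" for i in range(n)])
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t1", "t2")))
        state = initialize_state(mme)
        state.b[:] = 0.0
        state.u[:] = 0.0
        state.pe[:] = 0.0
        state.sigma_e = np.asarray(sigma_e, dtype=float)
        return mme, state, t1

    def test_diagonal_sigma_imputes_linear_predictor(self):
        mme, state, _ = self._bivariate_mme(np.diag([1.0, 1.0]))
        miss = np.isnan(mme.y[:, 1])
        # force a known linear predictor of 3.0 on the missing cells
        state.y[miss, 1] = 7.0
        state.e[miss, 1] = 4.0
        g = np.random.default_rng(7)
        acc = np.zeros(miss.sum())
        n_draws = 2000
        for _ in range(n_draws):
            impute_missing_traits(state, mme, g)
            acc += state.y[miss, 1]
        np.testing.assert_allclose(acc / n_draws, 3.0, atol=0.15)

    def test_correlated_imputation_tracks_observed_residual(self):
        mme, state, t1 = self._bivariate_mme([[1.0, 0.9], [0.9, 1.0]])
        miss = np.isnan(mme.y[:, 1])
        state.e[:, 0] = state.y[:, 0]  # predictor 0 -> residual = observed score
        g = np.random.default_rng(8)
        xs, ys = [], []
        for _ in range(200):
            impute_missing_traits(state, mme, g)
            xs.append(state.e[miss, 0].copy())
            ys.append(state.e[miss, 1].copy())
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert r == pytest.approx(0.9, abs=0.03)

    def test_observed_entries_untouched(self):
        mme, state, t1 = self._bivariate_mme(np.eye(2))
        before = state.y[:, 0].copy()
        impute_missing_traits(state, mme, np.random.default_rng(9))
        np.testing.assert_array_equal(state.y[:, 0], before)

    def test_no_missing_is_noop(self):
        ped = _founders(5)
        rec = toy_records(5, {"t": np.arange(5.0)}, animals=[f"A{i:03d}" for i in range(5)])
        mme = build_design_matrices(rec, ped, ModelSpec(traits=("t",)))
        state = initialize_state(mme)
        before = state.y.copy()
        impute_missing_traits(state, mme, np.random.default_rng(0))
        np.testing.assert_array_equal(state.y, before)


class TestRunGibbs:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=3, n_founders=40, n_per_generation=40,
                               n_generations=2, n_evaluated=50)
        ds = simulate_dataset(cfg)
        spec = ModelSpec(traits=("trait1",), n_iterations=400, burn_in=100, seed=11)
        a = run_gibbs(ds.records, ds.pedigree, spec)
        b = run_gibbs(ds.records, ds.pedigree, spec)
        np.testing.assert_array_equal(a.sigma_u, b.sigma_u)
        np.testing.assert_array_equal(a.sigma_e, b.sigma_e)

    def test_saved_draw_count_exact(self):
        cfg = SimulationConfig(seed=3, n_founders=30, n_per_generation=30,
                               n_generations=1, n_evaluated=30)
        ds = simulate_dataset(cfg)
        spec = ModelSpec(traits=("trait1",), n_iterations=100 + 7 * 13, burn_in=100,
                         thin=7, seed=1)
        s = run_gibbs(ds.records, ds.pedigree, spec)
        assert s.n_saved == 13

    def test_relabelling_invariance(self):
        # order-preserving rename of every animal: identical variance draws
        cfg = SimulationConfig(seed=5, n_founders=40, n_per_generation=40,
                               n_generations=2, n_evaluated=40)
        ds = simulate_dataset(cfg)
        spec = ModelSpec(traits=("trait1",), n_iterations=300, burn_in=50, seed=2)
        a = run_gibbs(ds.records, ds.pedigree, spec)

        rename = {aid: f"Z{aid}" for aid in ds.pedigree.ids}
        ped_frame = ds.pedigree.to_frame()
        for col in ("animal", "sire", "dam"):
            ped_frame[col] = ped_frame[col].map(lambda x: rename.get(x, ""))
        ped2 = validate_and_sort(ped_frame)
        rec2 = ds.records.copy()
        rec2["animal"] = rec2["animal"].map(rename)
        b = run_gibbs(rec2, ped2, spec)
        np.testing.assert_array_equal(a.sigma_u, b.sigma_u)
        np.testing.assert_array_equal(a.sigma_pe, b.sigma_pe)
        np.testing.assert_array_equal(a.sigma_e, b.sigma_e)

    def test_pedigree_pe_mode_runs(self):
        cfg = SimulationConfig(seed=6, n_founders=30, n_per_generation=30,
                               n_generations=1, n_evaluated=30)
        ds = simulate_dataset(cfg)
        spec = ModelSpec(traits=("trait1",), n_iterations=300, burn_in=100, seed=3,
                         pe_covariance="pedigree")
        s = run_gibbs(ds.records, ds.pedigree, spec)
        assert s.meta["n_pe_levels"] == ds.pedigree.n
        assert np.isfinite(s.sigma_pe).all()

    def test_augmentation_handles_missingness(self):
        cfg = SimulationConfig(
            seed=7, traits=("t1", "t2"), sigma_u=np.eye(2) * 0.25,
            sigma_pe=np.eye(2) * 0.2, sigma_e=np.eye(2) * 0.55,
            missingness={"t1": 0.7, "t2": 0.8},
            n_founders=40, n_per_generation=40, n_generations=2, n_evaluated=50,
        )
        ds = simulate_dataset(cfg)
        spec = ModelSpec(traits=("t1", "t2"), n_iterations=400, burn_in=100, seed=4)
        s = run_gibbs(ds.records, ds.pedigree, spec)
        assert np.isfinite(s.sigma_u).all()
        # covariance draws stay symmetric PD
        eigs = np.linalg.eigvalsh(s.sigma_e)
        assert eigs.min() > 0
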