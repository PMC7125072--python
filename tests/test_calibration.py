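"""Tests for the objective, the MCMC sampler, and fit diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from acetokin.calibration import (
    CalibrationError,
    FitConfig,
    MCMCCalibrator,
    TimeSeriesDataset,
    convergence_diagnostic,
    mcmc_fit,
    objective,
    parameter_correlation,
    r_squared,
    split_rhat,
)
from acetokin.kinetics import CultureState, ModelSpec
from acetokin.literature import FIRST_ORDER_BEST_FIT, T1_BEST_FIT
from acetokin.simulation import integrate_fast
from acetokin.synthetic import generate_dataset

from conftest import INITIAL, make_scenario, noiseless_dataset

FO_SPEC = ModelSpec("first_order", FIRST_ORDER_BEST_FIT)


def _model_H(times):
    return integrate_fast(FO_SPEC, INITIAL.as_array(), times)[:, 0]


class TestObjective:
    def test_perfect_fit_is_zero(self):
        data, _, sc = noiseless_dataset("first_order")
        assert objective(FO_SPEC, sc.initial, data) == pytest.approx(0.0, abs=1e-9)

    def test_single_unit_residual(self):
        times = np.array([0.0, 10.0, 20.0])
        obs = _model_H(times)
        obs[2] -= 2.0  # one observation off by exactly its SD
        data = TimeSeriesDataset(
            times=times, observed={"H": obs}, sd={"H": np.full(3, 2.0)}
        )
        assert objective(FO_SPEC, INITIAL, data) == pytest.approx(1.0, abs=1e-6)

    def test_residuals_add_across_variables(self):
        times = np.array([0.0, 10.0, 20.0])
        ys = integrate_fast(FO_SPEC, INITIAL.as_array(), times)
        obs_h, obs_p = ys[:, 0].copy(), ys[:, 1].copy()
        obs_h[1] += 3.0
        obs_p[2] -= 0.5
        data = TimeSeriesDataset(
            times=times,
            observed={"H": obs_h, "P": obs_p},
            sd={"H": np.full(3, 3.0), "P": np.full(3, 0.5)},
        )
        assert objective(FO_SPEC, INITIAL, data) == pytest.approx(2.0, abs=1e-6)

    def test_missing_observations_contribute_nothing(self):
        times = np.array([0.0, 10.0, 20.0, 30.0])
        obs = _model_H(times)
        obs_missing = obs.copy()
        obs_missing[1] = np.nan
        full = TimeSeriesDataset(times=times, observed={"H": obs})
        sparse = TimeSeriesDataset(times=times, observed={"H": obs_missing})
        assert objective(FO_SPEC, INITIAL, sparse) <= objective(
            FO_SPEC, INITIAL, full
        ) + 1e-12

    def test_row_permutation_invariance(self):
        data, _, sc = noiseless_dataset("t1", sd_fraction=0.05)
        tidy = data.to_tidy()
        shuffled = tidy.sample(frac=1.0, random_state=3)
        spec = ModelSpec("t1", T1_BEST_FIT)
        assert objective(spec, sc.initial, TimeSeriesDataset.from_tidy(shuffled)) == (
            objective(spec, sc.initial, TimeSeriesDataset.from_tidy(tidy))
        )

    def test_zero_sd_falls_back_to_mean_normalisation(self):
        times = np.array([0.0, 10.0, 20.0])
        obs = _model_H(times) + 1.0
        plain = TimeSeriesDataset(times=times, observed={"H": obs})
        zero_sd = TimeSeriesDataset(
            times=times, observed={"H": obs}, sd={"H": np.zeros(3)}
        )
        assert objective(FO_SPEC, INITIAL, zero_sd) == pytest.approx(
            objective(FO_SPEC, INITIAL, plain)
        )

    def test_integration_failure_gives_infinite_objective(self, monkeypatch):
        from acetokin import calibration as cal
        from acetokin.simulation import IntegrationError

        def boom(*a, **k):
            raise IntegrationError("step-size collapse", 1.0)

        monkeypatch.setattr(cal, "integrate_fast", boom)
        data, _, sc = noiseless_dataset("first_order")
        assert objective(FO_SPEC, sc.initial, data) == np.inf


class TestDatasetValidation:
    def test_requires_three_observations_somewhere(self):
        with pytest.raises(ValueError, match=">= 3"):
            TimeSeriesDataset(
                times=np.array([0.0, 1.0, 2.0]),
                observed={"H": np.array([1.0, np.nan, np.nan])},
            )

    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeSeriesDataset(
                times=np.array([0.0, 2.0, 1.0]),
                observed={"H": np.array([1.0, 2.0, 3.0])},
            )

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            TimeSeriesDataset(
                times=np.array([0.0, 1.0, 2.0]),
                observed={"Z": np.array([1.0, 2.0, 3.0])},
            )

    def test_tidy_round_trip(self):
        sc = make_scenario("t1", noise_cv=0.1, n_replicates=3, seed=9)
        data, _ = generate_dataset(sc)
        back = TimeSeriesDataset.from_tidy(data.to_tidy())
        assert np.array_equal(back.times, data.times)
        for var in data.observed:
            assert np.allclose(back.observed[var], data.observed[var])
            assert np.allclose(back.sd[var], data.sd[var])


class TestRSquared:
    def _data(self):
        times = np.array([0.0, 1.0, 2.0, 3.0])
        return TimeSeriesDataset(
            times=times, observed={"H": np.array([4.0, 3.0, 2.0, 1.0])}
        )

    def test_exact_model_scores_one(self):
        data = self._data()
        assert r_squared(data.observed["H"], data, "H") == pytest.approx(1.0)

    def test_mean_model_scores_zero(self):
        data = self._data()
        mean = np.full(4, data.observed["H"].mean())
        assert r_squared(mean, data, "H") == pytest.approx(0.0)

    def test_constant_offset_closed_form(self):
        data = self._data()
        c = 0.7
        obs = data.observed["H"]
        expected = 1.0 - 4 * c**2 / float(np.sum((obs - obs.mean()) ** 2))
        assert r_squared(obs + c, data, "H") == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        data = TimeSeriesDataset(
            times=np.array([0.0, 1.0, 2.0]),
            observed={"H": np.array([2.0, 2.0, 2.0])},
        )
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.array([2.0, 2.0, 2.0]), data, "H")

    def test_too_few_observations_rejected(self):
        data = TimeSeriesDataset(
            times=np.array([0.0, 1.0, 2.0]),
            observed={
                "H": np.array([1.0, 2.0, 3.0]),
                "P": np.array([1.0, np.nan, np.nan]),
            },
        )
        with pytest.raises(ValueError, match=">= 2"):
            r_squared(np.array([1.0, 1.0, 1.0]), data, "P")


class TestCorrelation:
    def test_linear_dependence(self):
        x = np.linspace(1.0, 2.0, 50)
        corr = parameter_correlation({"a": x, "b": 2 * x})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(12)
        corr = parameter_correlation(
            {"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)}
        )
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_constant_chain_gives_nan(self):
        corr = parameter_correlation(
            {"a": np.ones(100), "b": np.linspace(0, 1, 100)}
        )
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0


class TestConvergenceDiagnostic:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        assert split_rhat(np.vstack([chain, chain])) == 1.0

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = {
            "a": np.vstack(
                [rng.normal(0, 0.1, 500), rng.normal(100, 0.1, 500)]
            )
        }
        rhat, flags = convergence_diagnostic(chains)
        assert rhat["a"] > 10.0
        assert flags["a"] is False

    def test_well_mixed_gaussian_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(4, 10_000))
        ours = split_rhat(arr)
        theirs = float(az.rhat(az.convert_to_dataset(arr), method="split").x)
        assert ours < 1.01
        assert abs(ours - max(theirs, 1.0)) < 5e-3

    def test_short_chains_rejected(self):
        with pytest.raises(CalibrationError, match="4 samples"):
            split_rhat(np.array([1.0, 2.0, 3.0]))


class TestSampler:
    def test_seed_determinism(self):
        sc = make_scenario("first_order", noise_cv=0.05, n_replicates=1, seed=2)
        data, _ = generate_dataset(sc)
        cfg = FitConfig(n_iterations=800, n_chains=2, seed=17)
        a = mcmc_fit(FO_SPEC, sc.initial, data, cfg)
        b = mcmc_fit(FO_SPEC, sc.initial, data, cfg)
        assert a.best_fit == b.best_fit
        for name in a.param_names:
            assert np.array_equal(a.chains[name], b.chains[name])

    def test_single_iteration_returns_initial_sample(self):
        data, _, sc = noiseless_dataset("first_order")
        cfg = FitConfig(n_iterations=1, n_chains=1, seed=0)
        res = mcmc_fit(FO_SPEC, sc.initial, data, cfg)
        for name, value in FIRST_ORDER_BEST_FIT.to_dict().items():
            assert res.chains[name].shape == (1, 1)
            assert res.chains[name][0, 0] == pytest.approx(value)
            assert res.best_fit[name] == pytest.approx(value)

    def test_chain_length_follows_burn_in(self):
        data, _, sc = noiseless_dataset("first_order")
        cfg = FitConfig(n_iterations=1000, n_chains=2, burn_in_fraction=0.2, seed=0)
        res = mcmc_fit(FO_SPEC, sc.initial, data, cfg)
        assert res.chains["eta"].shape == (2, 800)

    def test_degenerate_proposal_raises(self):
        sc = make_scenario("first_order", noise_cv=0.05, n_replicates=1, seed=1)
        data, _ = generate_dataset(sc)
        cfg = FitConfig(
            n_iterations=200,
            n_chains=1,
            proposal_scale=200.0,
            prior_log10_halfwidth=0.05,
            adapt=False,
            seed=0,
        )
        with pytest.raises(CalibrationError, match="rejected"):
            mcmc_fit(FO_SPEC, sc.initial, data, cfg)

    def test_prior_pinning_bad_start_raises(self):
        # prior bounds exclude every decent fit and the proposal scale
        # cannot reach one: flagged as a degenerate configuration
        sc = make_scenario("first_order", noise_cv=0.05, n_replicates=1, seed=1)
        data, _ = generate_dataset(sc)
        cfg = FitConfig(
            n_iterations=200,
            n_chains=1,
            proposal_scale=50.0,
            prior_log10_halfwidth=0.01,  # essentially pins the bad start
            adapt=False,
            seed=0,
        )
        spec = ModelSpec(
            "first_order",
            type(FIRST_ORDER_BEST_FIT)(eta=0.5, Y=0.0037, k_d=0.087),
        )
        with pytest.raises(CalibrationError, match="rejected"):
            mcmc_fit(spec, sc.initial, data, cfg)

    def test_perfect_fit_chain_with_no_accepts_is_not_degenerate(self):
        # on noise-free data the posterior collapses at the optimum; a chain
        # that rejects every move from there is converged, not broken
        data, _, sc = noiseless_dataset("first_order")
        cfg = FitConfig(
            n_iterations=200, n_chains=1, proposal_scale=2.0, adapt=False, seed=0
        )
        res = mcmc_fit(FO_SPEC, sc.initial, data, cfg)
        assert res.objective_at_best < 1e-6

    def test_noiseless_first_order_recovery_within_5_percent(self):
        # generating values recovered from noise-free data with 5% error bars
        data, _, sc = noiseless_dataset("first_order", sd_fraction=0.05)
        gen = FIRST_ORDER_BEST_FIT.to_dict()
        cal = MCMCCalibrator(
            "first_order",
            initial_params={k: 2 * v for k, v in gen.items()},
            n_iterations=8000,
            n_chains=1,
            random_state=7,
            initial_state=sc.initial,
        ).fit(data)
        for name, value in gen.items():
            assert cal.best_fit_[name] == pytest.approx(value, rel=0.05)

    def test_t1_threshold_recovered(self):
        data, _, sc = noiseless_dataset("t1", sd_fraction=0.05)
        gen = T1_BEST_FIT.to_dict()
        cal = MCMCCalibrator(
            "t1",
            initial_params={k: 2 * v for k, v in gen.items()},
            n_iterations=8000,
            n_chains=1,
            random_state=3,
            initial_state=sc.initial,
        ).fit(data)
        # noise-free data: the posterior collapses to integrator precision,
        # so check point recovery (interval coverage is a noisy-data property)
        assert cal.best_fit_["H_t"] == pytest.approx(gen["H_t"], rel=0.05)
        assert cal.best_fit_["eta"] == pytest.approx(gen["eta"], rel=0.05)

    def test_nonlinearised_structures_need_explicit_optin(self):
        data, _, sc = noiseless_dataset("first_order")
        from acetokin.kinetics import T1NonlinearParams

        spec = ModelSpec(
            "t1_nonlinear",
            T1NonlinearParams(mu_max=0.24, K_H=300.0, Y=0.0014, k_d=0.014, H_t=86.2),
        )
        with pytest.raises(CalibrationError, match="allow_nonidentifiable"):
            mcmc_fit(spec, sc.initial, data, FitConfig(n_iterations=10, n_chains=1))


class TestEstimatorSurface:
    def test_fitted_attributes(self, quick_t1_fit):
        cal, data, truth, sc = quick_t1_fit
        assert set(cal.best_fit_) == {"eta", "Y", "k_d", "H_t"}
        assert cal.chains_["H_t"].shape == (2, 1600)
        assert set(cal.r_squared_) == {"H", "P", "X"}
        assert cal.objective_at_best_ >= 0.0
        assert all(lo < hi for lo, hi in cal.ci95_.values())
        assert cal.result_.summary().shape[0] == 4

    def test_predict_returns_trajectory_frame(self, quick_t1_fit):
        cal, data, *_ = quick_t1_fit
        out = cal.predict(np.linspace(0.0, 80.0, 5))
        assert list(out.columns) == ["time_h", "H_mM", "P_mM", "X_gL"]
        assert out.shape == (5, 4)
        assert out["H_mM"].iloc[0] == pytest.approx(cal.initial_state_.H)

    def test_score_is_mean_r_squared(self, quick_t1_fit):
        cal, data, *_ = quick_t1_fit
        assert cal.score(data) == pytest.approx(
            np.mean(list(cal.r_squared_.values()))
        )

    def test_sklearn_params_round_trip(self):
        cal = MCMCCalibrator("t2", n_iterations=123, random_state=9)
        params = cal.get_params()
        assert params["structure"] == "t2"
        cloned = clone(cal)
        assert cloned.get_params() == params
        cal.set_params(n_chains=7)
        assert cal.n_chains == 7

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            MCMCCalibrator().predict([0.0, 1.0])

    def test_fit_accepts_tidy_frame(self):
        sc = make_scenario("first_order", noise_cv=0.05, n_replicates=3, seed=6)
        data, _ = generate_dataset(sc)
        cal = MCMCCalibrator(
            "first_order", n_iterations=300, n_chains=1, random_state=0
        ).fit(data.to_tidy())
        assert hasattr(cal, "best_fit_")

    def test_initial_state_from_first_observations(self):
        sc = make_scenario("first_order", noise_cv=0.0, n_replicates=1)
        data, truth = generate_dataset(sc)
        cal = MCMCCalibrator(
            "first_order", n_iterations=200, n_chains=1, random_state=0
        ).fit(data)
        assert cal.initial_state_.H == pytest.approx(truth.H[0])
        assert cal.initial_state_.X == pytest.approx(truth.X[0])

    def test_missing_initial_variable_is_named(self):
        times = np.array([0.0, 10.0, 20.0])
        data = TimeSeriesDataset(times=times, observed={"H": _model_H(times)})
        with pytest.raises(ValueError, match="'P'"):
            MCMCCalibrator("first_order", n_iterations=10, n_chains=1).fit(data)
        # a default fills the gap
        cal = MCMCCalibrator(
            "first_order",
            n_iterations=50,
            n_chains=1,
            default_initial={"X": 0.01, "P": 0.0},
            random_state=0,
        ).fit(data)
        assert cal.initial_state_.X == 0.01

    def test_extension_fit_with_fixed_base(self):
        from acetokin.synthetic import dsmz_like_scenario

        sc = dsmz_like_scenario(base="t3", noise_cv=0.05, n_replicates=1, seed=5)
        data, _ = generate_dataset(sc)
        base = sc.spec.params.to_dict()
        cal = MCMCCalibrator(
            "t3",
            initial_params=base,
            extension_params=sc.spec.extension.to_dict(),
            fixed_params=base,  # only eta_E, Y_E, b_EP sampled
            n_iterations=300,
            n_chains=1,
            random_state=1,
            initial_state=sc.initial,
        ).fit(data)
        assert set(cal.best_fit_) == {"eta_E", "Y_E", "b_EP"}
        assert set(cal.result_.fixed) == set(base)
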