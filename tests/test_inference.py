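import warnings

import numpy as np
import pytest

from conftest import make_experiment
from threadkin.inference import (
    ConditionSeries,
    analyze_experiment,
    consistency_report,
    decompose_rates,
    equilibrium_route,
    fit_force_dependence,
    fit_force_law,
    fit_trace,
    refine_bell_global,
)
from threadkin.kinetics import (
    BellParams,
    bell_rate,
    observed_rates_preequilibrium,
)
from threadkin.trace_model import (
    RelaxationParams,
    Trace,
    amplitude_ratio,
    biexp_extension,
    equilibrium_extension,
)
from threadkin.synthetic import SimulationConfig, simulate_trace

KBT = 4.05


def synthetic_trace(params: RelaxationParams, duration=600.0, rate=1.0,
                    noise_sd=0.0, seed=0, force=20.0, conc=5.0) -> Trace:
    t = np.arange(int(duration * rate) + 1) / rate
    dx = biexp_extension(params, t)
    if noise_sd > 0:
        dx = dx + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return Trace(times=t, extensions=dx, force=force, concentration=conc)


class TestFitTrace:
    TRUTH = RelaxationParams(dx_eq=0.12, dx_f=0.03, dx_s=0.05, k_f=0.1, k_s=0.01)

    def test_noiseless_exact_recovery(self):
        fit = fit_trace(synthetic_trace(self.TRUTH))
        for name in ("dx_eq", "dx_f", "dx_s", "k_f", "k_s"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=1e-3)
        assert fit.converged and fit.residual_rms < 1e-10

    def test_noisy_replicates_recover_rates_within_10pct(self):
        # 50 replicates at the instrument noise level, 1 Hz over 600 s
        k_f, k_s = [], []
        for rep in range(50):
            fit = fit_trace(synthetic_trace(self.TRUTH, noise_sd=0.002, seed=rep))
            k_f.append(fit.params.k_f)
            k_s.append(fit.params.k_s)
        assert np.median(k_f) == pytest.approx(self.TRUTH.k_f, rel=0.10)
        assert np.median(k_s) == pytest.approx(self.TRUTH.k_s, rel=0.10)

    def test_single_exponential_truth_flags_vanishing_fast_amplitude(self):
        single = RelaxationParams(dx_eq=0.1, dx_f=0.0, dx_s=0.1, k_f=0.1, k_s=0.01)
        fit = fit_trace(synthetic_trace(single, noise_sd=0.001, seed=4))
        assert (fit.params.dx_f <= 3 * fit.uncertainties["dx_f"]
                or "fast_amplitude_consistent_with_zero" in fit.flags
                or fit.params.dx_f < 0.01 * fit.params.dx_eq)

    def test_decreasing_trace_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError, match="decreases"):
            fit_trace(Trace(times=t, extensions=0.1 * np.exp(-t / 20.0),
                            force=20.0, concentration=5.0))

    def test_short_trace_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match=">= 20"):
            fit_trace(Trace(times=t, extensions=np.linspace(0, 0.1, 10),
                            force=20.0, concentration=5.0))

    def test_unresolved_slow_mode_is_flagged(self):
        slow = RelaxationParams(dx_eq=0.1, dx_f=0.02, dx_s=0.08, k_f=0.05, k_s=1e-4)
        fit = fit_trace(synthetic_trace(slow, duration=300.0))
        assert "slow_mode_unresolved" in fit.flags


class TestDecomposeRates:
    CONCS = np.array([1.0, 3.0, 5.0, 7.0])

    def _series(self, rates, noise=0.0, seed=0):
        pairs = [observed_rates_preequilibrium(rates, c) for c in self.CONCS]
        k_f = np.array([p[0] for p in pairs])
        k_s = np.array([p[1] for p in pairs])
        if noise > 0:
            rng = np.random.default_rng(seed)
            k_f = k_f * (1 + noise * rng.standard_normal(k_f.shape))
            k_s = k_s * (1 + noise * rng.standard_normal(k_s.shape))
        return ConditionSeries(force=0.0, concentrations=self.CONCS, k_f=k_f, k_s=k_s)

    def test_noiseless_inversion_recovers_generating_rates(self, zero_force_rates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose_rates(self._series(zero_force_rates))
        for name in ("k1", "k_m1", "k2", "k_m2"):
            assert getattr(dec.rates, name) == pytest.approx(
                getattr(zero_force_rates, name), rel=1e-3)

    def test_noisy_replicates_recover_within_25pct(self, zero_force_rates):
        # 10% multiplicative noise on the observed rates, 100 replicates.
        # The bounded joint fit is the noise-robust variant: at zero force
        # k1*C << k-1, so the sequential two-stage route propagates a noisy
        # (sometimes negative) k1 into the slow-rate design and loses k2.
        estimates = {n: [] for n in ("k1", "k_m1", "k2", "k_m2")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(100):
                dec = decompose_rates(self._series(zero_force_rates, noise=0.10, seed=rep),
                                      joint=True)
                for n in estimates:
                    estimates[n].append(getattr(dec.rates, n))
        for n, values in estimates.items():
            assert np.median(values) == pytest.approx(
                getattr(zero_force_rates, n), rel=0.25)

    def test_two_stage_unbiased_for_first_step_under_noise(self, zero_force_rates):
        # the sequential route still recovers the well-conditioned
        # first-step rates and the slow intercept
        estimates = {n: [] for n in ("k1", "k_m1", "k_m2")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(100):
                dec = decompose_rates(self._series(zero_force_rates, noise=0.10, seed=rep))
                for n in estimates:
                    estimates[n].append(getattr(dec.rates, n))
        for n, values in estimates.items():
            assert np.median(values) == pytest.approx(
                getattr(zero_force_rates, n), rel=0.25)

    def test_concentration_independent_slow_rate_gives_zero_k2(self, zero_force_rates):
        from dataclasses import replace
        no_conversion = replace(zero_force_rates, k2=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose_rates(self._series(no_conversion))
        assert dec.rates.k2 == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_concentration_ordering(self, zero_force_rates):
        series = self._series(zero_force_rates, noise=0.05, seed=1)
        perm = np.array([2, 0, 3, 1])
        shuffled = ConditionSeries(force=0.0,
                                   concentrations=series.concentrations[perm],
                                   k_f=series.k_f[perm], k_s=series.k_s[perm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = decompose_rates(series)
            b = decompose_rates(shuffled)
        assert a.rates.k1 == pytest.approx(b.rates.k1, rel=1e-9)
        assert a.rates.k_m2 == pytest.approx(b.rates.k_m2, rel=1e-9)

    def test_invariant_to_uniform_uncertainty_rescaling(self, zero_force_rates):
        base = self._series(zero_force_rates, noise=0.05, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = []
            for scale in (1.0, 10.0):
                series = ConditionSeries(
                    force=0.0, concentrations=base.concentrations,
                    k_f=base.k_f, k_s=base.k_s,
                    sigma_k_f=scale * 0.1 * base.k_f,
                    sigma_k_s=scale * 0.1 * base.k_s)
                results.append(decompose_rates(series).rates)
        assert results[0].k1 == pytest.approx(results[1].k1, rel=1e-9)
        assert results[0].k2 == pytest.approx(results[1].k2, rel=1e-9)

    def test_exact_method_removes_preequilibrium_bias(self, zero_force_rates):
        from threadkin.kinetics import observed_rates_exact
        pairs = [observed_rates_exact(zero_force_rates, c) for c in self.CONCS]
        series = ConditionSeries(force=0.0, concentrations=self.CONCS,
                                 k_f=np.array([p[0] for p in pairs]),
                                 k_s=np.array([p[1] for p in pairs]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose_rates(series, method="exact")
        for name in ("k1", "k_m1", "k2", "k_m2"):
            assert getattr(dec.rates, name) == pytest.approx(
                getattr(zero_force_rates, name), rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            ConditionSeries(force=0.0, concentrations=[1.0, 3.0],
                            k_f=[0.07, 0.07], k_s=[4e-3, 4e-3])


class TestFitForceDependence:
    def test_noiseless_log_linear_inversion(self):
        truth = BellParams(k0=5.8e-3, x_dagger=0.08)
        rows = [(f, float(bell_rate(truth, f, KBT))) for f in (20.0, 30.0, 50.0)]
        fit = fit_force_dependence(rows, KBT)
        assert fit.params.k0 == pytest.approx(truth.k0, rel=1e-10)
        assert fit.params.x_dagger == pytest.approx(truth.x_dagger, abs=1e-10)

    def test_equals_closed_form_regression(self):
        # the fit must be exactly the least-squares solution in log space
        rng = np.random.default_rng(5)
        forces = np.array([20.0, 30.0, 50.0])
        rates = 1e-3 * np.exp(rng.normal(0, 0.3, 3))
        fit = fit_force_dependence(list(zip(forces, rates)), KBT)
        slope, intercept = np.polyfit(forces, np.log(rates), 1)
        assert fit.params.x_dagger == pytest.approx(slope * KBT, rel=1e-10)
        assert fit.params.k0 == pytest.approx(np.exp(intercept), rel=1e-10)

    def test_decreasing_rates_give_negative_distance(self):
        truth = BellParams(k0=3.6e-3, x_dagger=-0.15)
        rows = [(f, float(bell_rate(truth, f, KBT))) for f in (20.0, 30.0, 50.0)]
        assert fit_force_dependence(rows, KBT).params.x_dagger < 0

    def test_constant_rates_give_zero_distance(self):
        fit = fit_force_dependence([(20.0, 1e-3), (30.0, 1e-3), (50.0, 1e-3)], KBT)
        assert fit.params.x_dagger == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            fit_force_dependence([(20.0, 1e-3), (30.0, 0.0), (50.0, 1e-3)], KBT)

    def test_too_few_forces_rejected(self):
        with pytest.raises(ValueError):
            fit_force_dependence([(20.0, 1e-3), (30.0, 1e-3)], KBT)


class TestEquilibriumRoute:
    FORCES = (20.0, 30.0, 50.0)

    def _route_inputs(self, kd_by_force, kd1_by_force, concs=(1.0, 3.0, 5.0, 7.0, 20.0)):
        c = np.array(concs)
        occupancy = {F: (c, equilibrium_extension(c, kd_by_force[F], 1.0))
                     for F in kd_by_force}
        ratios = {F: (c, amplitude_ratio(c, kd1_by_force[F])) for F in kd1_by_force}
        return occupancy, ratios

    def test_noiseless_isotherm_recovers_Kd(self):
        occ, rat = self._route_inputs({F: 4.1 for F in self.FORCES},
                                      {F: 11.0 for F in self.FORCES})
        result = equilibrium_route(occ, rat, KBT)
        assert np.allclose(result.per_force["Kd"], 4.1, rtol=1e-6)
        assert np.allclose(result.per_force["Kd1"], 11.0, rtol=1e-6)

    def test_K2_identity_holds(self):
        occ, rat = self._route_inputs({F: 4.1 for F in self.FORCES},
                                      {F: 11.0 for F in self.FORCES})
        result = equilibrium_route(occ, rat, KBT)
        np.testing.assert_allclose(result.per_force["K2"],
                                   result.per_force["Kd1"] / result.per_force["Kd"],
                                   rtol=1e-12)

    def test_force_law_recovered_from_exponential_constants(self):
        # K(F) generated from (K0 = 4.1 nM, x0 = 0.33 nm) must invert exactly
        kd = {F: 4.1 * np.exp(-F * 0.33 / KBT) for F in self.FORCES}
        kd1 = {F: 11.0 * np.exp(-F * 0.25 / KBT) for F in self.FORCES}
        occ, rat = self._route_inputs(kd, kd1)
        result = equilibrium_route(occ, rat, KBT)
        assert result.laws["Kd"].law.K0 == pytest.approx(4.1, rel=1e-4)
        assert result.laws["Kd"].law.x0 == pytest.approx(0.33, abs=1e-4)
        assert result.laws["Kd1"].law.K0 == pytest.approx(11.0, rel=1e-4)

    def test_saturated_isotherm_flagged_unidentifiable(self):
        c = np.array([1.0, 3.0, 5.0])
        occ = {20.0: (c, np.ones_like(c))}
        rat = {20.0: (c, amplitude_ratio(c, 11.0))}
        result = equilibrium_route(occ, rat, KBT)
        assert any("unidentifiable" in f for f in result.flags)


class TestConsistencyReport:
    def test_identical_inputs_give_unit_ratios(self):
        vals = {"Kd": (15.0, 6.0), "Kd1": (35.0, 9.0), "K2": (1.8, 0.6)}
        report = consistency_report(vals, vals)
        assert np.allclose(report["ratio"], 1.0)
        assert report["overlap_within_errors"].all()

    def test_published_two_column_comparison(self):
        kinetic = {"Kd": (15.0, 6.0), "Kd1": (35.0, 9.0), "K2": (1.8, 0.6)}
        equilibrium = {"Kd": (4.1, 1.4), "Kd1": (11.0, 4.0), "K2": (2.7, 0.8)}
        report = consistency_report(kinetic, equilibrium)
        assert report.loc["Kd", "kinetic"] == 15.0
        assert report.loc["Kd", "equilibrium"] == 4.1
        assert report.loc["Kd1", "ratio"] == pytest.approx(35 / 11, rel=1e-12)
        # overall binding is roughly twice as tight as the first step in
        # both columns
        assert 0.3 < kinetic["Kd"][0] / kinetic["Kd1"][0] < 0.6
        assert 0.3 < equilibrium["Kd"][0] / equilibrium["Kd1"][0] < 0.6


class TestFullPipeline:
    def test_noiseless_pipeline_recovers_truth_within_10pct(
            self, noiseless_experiment, kinetic_truth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_experiment(noiseless_experiment)
        for name, truth in kinetic_truth.items():
            got = result.bell[name].params
            assert got.k0 == pytest.approx(truth.k0, rel=0.10)
            assert got.x_dagger == pytest.approx(truth.x_dagger, abs=0.01)

    def test_single_force_skips_bell_stage(self):
        traces = [simulate_trace(SimulationConfig(force=20.0, concentration=c,
                                                  noise_sd=0.0, seed=0))
                  for c in (1.0, 3.0, 5.0, 7.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_experiment(traces)
        assert result.bell == {}
        assert any("too_few_forces" in f for f in result.flags)

    def test_staged_estimates_preserved_alongside_refinement(self, noiseless_experiment):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_experiment(noiseless_experiment)
        assert set(result.bell_staged) == {"k1", "k_m1", "k2", "k_m2"}

    def test_global_refinement_matches_truth_given_exact_observations(
            self, kinetic_truth, zero_force_rates):
        from threadkin.kinetics import observed_rates_exact, rates_at_force
        observations = []
        for F in (20.0, 30.0, 50.0):
            rates = rates_at_force(kinetic_truth, F, KBT)
            for C in (1.0, 3.0, 5.0, 7.0):
                lam_f, lam_s = observed_rates_exact(rates, C)
                observations.append((F, C, lam_f, lam_s, 1e-5, 1e-6))
        init = {n: BellParams(k0=2e-3 if n == "k1" else 1e-2, x_dagger=0.0)
                for n in kinetic_truth}
        refined = refine_bell_global(observations, init, KBT)
        for name, truth in kinetic_truth.items():
            assert refined[name].params.k0 == pytest.approx(truth.k0, rel=1e-4)
            assert refined[name].params.x_dagger == pytest.approx(
                truth.x_dagger, abs=1e-4)


class TestForceLawFit:
    def test_log_linear_inversion(self):
        rows = [(F, 15.0 * np.exp(-F * 0.44 / KBT)) for F in (20.0, 30.0, 50.0)]
        fit = fit_force_law(rows, KBT)
        assert fit.law.K0 == pytest.approx(15.0, rel=1e-10)
        assert fit.law.x0 == pytest.approx(0.44, abs=1e-10)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            fit_force_law([(20.0, 1.0), (30.0, -1.0)], KBT)
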