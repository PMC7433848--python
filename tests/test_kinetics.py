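"""Rate-law simulation, numerical differentiation, order fitting, reagents."""

import numpy as np
import pytest

from ironstrip import (
    ComputationError,
    ConfigurationError,
    KineticConditions,
    KineticTrace,
    OpticalConstants,
    RateLawEstimator,
    RateLawParams,
    absorbance_from_complex,
    complex_from_absorbance,
    estimate_rates,
    fit_reaction_orders,
    gen_kinetic_trace,
    simulate_complex_formation,
)
from ironstrip.kinetics import (
    OPTIMIZED_SCHEME,
    SCHEME_PRESETS,
    compute_molar_ratios,
    ug_dl_to_mol_l,
)

K_PRIME = 5000.0


class TestSimulation:
    def test_zero_rate_constant_gives_flat_zero(self):
        cond = KineticConditions.from_assay(100.0, 4.0)
        trace = simulate_complex_formation(cond, RateLawParams(k_prime=0.0))
        assert np.all(trace.values == 0)

    def test_pseudo_first_order_closed_form(self):
        # alpha=1 with ferene in vast excess: COM(t) = iron0*(1 - e^(-k_obs t))
        cond = KineticConditions(iron0=1e-6, ferene0=1.0, duration=60.0, n_points=601)
        params = RateLawParams(k_prime=0.05, alpha=1.0, beta=2.0)
        trace = simulate_complex_formation(cond, params)
        k_obs = params.k_prime * cond.ferene0**params.beta
        closed = cond.iron0 * (1.0 - np.exp(-k_obs * trace.times))
        np.testing.assert_allclose(trace.values[1:], closed[1:], rtol=1e-5)

    def test_stoichiometric_conservation_and_bounds(self, design_2x2):
        for trace in design_2x2:
            iron0, ferene0 = trace.conditions.iron0, trace.conditions.ferene0
            com = trace.values
            fe = iron0 - com
            fer = ferene0 - 3.0 * com
            assert np.all(fe >= -1e-6 * iron0)
            assert np.all(fer >= -1e-6 * ferene0)
            assert np.all(com <= min(iron0, ferene0 / 3.0) * (1 + 1e-12))
            assert np.all(np.diff(com) >= -1e-18)

    def test_endpoint_stable_under_grid_refinement(self):
        params = RateLawParams(k_prime=K_PRIME)
        coarse = simulate_complex_formation(
            KineticConditions.from_assay(100.0, 4.0, n_points=601), params
        )
        fine = simulate_complex_formation(
            KineticConditions.from_assay(100.0, 4.0, n_points=1201), params
        )
        rel = abs(fine.values[-1] - coarse.values[-1]) / fine.values[-1]
        assert rel < 1e-6

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigurationError, match="iron0"):
            KineticConditions(iron0=-1e-6, ferene0=1e-3)


class TestBeerLambert:
    def test_zero_complex_gives_zero_absorbance(self, optics):
        cond = KineticConditions.from_assay(100.0, 4.0, duration=1.0, n_points=3)
        trace = simulate_complex_formation(cond, RateLawParams(k_prime=0.0))
        assert np.all(absorbance_from_complex(trace, optics).values == 0)

    def test_hand_computed_absorbance(self, optics):
        # epsilon*l*[COM] = 33366 * 0.6 * 5e-6 = 0.100098
        cond = KineticConditions(iron0=5e-6, ferene0=1e-3, duration=1.0, n_points=3)
        trace = KineticTrace(
            times=np.array([0.0, 0.5, 1.0]), values=np.full(3, 5e-6), conditions=cond
        )
        out = absorbance_from_complex(trace, optics)
        np.testing.assert_allclose(out.values, 0.100098, rtol=1e-12)

    def test_linearity_and_round_trip(self, optics, design_2x2):
        trace = design_2x2[0]
        a1 = absorbance_from_complex(trace, optics)
        doubled = KineticTrace(
            times=trace.times, values=2 * trace.values, conditions=trace.conditions
        )
        a2 = absorbance_from_complex(doubled, optics)
        np.testing.assert_allclose(a2.values, 2 * a1.values, rtol=1e-15)
        back = complex_from_absorbance(a1, optics)
        np.testing.assert_allclose(back.values, trace.values, rtol=1e-15)

    def test_double_transform_rejected(self, optics, design_2x2):
        a = absorbance_from_complex(design_2x2[0], optics)
        with pytest.raises(ConfigurationError):
            absorbance_from_complex(a, optics)


class TestRateEstimation:
    @staticmethod
    def _trace(values, times):
        cond = KineticConditions(
            iron0=1e-5, ferene0=1e-3, duration=float(times[-1]), n_points=len(times)
        )
        return KineticTrace(times=times, values=values, conditions=cond)

    def test_linear_trace_has_constant_rate(self):
        t = np.linspace(0, 10, 51)
        series = estimate_rates(self._trace(3e-7 * t, t))
        np.testing.assert_allclose(series.rates, 3e-7, rtol=1e-12)

    def test_quadratic_trace_central_difference_exact(self):
        t = np.linspace(0, 4, 41)
        series = estimate_rates(self._trace(t**2, t))
        np.testing.assert_allclose(series.rates[1:-1], 2 * t[1:-1], rtol=1e-12)

    def test_smoothing_shrinks_derivative_noise(self):
        # central difference of a width-w moving average telescopes: interior
        # rate noise SD is sigma/(w*dt) vs sigma/(sqrt(2)*dt) unsmoothed,
        # so the w=9 window shrinks it by a factor w/sqrt(2) ~ 6.4
        t = np.linspace(0, 10, 101)
        sds = {w: [] for w in (1, 9)}
        for seed in range(300):
            noise = np.random.default_rng(seed).normal(0, 1e-6, t.size)
            for w in sds:
                series = estimate_rates(self._trace(noise, t), smoothing_window=w)
                sds[w].append(series.rates[5:-5].std())
        ratio = np.mean(sds[1]) / np.mean(sds[9])
        assert ratio == pytest.approx(9 / np.sqrt(2), rel=0.1)

    def test_non_monotonic_times_rejected(self):
        with pytest.raises(ConfigurationError):
            self._trace(np.zeros(3), np.array([0.0, 2.0, 1.0]))

    def test_even_smoothing_window_rejected(self, design_2x2):
        with pytest.raises(ConfigurationError):
            estimate_rates(design_2x2[0], smoothing_window=4)


class TestOrderFitting:
    def test_noise_free_recovery_of_orders_and_k(self, design_2x2):
        est = fit_reaction_orders(design_2x2)
        assert est.alpha == pytest.approx(1.0, abs=0.05)
        assert est.beta == pytest.approx(2.0, abs=0.05)
        assert est.k_prime == pytest.approx(K_PRIME, rel=0.05)
        assert np.all(np.abs(est.residuals) < 0.05)

    def test_loglog_cross_check_agrees(self, design_2x2):
        est = fit_reaction_orders(design_2x2)
        assert est.alpha_loglog == pytest.approx(est.alpha, abs=0.01)
        assert est.beta_loglog == pytest.approx(est.beta, abs=0.01)
        assert est.k_prime_loglog == pytest.approx(est.k_prime, rel=0.05)

    def test_derivative_route_agrees_with_poly_route(self, design_2x2):
        poly = fit_reaction_orders(design_2x2, rate_method="poly")
        deriv = fit_reaction_orders(design_2x2, rate_method="derivative")
        assert deriv.alpha == pytest.approx(poly.alpha, abs=0.01)
        assert deriv.beta == pytest.approx(poly.beta, abs=0.02)
        assert deriv.k_prime == pytest.approx(poly.k_prime, rel=0.06)

    def test_iron_independent_rates_give_zero_alpha(self):
        params = RateLawParams(k_prime=0.002, alpha=0.0, beta=1.0)
        traces = [
            simulate_complex_formation(
                KineticConditions.from_assay(iron, fer, duration=5.0, n_points=501), params
            )
            for iron in (50.0, 100.0)
            for fer in (2.0, 4.0)
        ]
        est = fit_reaction_orders(traces)
        assert est.alpha == pytest.approx(0.0, abs=0.02)
        assert est.beta == pytest.approx(1.0, abs=0.02)

    def test_noisy_recovery_within_fifteen_percent(self, optics):
        # absorbance noise SD 0.002 a.u., dense grid, wider initial window
        params = RateLawParams(k_prime=K_PRIME)
        results = []
        for seed in range(6):
            traces = []
            for i, (iron, fer) in enumerate([(50, 2), (50, 4), (100, 2), (100, 4)]):
                cond = KineticConditions.from_assay(iron, fer, duration=120.0, n_points=6001)
                tr = gen_kinetic_trace(cond, params, optics, noise_sd=0.002, seed=97 * seed + i)
                traces.append(complex_from_absorbance(tr, optics))
            est = fit_reaction_orders(traces, window_fraction=0.3)
            results.append((est.alpha, est.beta, est.k_prime))
        alpha, beta, k_prime = np.mean(results, axis=0)
        assert alpha == pytest.approx(1.0, rel=0.15)
        assert beta == pytest.approx(2.0, rel=0.15)
        assert k_prime == pytest.approx(K_PRIME, rel=0.15)

    def test_incomplete_design_rejected(self, design_2x2):
        with pytest.raises(ConfigurationError):
            RateLawEstimator().fit(design_2x2[:3])

    def test_zero_rate_cell_rejected(self):
        traces = [
            simulate_complex_formation(
                KineticConditions.from_assay(iron, fer, duration=1.0, n_points=11),
                RateLawParams(k_prime=0.0),
            )
            for iron in (50.0, 100.0)
            for fer in (2.0, 4.0)
        ]
        with pytest.raises(ComputationError):
            fit_reaction_orders(traces)


class TestReagentRatios:
    def test_optimized_ferene_ratio_in_expected_band(self):
        ratios = compute_molar_ratios(OPTIMIZED_SCHEME).set_index("species")["ratio_to_iron"]
        assert 220 <= ratios["ferene"] <= 320
        assert ratios["ferene"] == pytest.approx(223.4, rel=0.01)

    def test_far_excess_reagents_in_expected_band(self):
        ratios = compute_molar_ratios(OPTIMIZED_SCHEME).set_index("species")["ratio_to_iron"]
        for species in ("citric_acid", "ascorbic_acid", "thiourea"):
            assert 2_700 <= ratios[species] <= 55_000
        assert ratios["ascorbic_acid"] == pytest.approx(5.7e3, rel=0.01)

    @pytest.mark.parametrize("label", ["original", "optimized", "strip"])
    def test_presets_ferene_excess(self, label):
        ratios = compute_molar_ratios(SCHEME_PRESETS[label]).set_index("species")[
            "ratio_to_iron"
        ]
        assert 220 <= ratios["ferene"] <= 320

    def test_wet_volume_fractions_sum_to_one(self):
        s = OPTIMIZED_SCHEME
        total = s.volume_reagent_a_ul + s.volume_reagent_b_ul + s.volume_sample_ul
        assert total == pytest.approx(s.final_volume_ul)

    def test_zero_iron_rejected(self):
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            compute_molar_ratios(replace(OPTIMIZED_SCHEME, sample_iron_ug_dl=0.0))


def test_unit_conversion_round_trip():
    from ironstrip.kinetics import mol_l_to_ug_dl

    assert mol_l_to_ug_dl(ug_dl_to_mol_l(100.0)) == pytest.approx(100.0, rel=1e-12)
    # 100 ug/dL of iron is ~17.9 umol/L
    assert ug_dl_to_mol_l(100.0) == pytest.approx(1.7906e-5, rel=1e-4)
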