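"""Circuit model and complex nonlinear least-squares fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from growthmon import eis, simulate
from conftest import circuit_impedance_oracle

positive = st.floats(min_value=1e-3, max_value=1e6)
capacitance = st.floats(min_value=1e-12, max_value=1e-5)


def params_strategy():
    return st.builds(
        eis.CircuitParameters,
        r_med=positive,
        r_cell=positive,
        c_cell=capacitance,
        r_el=positive,
        c_el=capacitance,
    )


class TestCircuitImpedance:
    def test_matches_direct_complex_arithmetic_oracle(self, circuit):
        """Branch-by-branch 1/(1/R + i*2*pi*f*C) evaluation agrees to 1e-9 rel."""
        f = np.logspace(1, 7, 100)
        z = eis.circuit_impedance(circuit, f)
        z_oracle = circuit_impedance_oracle(circuit, f)
        assert np.all(np.abs(z - z_oracle) <= 1e-9 * np.abs(z_oracle))

    def test_single_frequency_example(self, circuit):
        z = eis.circuit_impedance(circuit, 10e3)
        z_oracle = complex(circuit_impedance_oracle(circuit, np.array([10e3]))[0])
        assert abs(z - z_oracle) <= 1e-9 * abs(z_oracle)

    @given(params=params_strategy())
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_asymptotes(self, params):
        """High f: Re -> R_med, Im -> 0; low f: Re -> sum of resistances.

        Probe frequencies sit far beyond the branch corner frequencies, which
        depend on the sampled parameters."""
        corners = [
            1.0 / (2 * np.pi * params.r_cell * params.c_cell),
            1.0 / (2 * np.pi * params.r_el * params.c_el),
        ]
        total = params.r_med + params.r_cell + params.r_el
        z_hi = eis.circuit_impedance(params, 1e7 * max(corners))
        assert z_hi.real == pytest.approx(params.r_med, abs=1e-6 * total)
        assert abs(z_hi.imag) < 1e-6 * total
        z_lo = eis.circuit_impedance(params, 1e-7 * min(corners))
        assert z_lo.real == pytest.approx(total, rel=1e-6)
        assert abs(z_lo.imag) < 1e-6 * total

    @given(params=params_strategy())
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_real_part_monotone_nonincreasing_in_frequency(self, params):
        f = np.logspace(0, 8, 200)
        re = eis.circuit_impedance(params, f).real
        assert np.all(np.diff(re) <= 1e-9 * re[:-1] + 1e-12)

    def test_capacitive_sign_convention(self, circuit):
        """Stored Im(Z) is the mathematical imaginary part: negative here."""
        f = simulate.default_frequencies(10)
        assert np.all(eis.circuit_impedance(circuit, f).imag < 0)

    def test_imag_magnitude_decreases_with_c_cell_in_high_regime(self):
        """In the regime 2*pi*f*R_cell*C_cell > 1 across the band, growing
        cell capacitance shrinks |Im(Z)| at every fixed frequency."""
        f = simulate.default_frequencies(15)
        r_cell = 1e4
        c_grid = np.linspace(4e-8, 4e-7, 12)
        assert 2 * np.pi * f.min() * r_cell * c_grid.min() > 1
        prev = None
        for c in c_grid:
            p = eis.CircuitParameters(100.0, r_cell, c, 500.0, 1e-7)
            cur = np.abs(eis.circuit_impedance(p, f).imag)
            if prev is not None:
                assert np.all(cur < prev)
            prev = cur

    def test_rejects_nonpositive_frequency(self, circuit):
        with pytest.raises(ValueError, match="frequency"):
            eis.circuit_impedance(circuit, 0.0)

    def test_rejects_nonpositive_parameter(self):
        with pytest.raises(ValueError, match="c_cell"):
            eis.CircuitParameters(100.0, 1000.0, -1e-9, 500.0, 1e-7)


class TestSpectrumComponents:
    def test_three_four_five_triangle(self):
        sp = eis.ImpedanceSpectrum(np.array([1e3]), np.array([3 + 4j]))
        mod, re, im = eis.spectrum_components(sp)
        assert mod[0] == pytest.approx(5.0)
        assert re[0] == pytest.approx(3.0)
        assert im[0] == pytest.approx(4.0)

    def test_purely_real_spectrum(self):
        sp = eis.ImpedanceSpectrum(np.array([1e3, 2e3]), np.array([10.0, 20.0]))
        mod, re, im = eis.spectrum_components(sp)
        assert np.all(im == 0)
        assert np.allclose(mod, np.abs(re))

    def test_model_spectrum_components_match_oracle(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(circuit, frequencies)
        mod, re, im = eis.spectrum_components(sp)
        z_oracle = circuit_impedance_oracle(circuit, frequencies)
        assert np.allclose(re, z_oracle.real, rtol=1e-12)
        assert np.allclose(im, z_oracle.imag, rtol=1e-12)
        assert np.allclose(mod**2, re**2 + im**2, rtol=1e-12)

    def test_spectrum_sorts_and_validates(self):
        sp = eis.ImpedanceSpectrum(np.array([2e3, 1e3]), np.array([1 + 0j, 2 + 0j]))
        assert np.all(np.diff(sp.frequencies) > 0)
        assert sp.z[0] == 2 + 0j
        with pytest.raises(ValueError):
            eis.ImpedanceSpectrum(np.array([1e3, 1e3]), np.array([1j, 2j]))
        with pytest.raises(ValueError):
            eis.ImpedanceSpectrum(np.array([-1e3, 1e3]), np.array([1j, 2j]))


class TestFitCircuit:
    def test_noiseless_roundtrip_recovers_free_params(self, circuit, frequencies):
        """Fit of an exact model spectrum recovers parameters to 0.1%."""
        sp = simulate.simulate_spectrum(circuit, frequencies)
        init = eis.CircuitParameters.from_array(circuit.as_array() * 2.0)
        res = eis.fit_circuit(sp, init=init)
        assert res.converged
        assert np.all(
            np.abs(res.params.as_array() / circuit.as_array() - 1.0) < 1e-3
        )

    def test_degenerate_cell_branch(self, circuit, frequencies):
        """With the cell branch removed, the fit reproduces the medium plus
        electrode-only spectrum."""
        no_cell = circuit.replace(r_cell=eis.NEGLIGIBLE_RESISTANCE_OHM)
        sp = simulate.simulate_spectrum(no_cell, frequencies)
        init = no_cell.replace(r_med=70.0, r_el=900.0, c_el=3e-7)
        res = eis.fit_circuit(sp, init=init, fixed=("r_cell", "c_cell"))
        assert res.params.r_med == pytest.approx(circuit.r_med, rel=1e-4)
        assert res.params.r_el == pytest.approx(circuit.r_el, rel=1e-4)
        assert res.params.c_el == pytest.approx(circuit.c_el, rel=1e-4)

    def test_noisy_c_cell_within_5_percent(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(
            circuit, frequencies, simulate.SpectrumNoise(0.01, seed=42)
        )
        init = circuit.replace(r_med=150.0, r_cell=1500.0, c_cell=5e-9)
        res = eis.fit_circuit(sp, init=init, fixed=("r_el", "c_el"))
        assert abs(res.params.c_cell / circuit.c_cell - 1.0) < 0.05

    def test_fit_invariant_to_input_ordering(self, circuit, frequencies):
        rng = np.random.default_rng(3)
        sp = simulate.simulate_spectrum(
            circuit, frequencies, simulate.SpectrumNoise(0.01, seed=5)
        )
        perm = rng.permutation(len(sp))
        shuffled = eis.ImpedanceSpectrum(sp.frequencies[perm], sp.z[perm])
        init = eis.CircuitParameters.from_array(circuit.as_array() * 1.5)
        a = eis.fit_circuit(sp, init=init)
        b = eis.fit_circuit(shuffled, init=init)
        assert np.allclose(a.params.as_array(), b.params.as_array(), rtol=1e-12)

    def test_optimizer_never_worsens_objective(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(
            circuit, frequencies, simulate.SpectrumNoise(0.02, seed=8)
        )
        init = eis.CircuitParameters.from_array(circuit.as_array() * 3.0)
        res = eis.fit_circuit(sp, init=init)
        assert res.residual_norm <= eis.residual_norm(sp, init) + 1e-15

    def test_residual_norm_zero_only_for_exact_model(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(circuit, frequencies)
        assert eis.residual_norm(sp, circuit) == pytest.approx(0.0, abs=1e-12)
        assert eis.residual_norm(sp, circuit.replace(r_med=101.0)) > 0

    def test_too_few_points_rejected(self, circuit):
        sp = eis.ImpedanceSpectrum(
            np.array([5e3, 20e3, 90e3]), np.array([1 + 1j, 2 + 2j, 3 + 3j])
        )
        with pytest.raises(ValueError, match="free parameters"):
            eis.fit_circuit(sp, init=circuit)

    def test_all_fixed_returns_init(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(circuit, frequencies)
        res = eis.fit_circuit(sp, init=circuit, fixed=eis.PARAM_NAMES)
        assert res.params == circuit
        assert res.converged


class TestFitSeries:
    def _series(self, circuit, frequencies, noise_sd=0.01, seed=0, n_t=13):
        growth = simulate.GrowthSimParams(seed=seed)
        t = np.linspace(0, 96, n_t)
        c_true, _ = simulate.simulate_growth_curve(growth, t)
        rng = np.random.default_rng(seed)
        spectra = [
            simulate.simulate_spectrum(
                circuit.replace(c_cell=float(c)),
                frequencies,
                simulate.SpectrumNoise(noise_sd, int(rng.integers(2**31))),
                timepoint=float(tp),
            )
            for tp, c in zip(t, c_true)
        ]
        return t, c_true, spectra

    def test_recovers_rising_c_cell_within_5_percent(self, circuit, frequencies):
        t, c_true, spectra = self._series(circuit, frequencies)
        series = eis.fit_series(
            spectra, electrode_params=(circuit.r_el, circuit.c_el)
        )
        rel = np.abs(series.c_cell() / c_true - 1.0)
        assert np.all(rel < 0.05)

    def test_held_constant_parameters_stay_flat(self, circuit, frequencies):
        """R_med and R_cell do not drift when only C_cell varies."""
        t, c_true, spectra = self._series(circuit, frequencies)
        series = eis.fit_series(
            spectra, electrode_params=(circuit.r_el, circuit.c_el)
        )
        r_med = np.array([r.params.r_med for r in series.results])
        r_cell = np.array([r.params.r_cell for r in series.results])
        assert r_med.std() / r_med.mean() < 0.05
        assert r_cell.std() / r_cell.mean() < 0.05

    def test_electrode_pinned_from_calibration(self, circuit, frequencies):
        jw = 2j * np.pi * frequencies
        z_cal = circuit.r_med + circuit.r_el / (1 + jw * circuit.r_el * circuit.c_el)
        cal = eis.ImpedanceSpectrum(frequencies, z_cal)
        r_el, c_el = eis.fit_electrode_calibration(cal)
        assert r_el == pytest.approx(circuit.r_el, rel=1e-4)
        assert c_el == pytest.approx(circuit.c_el, rel=1e-4)

    def test_single_timepoint_equals_fit_circuit(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(
            circuit, frequencies, simulate.SpectrumNoise(0.01, 4), timepoint=0.0
        )
        series = eis.fit_series([sp], electrode_params=(circuit.r_el, circuit.c_el))
        init = eis.initial_guess(sp).replace(r_el=circuit.r_el, c_el=circuit.c_el)
        single = eis.fit_circuit(sp, init=init, fixed=("r_el", "c_el"))
        assert np.allclose(
            series.results[0].params.as_array(), single.params.as_array(), rtol=1e-12
        )

    def test_missing_calibration_is_instructive(self, circuit, frequencies):
        sp = simulate.simulate_spectrum(circuit, frequencies)
        with pytest.raises(ValueError, match="electrode"):
            eis.fit_series([sp])

    def test_output_ordered_by_time(self, circuit, frequencies):
        _, _, spectra = self._series(circuit, frequencies, n_t=5)
        series = eis.fit_series(
            spectra[::-1], electrode_params=(circuit.r_el, circuit.c_el)
        )
        assert np.all(np.diff(series.timepoints) > 0)
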