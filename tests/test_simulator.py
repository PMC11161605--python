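"""Vocal fold model: grid assembly, forces, integrator, flow, spectra.

The long self-oscillation runs that reproduce the tight/weak adduction
fundamental frequencies live in the acceptance suite; here the model is
exercised piece by piece against closed-form oracles.
"""

import math

import numpy as np
import pytest

from glottkit.simulator import (
    SimState,
    VFModelParams,
    build_grid,
    derivatives,
    flow_spectrum,
    glottal_flow,
    simulate,
    step_rk4,
    string_natural_frequency,
)


class TestStringFormula:
    def test_ligament_stress_prediction(self):
        """0.9 MPa over 0.945 cm of tissue at 1000 kg/m^3 -> 1587 Hz."""
        f = string_natural_frequency(0.9e6, 1000.0, 0.00945)
        assert f == pytest.approx(1587.3, abs=0.5)

    def test_square_root_stress_scaling(self):
        f1 = string_natural_frequency(0.9e6, 1000.0, 0.00945)
        f4 = string_natural_frequency(3.6e6, 1000.0, 0.00945)
        assert f4 == pytest.approx(2 * f1, rel=1e-12)

    def test_muscle_stress_value(self):
        # sqrt(5000/1000) / (2 * 0.00945)
        f = string_natural_frequency(5e3, 1000.0, 0.00945)
        assert f == pytest.approx(118.3, abs=0.1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            string_natural_frequency(0.0, 1000.0, 0.00945)


class TestBuildGrid:
    def test_default_grid_has_90_masses_180_states(self):
        p = VFModelParams()
        assert p.n_masses == 90
        assert p.n_state == 180
        state, tables = build_grid(p)
        assert state.displacement.size == 90
        assert state.velocity.size == 90
        assert tables.stiffness.shape == (90, 90)

    def test_total_mass_matches_discretised_volume(self):
        """Lumped masses cover n_ap/(n_ap+1) of the fold volume (the two
        phantom half-cells at the fixed ends carry no mass)."""
        p = VFModelParams()
        _, tables = build_grid(p)
        total = tables.mass * p.n_masses
        expect = p.tissue_density * p.length_L * p.thickness_T * p.depth_D
        assert total == pytest.approx(expect * 5.0 / 6.0, rel=1e-12)

    def test_zero_posterior_width_gives_zero_gap(self):
        _, tables = build_grid(VFModelParams(posterior_width=0.0))
        assert np.all(tables.prephonatory_half_width == 0.0)

    def test_linear_posterior_taper(self):
        p = VFModelParams(posterior_width=6e-4)
        _, tables = build_grid(p)
        h = tables.prephonatory_half_width
        # half-widths at y=(i+1)L/6: 5/6, 4/6, ... of posterior half-gap
        expect = 3e-4 * (1 - (np.arange(5) + 1) / 6.0)
        np.testing.assert_allclose(h, expect, rtol=1e-12)
        assert np.all(np.diff(h) < 0)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            VFModelParams(length_L=-1.0)
        with pytest.raises(ValueError):
            VFModelParams(damping_ratio=1.5)


class TestDerivatives:
    def test_equilibrium_is_a_fixed_point_without_pressure(self):
        p = VFModelParams(lung_pressure=0.0)
        state, tables = build_grid(p)
        dx, dv = derivatives(state, p, tables)
        assert np.all(dx == 0.0)
        np.testing.assert_allclose(dv, 0.0, atol=1e-20)

    def test_discrete_string_second_difference(self):
        """One displaced mass on a 3-mass fiber with shear off: the
        acceleration is -(2 sigma / (rho dy^2)) x."""
        p = VFModelParams(grid=(3, 1, 1), shear_modulus=0.0,
                          lung_pressure=0.0, damping_ratio=0.0,
                          posterior_width=1e-2)  # far from collision
        state, tables = build_grid(p)
        x0 = 1e-5
        state.displacement[1] = x0
        _, dv = derivatives(state, p, tables)
        dy = p.length_L / 4.0
        expect = -2.0 * p.fiber_stress_cover / (p.tissue_density * dy**2) * x0
        assert dv[1] == pytest.approx(expect, rel=1e-12)
        # neighbours feel the single-string pull upward
        assert dv[0] == pytest.approx(-expect / 2.0, rel=1e-12)

    def test_free_vibration_dissipates_energy(self):
        """With damping on and no lung pressure, total mechanical energy
        is non-increasing across RK4 steps."""
        p = VFModelParams(lung_pressure=0.0, dt=2e-6, posterior_width=6e-4)
        state, tables = build_grid(p)
        rng = np.random.default_rng(5)
        state.displacement[:] = 1e-6 * rng.standard_normal(90)

        def energy(s):
            return (0.5 * tables.mass * np.sum(s.velocity**2)
                    + 0.5 * s.displacement @ tables.stiffness @ s.displacement)

        e = [energy(state)]
        for _ in range(10):
            state = step_rk4(state, p, tables=tables)
            e.append(energy(state))
        assert np.all(np.diff(e) <= 1e-18)

    def test_nan_state_raises_with_timestamp(self):
        p = VFModelParams()
        state, tables = build_grid(p)
        state.displacement[0] = np.nan
        state.time = 0.123
        with pytest.raises(FloatingPointError, match="0.123"):
            derivatives(state, p, tables)


def _single_mass_params(**kw):
    """1-mass configuration: a linear oscillator with k = 2 k_string."""
    return VFModelParams(grid=(1, 1, 1), shear_modulus=0.0,
                         lung_pressure=0.0, damping_ratio=0.0,
                         posterior_width=1e-2, **kw)


class TestStepRK4:
    def test_harmonic_oscillator_against_closed_form(self):
        p = _single_mass_params()
        state, tables = build_grid(p)
        k = tables.stiffness[0, 0]
        omega = math.sqrt(k / tables.mass)
        period = 2 * math.pi / omega
        dt = period / 1000.0
        x0 = 1e-5
        state.displacement[0] = x0
        for _ in range(1000):
            state = step_rk4(state, p, dt, tables)
        exact = x0 * math.cos(omega * 1000 * dt)
        assert state.displacement[0] == pytest.approx(exact, rel=1e-6)

    def test_fourth_order_phase_convergence(self):
        """Halving dt shrinks the per-period phase error by ~2^4.

        The phase is reconstructed from (x, v) after one period; the
        displacement alone would hide the phase error at a cosine
        maximum (where it enters only quadratically).
        """
        p = _single_mass_params()
        _, tables = build_grid(p)
        k = tables.stiffness[0, 0]
        omega = math.sqrt(k / tables.mass)
        period = 2 * math.pi / omega
        x0 = 1e-5

        def phase_error(n_steps):
            s = SimState(np.array([x0]), np.array([0.0]))
            dt = period / n_steps
            for _ in range(n_steps):
                s = step_rk4(s, p, dt, tables)
            return abs(math.atan2(-s.velocity[0] / omega, s.displacement[0]))

        ratio = phase_error(256) / phase_error(512)
        assert 12.0 < ratio < 20.0

    def test_zero_rate_is_a_fixed_point(self):
        p = _single_mass_params()
        state, tables = build_grid(p)
        new = step_rk4(state, p, 1e-6, tables)
        assert np.all(new.displacement == 0.0)
        assert np.all(new.velocity == 0.0)

    def test_instability_detector_aborts(self):
        p = _single_mass_params()
        state, tables = build_grid(p)
        state.displacement[0] = 1e-3
        k = tables.stiffness[0, 0]
        dt_unstable = 4.0 / math.sqrt(k / tables.mass)
        with pytest.raises(FloatingPointError, match="unstable"):
            for _ in range(200):
                state = step_rk4(state, p, dt_unstable, tables)

    def test_dt_must_be_positive(self):
        p = _single_mass_params()
        state, tables = build_grid(p)
        with pytest.raises(ValueError):
            step_rk4(state, p, 0.0, tables)


class TestGlottalFlow:
    def test_closed_glottis_carries_no_flow(self):
        p = VFModelParams()
        flow, pressure = glottal_flow(np.zeros((5, 3)), p)
        assert flow == 0.0

    def test_bernoulli_value(self):
        """a_min = 1e-5 m^2 at 4 kPa and 1.14 kg/m^3 -> 8.38e-4 m^3/s."""
        p = VFModelParams(lung_pressure=4e3, air_density=1.14)
        area = np.full((5, 3), 1e-5 / 5.0)  # uniform -> a_min = 1e-5
        flow, _ = glottal_flow(area, p)
        expect = 1e-5 * math.sqrt(2 * 4e3 / 1.14)
        assert flow == pytest.approx(expect, rel=1e-12)
        assert flow == pytest.approx(8.38e-4, rel=1e-3)

    def test_pressure_distribution_follows_separation(self):
        p = VFModelParams(lung_pressure=4e3)
        # convergent: wide at the bottom level, narrow at the top
        area = np.tile(np.array([3e-6, 2e-6, 1e-6]), (5, 1))
        _, pressure = glottal_flow(area, p)
        # upstream of the minimal (top) level: graded Bernoulli pressure
        assert np.all(pressure[:, 0] > pressure[:, 1])
        assert np.all(pressure[:, 1] > 0)
        assert np.all(pressure[:, 2] == 0.0)  # at the separation level
        # divergent: minimum at the entry -> no driving pressure anywhere
        _, pressure = glottal_flow(area[:, ::-1], p)
        assert np.all(pressure == 0.0)

    def test_closed_segment_carries_lung_pressure_below_closure(self):
        p = VFModelParams(lung_pressure=4e3)
        area = np.tile(np.array([2e-6, 0.0, 2e-6]), (5, 1))
        flow, pressure = glottal_flow(area, p)
        assert flow == 0.0
        assert np.all(pressure[:, 0] == 4e3)
        assert np.all(pressure[:, 1:] == 0.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            glottal_flow(np.full((5, 3), -1.0), VFModelParams())


class TestSimulate:
    def test_no_lung_pressure_no_self_oscillation(self):
        """Without the aerodynamic energy source a perturbed fold decays
        back to rest: the run reports no sustained oscillation."""
        p = VFModelParams(lung_pressure=0.0, duration=0.03,
                          transient_discard=0.015, dt=5e-6, tract="none")
        out = simulate(p, seed_amplitude=1e-4)
        assert not out.sustained
        assert out.f_o is None

    def test_outputs_are_nonnegative(self):
        p = VFModelParams(duration=0.02, transient_discard=0.01, dt=5e-6)
        out = simulate(p)
        assert np.all(out.glottal_area >= 0.0)
        assert np.all(out.glottal_flow >= 0.0)

    def test_duration_must_exceed_transient(self):
        with pytest.raises(ValueError):
            simulate(VFModelParams(duration=0.05, transient_discard=0.1))


class TestFlowSpectrum:
    FS = 50000.0

    def test_pure_sinusoid_has_no_second_harmonic(self):
        t = np.arange(int(0.2 * self.FS)) / self.FS
        flow = 2.0 + np.sin(2 * np.pi * 1000.0 * t)
        _, _, h1, h2 = flow_spectrum(flow, self.FS, f_o=1000.0)
        assert h1 == pytest.approx(0.0, abs=0.01)
        assert h2 <= -60.0

    def test_half_rectified_sine_against_fourier_oracle(self):
        """The H1-H2 of max(0, sin) is fixed by its analytic Fourier
        series; an independent numerical projection provides the oracle."""
        f0 = 1000.0
        t = np.arange(int(0.5 * self.FS)) / self.FS
        flow = np.maximum(0.0, np.sin(2 * np.pi * f0 * t))
        # oracle: direct Fourier coefficients over an integer cycle count
        n = int(round(0.4 * self.FS))
        tt = t[:n]
        a1 = 2 * abs(np.mean(flow[:n] * np.exp(-2j * np.pi * f0 * tt)))
        a2 = 2 * abs(np.mean(flow[:n] * np.exp(-2j * np.pi * 2 * f0 * tt)))
        oracle_db = 20 * np.log10(a1 / a2)
        # analytic check of the oracle itself: 1/2 vs 2/(3 pi)
        assert oracle_db == pytest.approx(
            20 * np.log10(0.5 / (2 / (3 * np.pi))), abs=0.05)
        _, _, h1, h2 = flow_spectrum(flow, self.FS, f_o=f0)
        assert h1 - h2 == pytest.approx(oracle_db, abs=0.1)

    def test_spectrum_normalized_to_strongest_harmonic(self):
        t = np.arange(int(0.2 * self.FS)) / self.FS
        flow = np.maximum(0.0, np.sin(2 * np.pi * 1200.0 * t))
        freqs, db, h1, h2 = flow_spectrum(flow, self.FS, f_o=1200.0)
        assert db.max() == pytest.approx(0.0, abs=1e-9)
        assert h1 == pytest.approx(0.0, abs=0.05)

    def test_too_short_segment_rejected(self):
        t = np.arange(200) / self.FS
        with pytest.raises(ValueError, match="cycles"):
            flow_spectrum(np.sin(2 * np.pi * 1000 * t), self.FS, f_o=1000.0)
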