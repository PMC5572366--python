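"""Memristor emulator: memductance, scaling, loops, fingerprints."""

import mpmath as mp
import numpy as np
import pytest

from memhnn import (CircuitValues, DriveSignal, MemristorParams,
                    circuit_values_for, lobe_area, memductance, simulate_loop,
                    to_dimensionless)


class TestMemductance:
    @pytest.mark.parametrize("v0, a, b, expected", [
        (0.0, 1.0, 0.5, 1.0),                       # tanh(0) = 0
        (50.0, 1.0, 0.5, 0.5),                      # saturated: a - b
        (-50.0, 1.0, 0.5, 1.5),                     # saturated: a + b
    ])
    def test_limits(self, v0, a, b, expected):
        assert memductance(v0, MemristorParams(a=a, b=b)) == pytest.approx(
            expected, abs=1e-12)

    def test_against_arbitrary_precision_tanh(self):
        p = MemristorParams(a=1.0, b=0.5)
        for v0 in [-2.3, -1.0, 0.3, 1.0, 4.2]:
            expected = float(1 - mp.mpf("0.5") * mp.tanh(mp.mpf(repr(v0))))
            assert memductance(v0, p) == pytest.approx(expected, abs=1e-14)

    def test_bounded_in_open_interval(self):
        p = MemristorParams(a=1.0, b=0.5)
        v0 = np.linspace(-15, 15, 1001)
        w = memductance(v0, p)
        assert np.all(w > p.a - p.b) and np.all(w < p.a + p.b)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MemristorParams(a=0.0, b=0.5)
        with pytest.raises(ValueError):
            MemristorParams(a=1.0, b=-0.1)
        with pytest.raises(ValueError):
            MemristorParams(a=1.0, b=0.5, tau=0.0)


class TestScaling:
    def test_reference_design_scales_to_a1_b05(self, table1_circuit):
        p = to_dimensionless(table1_circuit)
        assert p.a == pytest.approx(1.0, abs=1e-15)
        assert p.b == pytest.approx(0.5, abs=1e-15)
        assert p.tau == pytest.approx(1e-3, rel=1e-12)

    def test_zero_gain_gives_b0(self):
        p = to_dimensionless(CircuitValues(R=10e3, Ra=10e3, Rb=2e3, g=0.0))
        assert (p.a, p.b) == (1.0, 0.0)

    def test_rb_scaling(self):
        p = to_dimensionless(CircuitValues(R=10e3, Ra=10e3, Rb=5e3, g=0.1))
        assert p.b == pytest.approx(0.2, abs=1e-15)

    def test_rejects_nonpositive_components(self):
        for field in ("R", "C", "Ra", "Rb"):
            with pytest.raises(ValueError):
                CircuitValues(**{field: -1.0})

    def test_resistances_for_target_coupling(self):
        Ra, _ = circuit_values_for(k=0.95, a=1.0, b=0.5)
        assert round(Ra / 1e3, 2) == 10.53
        Ra, _ = circuit_values_for(k=1.0, a=1.0, b=0.5)
        assert Ra == pytest.approx(10e3, rel=1e-12)
        _, Rb = circuit_values_for(k=0.8, a=1.0, b=0.5, R=10e3, g=0.1)
        assert Rb == pytest.approx(2.5e3, rel=1e-12)

    def test_rb_undefined_at_b0(self):
        with pytest.raises(ValueError):
            circuit_values_for(k=0.8, a=1.0, b=0.0)


class TestLoopSimulation:
    def test_port_current_is_memductance_times_voltage(self, table1_circuit,
                                                       drive_4v_400hz):
        loop = simulate_loop(table1_circuit, drive_4v_400hz, n_cycles=2,
                             samples_per_cycle=64)
        cv = table1_circuit
        w = 1.0 / cv.Ra - (cv.g / cv.Rb) * np.tanh(loop.v0)
        np.testing.assert_allclose(loop.i, w * loop.v, rtol=0, atol=1e-18)

    def test_loop_pinched_at_origin(self, table1_circuit, drive_4v_400hz):
        # |i| <= (a+b)/Ra-scale * |v| everywhere, so i -> 0 with v
        loop = simulate_loop(table1_circuit, drive_4v_400hz, n_cycles=2,
                             samples_per_cycle=128)
        p = to_dimensionless(table1_circuit)
        bound = (p.a + p.b) / table1_circuit.R
        assert np.all(np.abs(loop.i) <= bound * np.abs(loop.v) + 1e-18)
        zero_v = np.isclose(loop.v, 0.0, atol=1e-12)
        assert np.all(np.abs(loop.i[zero_v]) < 1e-12)

    def test_steady_state_matches_linear_filter_response(self, table1_circuit,
                                                         drive_4v_400hz):
        """The inner state obeys tau*v0' = -(v0 + v): closed-form sinusoid."""
        # 5 recorded cycles put the final cycle ~20 tau past t=0, so the
        # e^(-t/tau) start-up residual is ~1e-9 of the amplitude
        loop = simulate_loop(table1_circuit, drive_4v_400hz, n_cycles=5,
                             samples_per_cycle=256)
        p = to_dimensionless(table1_circuit)
        cyc = loop.steady_cycle
        om = 2 * np.pi * drive_4v_400hz.f
        amp = drive_4v_400hz.Vm / np.hypot(1.0, om * p.tau)
        expected = -amp * np.sin(om * cyc.t - np.arctan(om * p.tau))
        np.testing.assert_allclose(cyc.v0, expected, rtol=0,
                                   atol=1e-6 * amp)

    def test_normalized_inner_state_independent_of_amplitude(self,
                                                             table1_circuit):
        """Linearity: v0/Vm waveform identical across drive amplitudes."""
        waves = []
        for Vm in (2.0, 3.0, 4.0):
            loop = simulate_loop(table1_circuit, DriveSignal(Vm=Vm, f=400.0),
                                 n_cycles=2, samples_per_cycle=128,
                                 rtol=1e-11, atol=1e-14)
            waves.append(loop.steady_cycle.v0 / Vm)
        np.testing.assert_allclose(waves[0], waves[1], rtol=0, atol=1e-9)
        np.testing.assert_allclose(waves[0], waves[2], rtol=0, atol=1e-9)

    def test_input_validation(self, table1_circuit, drive_4v_400hz):
        with pytest.raises(ValueError):
            simulate_loop(table1_circuit, drive_4v_400hz, n_cycles=1)
        with pytest.raises(ValueError):
            simulate_loop(table1_circuit, drive_4v_400hz,
                          samples_per_cycle=8)

    def test_dimensionless_form(self):
        p = MemristorParams(a=1.0, b=0.5, tau=1.0)
        loop = simulate_loop(p, DriveSignal(Vm=1.0, f=0.5), n_cycles=2,
                             samples_per_cycle=64)
        np.testing.assert_allclose(loop.i, memductance(loop.v0, p) * loop.v,
                                   rtol=0, atol=1e-18)


class TestLobeArea:
    def test_constant_memductance_gives_zero_area(self):
        cv = CircuitValues(g=0.0)  # b = 0: straight line through origin
        loop = simulate_loop(cv, DriveSignal(Vm=4.0, f=400.0), n_cycles=2,
                             samples_per_cycle=256)
        pos, neg = lobe_area(loop)
        assert pos < 1e-12 and neg < 1e-12

    def test_lobe_area_decreases_with_frequency(self, table1_circuit):
        areas = []
        for f in (400.0, 1000.0, 2000.0):
            loop = simulate_loop(table1_circuit, DriveSignal(Vm=4.0, f=f),
                                 n_cycles=2, samples_per_cycle=512)
            areas.append(lobe_area(loop))
        pos = [a[0] for a in areas]
        neg = [a[1] for a in areas]
        assert pos[0] > pos[1] > pos[2] > 0
        assert neg[0] > neg[1] > neg[2] > 0

    def test_area_converged_in_sampling_density(self, table1_circuit,
                                                drive_4v_400hz):
        coarse = lobe_area(simulate_loop(table1_circuit, drive_4v_400hz,
                                         n_cycles=2, samples_per_cycle=256))
        fine = lobe_area(simulate_loop(table1_circuit, drive_4v_400hz,
                                       n_cycles=2, samples_per_cycle=4096))
        for c, f in zip(coarse, fine):
            assert abs(c - f) / f < 0.01
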