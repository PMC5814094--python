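"""Voltage-gated channel gating, currents, influx generation."""

import math

import numpy as np
import pytest

from holosim.channels import (ChannelBank, CurrentParams, GatingParams,
                              InfluxTrace, VoltageTrace, fit_channel_number,
                              gate_step, generate_influx,
                              generate_influx_ensemble, generate_voltage_trace,
                              ghk_current, ions_per_step, n_inf,
                              single_channel_current, tau_n)
from holosim.units import ELEMENTARY_CHARGE, FARADAY


class TestGatingFunctions:
    def test_half_activation(self):
        assert n_inf(-15.0) == pytest.approx(0.5)

    def test_ninf_one_slope_above_half(self):
        # V = V_half + slope -> 1/(1+e^-1)
        assert n_inf(-7.0) == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))

    def test_tau_at_half_activation(self):
        # both exponentials equal 1: 0.06 + 0.7425/2
        assert tau_n(-15.0) == pytest.approx(0.43125)

    def test_gate_step_zero_dt_no_transitions(self, rng):
        state = np.array([True, False, True])
        out = gate_step(state, -15.0, 0.0, rng)
        assert (out == state).all()

    @pytest.mark.parametrize("V", [-40.0, -25.0, -15.0, -5.0, 10.0])
    def test_stationary_open_fraction_tracks_ninf(self, V, rng):
        """Long voltage-clamp open fraction equals n_inf(V) within binomial
        error (small dt so the discrete chain matches the continuous one)."""
        dt_ms = 0.01
        n_ch, n_steps = 256, 6000
        state = rng.random(n_ch) < n_inf(V)
        total = 0
        count = 0
        for i in range(n_steps):
            state = gate_step(state, V, dt_ms, rng)
            if i >= 1000:
                total += state.sum()
                count += n_ch
        frac = total / count
        # effective sample size: n_ch independent chains, correlation time
        # tau_n / dt steps
        n_eff = n_ch * (n_steps - 1000) * dt_ms / float(tau_n(V)) / 2.0
        se = math.sqrt(float(n_inf(V)) * (1 - float(n_inf(V))) / n_eff)
        assert frac == pytest.approx(float(n_inf(V)), abs=4 * se + 1e-3)


class TestCurrents:
    def test_single_channel_limit_at_offset(self):
        # removable singularity: i(V_s) = -g * RT/zF = -0.06 pA
        assert single_channel_current(-1.91, V_s=-1.91) == pytest.approx(-0.06)

    def test_current_vanishes_at_large_depolarization(self):
        assert abs(single_channel_current(500.0)) < 1e-6

    def test_current_is_inward_over_physiological_range(self):
        V = np.arange(-80.0, 60.0, 1.0)
        assert (np.asarray(single_channel_current(V)) < 0).all()

    def test_ghk_zero_voltage_limit(self):
        p = CurrentParams()
        expected_density = (p.P_cm_s * p.z * FARADAY
                            * (p.Ca_in_nM * 1e-12 - p.Ca_out_mM * 1e-6))
        expected_pA = expected_density * p.area_um2 * 1e-8 * 1e12
        assert ghk_current(0.0) == pytest.approx(expected_pA, rel=1e-9)

    def test_fit_channel_number_defaults(self):
        n, v_s = fit_channel_number()
        assert n == 16

    def test_fit_scales_linearly_with_permeability(self):
        p2 = CurrentParams(P_cm_s=2 * CurrentParams().P_cm_s)
        n1, v1 = fit_channel_number()
        n2, v2 = fit_channel_number(p2)
        assert n2 == pytest.approx(2 * n1, abs=1)
        assert v2 == pytest.approx(v1, abs=0.05)


class TestInflux:
    def test_zero_current_zero_ions(self):
        assert ions_per_step(0.0, 1e-3) == 0

    def test_expected_ion_count(self, rng):
        # |i| = 0.06 pA over 1 ms -> 0.06e-12 * 1e-3 / (2e) ~ 187.3 ions
        mean = 0.06e-12 * 1e-3 / (2 * ELEMENTARY_CHARGE)
        draws = [ions_per_step(-0.06, 1e-3, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(mean, rel=0.005)
        assert set(draws) <= {math.floor(mean), math.floor(mean) + 1}

    def test_voltage_trace_burst_structure(self):
        tr = generate_voltage_trace(burst_interval_hz=5.0)
        # 25 spikes grouped 5 x 5: count threshold crossings at -20 mV
        above = tr.V_mV > -20.0
        onsets = np.sum(above[1:] & ~above[:-1])
        assert onsets == 25
        assert tr.V_mV.min() == pytest.approx(-65.0)

    def test_zero_amplitude_spikes_give_baseline_influx_only(self):
        tr = generate_voltage_trace(spike_amplitude_scale=0.0, tail_ms=50.0)
        flux = generate_influx(tr, ChannelBank(n_channels=16), seed=3)
        rest = generate_voltage_trace(tail_ms=50.0)
        rest_flux = generate_influx(
            VoltageTrace(tr.times_ms, np.full_like(tr.V_mV, -65.0)),
            ChannelBank(n_channels=16), seed=3)
        assert flux.total == rest_flux.total  # identical draws, resting V

    def test_influx_total_is_sum_of_steps(self):
        tr = generate_voltage_trace(tail_ms=20.0)
        flux = generate_influx(tr, ChannelBank(n_channels=4), seed=0)
        assert flux.total == int(flux.ions.sum())

    def test_ensemble_pair_totals_match(self):
        tr5 = generate_voltage_trace(5.0, n_bursts=2, tail_ms=50.0)
        tr10 = generate_voltage_trace(10.0, n_bursts=2, tail_ms=50.0)
        a, b = generate_influx_ensemble(tr5, tr10, ChannelBank(n_channels=16),
                                        n_trials=8, seed=2)
        assert abs(a.total - b.total) < 0.02 * max(a.total, b.total)

    def test_trace_text_roundtrip(self):
        tr = generate_voltage_trace(tail_ms=5.0)
        again = VoltageTrace.from_text(tr.to_text())
        assert np.allclose(again.V_mV, tr.V_mV, atol=1e-5)
        flux = InfluxTrace(tr.times_ms, np.zeros(tr.times_ms.size, dtype=int),
                           {"seed": 1})
        again = InfluxTrace.from_text(flux.to_text())
        assert again.total == 0 and again.meta["seed"] == "1"
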