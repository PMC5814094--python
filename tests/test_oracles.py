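"""Reference computations: ODE, SSA, exact ring chain, regime classifier."""

import math

import numpy as np
import pytest

from holosim.models import model1_wellmixed, reduced_wellmixed
from holosim.oracles import (Reaction, WellMixedModel, ode_trajectories,
                             regime_classify, ring_phospho_sampled_fraction,
                             ring_phospho_steady_fraction, ssa_trajectories)


def _ab_model():
    m = WellMixedModel(["A", "B"], [], 1.0)
    m.reactions = [Reaction("decay", (0,), (1,), 1.0)]
    return m


class TestODE:
    def test_zero_rates_constant_trajectories(self):
        m = WellMixedModel(["A", "B"], [Reaction("x", (0,), (1,), 0.0)], 1.0)
        traj = ode_trajectories(m, [10, 5], np.linspace(0, 1, 5))
        assert np.allclose(traj, [[10, 5]] * 5)

    def test_model1_conserves_moieties(self, rates):
        m, sp = model1_wellmixed(rates, 0.125)
        y0 = np.zeros(len(sp))
        y0[0], y0[1] = 3000, 700
        t = np.linspace(0, 0.2, 50)
        traj = ode_trajectories(m, y0, t)
        cam_total = traj[:, 1:].sum(axis=1)
        ca_bound = sum(
            (int(s[1]) + int(s[3])) * traj[:, i]
            for i, s in enumerate(sp) if s != "ca")
        assert np.allclose(cam_total, 700, rtol=1e-8)
        assert np.allclose(traj[:, 0] + ca_bound, 3000, rtol=1e-8)

    def test_model1_equilibrium_detailed_balance(self, rates):
        """At t -> inf every reversible pair's flux ratio equals K_eq."""
        m, sp = model1_wellmixed(rates, 0.125)
        y0 = np.zeros(len(sp))
        y0[0], y0[1] = 3000, 700
        traj = ode_trajectories(m, y0, np.linspace(0, 50.0, 11))
        y = traj[-1]
        by_name = {r.name: r for r in m.reactions}
        for name, rxn in by_name.items():
            if not name.endswith("+"):
                continue
            back = by_name[name.replace("+", "-")]
            fwd_flux = rxn.rate * y[rxn.reactants[0]] * y[rxn.reactants[1]]
            back_flux = back.rate * y[back.reactants[0]]
            assert fwd_flux == pytest.approx(back_flux, rel=1e-5)

    def test_species_guard(self):
        with pytest.raises(ValueError, match="refusing"):
            WellMixedModel([f"s{i}" for i in range(10_001)], [], 1.0)


class TestSSA:
    def test_zero_propensity_no_events(self):
        m = WellMixedModel(["A"], [Reaction("x", (0,), (0,), 0.0)], 1.0)
        out = ssa_trajectories(m, [5], 1.0, seed=0)
        assert (out == 5).all()

    def test_first_order_decay_closed_form(self):
        """Mean B(t) over replicates matches 1000 (1 - e^-t) within 3 se."""
        m = _ab_model()
        t_grid = np.array([0.0, 0.5, 1.0, 2.0])
        runs = np.stack([
            ssa_trajectories(m, [1000, 0], 2.0, seed=s, record_times=t_grid)
            for s in range(60)])
        mean_b = runs[:, :, 1].mean(axis=0)
        expected = 1000 * (1 - np.exp(-t_grid))
        se = runs[:, :, 1].std(axis=0, ddof=1) / math.sqrt(60)
        assert np.all(np.abs(mean_b - expected) <= 3 * se + 1e-9)

    def test_injections_are_applied(self):
        m = WellMixedModel(["A"], [Reaction("x", (0,), (0,), 0.0)], 1.0)
        out = ssa_trajectories(m, [0], 1.0, seed=0,
                               record_times=[0.0, 0.4, 0.9],
                               injections=[(0.5, 0, 7)])
        assert list(out[:, 0]) == [0, 0, 7]

    def test_paths_converge_to_ode_with_system_size(self, rates):
        """Per-trajectory relative fluctuation around the mass-action ODE
        shrinks as counts grow (law-of-large-numbers scaling ~ 1/sqrt(n0)),
        and the replicate mean stays consistent with the ODE."""
        rel_fluct = []
        for n0 in (100, 1000):
            # scale volume with counts: fixed concentrations, growing system
            m, sp = reduced_wellmixed(0.2 * n0 / 602.0)
            i = m.index
            y0 = np.zeros(len(sp))
            y0[i["N0C0"]] = n0
            y0[i["ca"]] = 2 * n0
            y0[i["K"]] = n0
            t = np.array([0.0, 0.05])
            ode = ode_trajectories(m, y0, t)[-1]
            runs = np.stack([ssa_trajectories(m, y0, 0.05, seed=s,
                                              record_times=t)[-1]
                             for s in range(15)])
            rel_fluct.append(
                np.sqrt(((runs - ode) ** 2).sum(axis=1)).mean() / n0)
            se = runs.std(axis=0, ddof=1) / math.sqrt(15)
            assert np.all(np.abs(runs.mean(axis=0) - ode) <= 4 * se + 1.0)
        assert rel_fluct[1] < 0.5 * rel_fluct[0]


class TestRingChain:
    def test_closed_form_small_rings(self):
        assert ring_phospho_steady_fraction(2) == pytest.approx(0.5)
        assert ring_phospho_steady_fraction(3) == pytest.approx(2.0 / 3.0)

    def test_limit_approaches_one_minus_inv_e(self):
        f64 = ring_phospho_sampled_fraction(64, n_rings=1500, seed=3)
        assert f64 == pytest.approx(1 - math.exp(-1), abs=0.01)

    def test_bounded_and_locally_monotone(self):
        f = [ring_phospho_steady_fraction(n) for n in range(2, 13)]
        assert f[0] < f[1]  # 1/2 < 2/3
        assert all(0.5 <= v <= 2.0 / 3.0 + 1e-12 for v in f)
        # convergence: later values hug the 1 - 1/e limit
        assert abs(f[-1] - (1 - math.exp(-1))) < 1e-3

    def test_guards(self):
        with pytest.raises(ValueError):
            ring_phospho_steady_fraction(1)
        with pytest.raises(ValueError):
            ring_phospho_steady_fraction(17)


class TestRegime:
    def test_infinite_encounter_rate_limit(self):
        rep = regime_classify(10.0, 1e9, sigma_enc_nm=5.0)
        assert rep.k_a == pytest.approx(10.0, rel=1e-3)

    def test_decomposition_arithmetic(self):
        # 1/k_a = 1/k_on - 1/k_enc with k_on=10, k_enc=1000 -> 10.101
        D = 1000.0 / (4 * math.pi * 5e-3 * 602.0)
        rep = regime_classify(10.0, D, sigma_enc_nm=5.0)
        assert rep.k_enc == pytest.approx(1000.0, rel=1e-9)
        assert rep.k_a == pytest.approx(10.101, rel=1e-3)
        assert rep.classification == "activation-limited"

    def test_diffusion_limited_flag(self):
        rep = regime_classify(1e6, 1.0, sigma_enc_nm=1.0)
        assert rep.classification == "diffusion-limited"
        assert math.isinf(rep.k_a)

    def test_model1_reactions_activation_limited(self, rates):
        """Every Ca2+-CaM step is activation-limited with the default
        diffusion constants, and stays so at half diffusion."""
        for factor in (1.0, 0.5):
            D_mut = (rates.D_ca * factor + rates.D_cam) * 1e8
            for step in ("C1", "C2", "N1", "N2"):
                kon, _ = rates.step_rates(step, "free")
                rep = regime_classify(kon, D_mut, sigma_enc_nm=5.0)
                assert rep.classification == "activation-limited"
                assert rep.ratio < 1.1
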