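"""Brownian dynamics, boundaries, reaction execution, conservation."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import kstest

from holosim.engine import (AbsorbingFace, Geometry, ModelDefinition,
                            SimConfig, Simulation, StepSizeWarning)
from holosim.rules import MoleculeType, SiteType, build_table, parse_rules
from holosim.units import kon_to_volume_rate


def _two_species(d_a=1e-6, d_b=1e-6, kf=20.0, kb=0.0):
    A = MoleculeType("A", (SiteType("a", "binding"),), diffusion_cm2_s=d_a)
    B = MoleculeType("B", (SiteType("b", "binding"),), diffusion_cm2_s=d_b)
    mols = {"A": A, "B": B}
    rules = parse_rules(
        f"A{{a==0}} + B{{b==0}} <-> A~B{{A.a=1, B.b=1}} kf={kf} kb={kb} "
        "label=bind", mols)
    return mols, build_table(rules, mols)


def _sim(mols, table, counts, dims, dt, t_end, seed=0, faces=None, **kw):
    model = ModelDefinition(molecules=mols, table=table, initial_counts=counts,
                            observables=[("A_free", "A", [("a", 0)])])
    geo = Geometry(dims, faces or {})
    cfg = SimConfig(dt=dt, t_end=t_end, record_interval=max(dt, t_end / 50),
                    seed=seed, **kw)
    return Simulation(model, geo, cfg)


class TestDiffusion:
    def test_immobile_species_never_move(self):
        mols, table = _two_species(d_a=0.0, kf=0.0)
        mols["A"] = MoleculeType("A", mols["A"].sites, 0.0, mobile=False)
        sim = _sim(mols, table, {"A": 50, "B": 0}, (1, 1, 1), 1e-5, 1e-3)
        before = sim.pos[sim.type_slice["A"]].copy()
        sim.run()
        assert np.array_equal(before, sim.pos[sim.type_slice["A"]])

    def test_einstein_relation_msd(self):
        """Mean squared displacement of free particles is 6 D t within
        sampling error (periodic box avoids wall truncation)."""
        D_um2 = 100.0  # 1e-6 cm^2/s * 1e8
        mols, table = _two_species(d_a=1e-6, kf=0.0)
        faces = {f"{ax}{s}": "periodic" for ax in "xyz" for s in "+-"}
        sim = _sim(mols, table, {"A": 10_000, "B": 0}, (5, 5, 5), 1e-5, 1e-5,
                   faces=faces)
        sl = sim.type_slice["A"]
        start = sim.pos[sl].copy()
        t = 2e-4
        # accumulate displacement without wrapping artifacts by summing steps
        disp = np.zeros_like(start)
        prev = start.copy()
        for _ in range(20):
            sim.step()
            cur = sim.pos[sl]
            step_vec = cur - prev
            step_vec -= 5.0 * np.round(step_vec / 5.0)  # unwrap
            disp += step_vec
            prev = cur.copy()
        msd = (disp ** 2).sum(axis=1).mean()
        expected = 6.0 * D_um2 * t
        se = (disp ** 2).sum(axis=1).std() / math.sqrt(10_000)
        assert msd == pytest.approx(expected, abs=4 * se)

    def test_bound_pair_moves_with_slower_partner(self):
        """After binding, both particles share the cluster position and the
        cluster moves with the smaller diffusion coefficient."""
        mols, table = _two_species(d_a=1e-6, d_b=1e-8, kf=50.0)
        sim = _sim(mols, table, {"A": 200, "B": 200}, (0.5, 0.5, 0.5),
                   1e-6, 0.0)
        sim.run(t_end=2e-3)
        bonded = np.nonzero(sim.bond_partner[sim.type_slice["A"], 0] >= 0)[0]
        assert bonded.size > 5
        ia = bonded[0] + sim.type_slice["A"].start
        ib = int(sim.bond_partner[ia, 0])
        assert np.allclose(sim.pos[ia], sim.pos[ib])
        assert sim.root[ia] == sim.root[ib]
        root = int(sim.root[ia])
        assert sim.root_D[root] == pytest.approx(1.0)  # 1e-8 cm2/s = 1 um2/s


class TestBoundaries:
    def test_reflection_conserves_counts(self):
        mols, table = _two_species(kf=0.0)
        sim = _sim(mols, table, {"A": 500, "B": 0}, (0.2, 0.2, 0.2), 1e-5, 2e-3)
        sim.run()
        assert sim.count("A") == 500
        assert (sim.pos[sim.alive] >= 0).all()
        assert (sim.pos[sim.alive] <= 0.2 + 1e-12).all()

    def test_zero_absorption_is_pure_reflection(self):
        mols, table = _two_species(kf=0.0)
        faces = {"z-": AbsorbingFace(frozenset({"A"}), 0.0)}
        sim = _sim(mols, table, {"A": 500, "B": 0}, (0.2, 0.2, 0.2), 1e-5,
                   2e-3, faces=faces)
        sim.run()
        assert sim.count("A") == 500

    def test_partial_absorption_removes_only_listed_species(self):
        mols, table = _two_species(kf=0.0)
        faces = {"z-": AbsorbingFace(frozenset({"A"}), 0.5)}
        sim = _sim(mols, table, {"A": 400, "B": 400}, (0.2, 0.2, 0.2), 1e-5,
                   2e-3, faces=faces)
        sim.run()
        assert sim.count("B") == 400
        assert sim.count("A") < 400
        assert sim.count("A") + sim.absorbed_counts.get("A", 0) == 400

    def test_periodic_wraps_into_box(self):
        mols, table = _two_species(kf=0.0)
        faces = {f"{ax}{s}": "periodic" for ax in "xyz" for s in "+-"}
        sim = _sim(mols, table, {"A": 300, "B": 0}, (0.2, 0.2, 0.2), 1e-5,
                   1e-3, faces=faces)
        sim.run()
        assert (sim.pos[sim.alive] >= 0).all()
        assert (sim.pos[sim.alive] <= 0.2).all()

    def test_mismatched_periodic_faces_rejected(self):
        with pytest.raises(ValueError, match="periodic"):
            Geometry((1, 1, 1), {"x-": "periodic"})


class TestReactions:
    def test_mass_action_contract(self):
        """A well-mixed irreversible A+B run reproduces the requested k_on
        within the calibration contract (plus Monte-Carlo error)."""
        kon = 20.0
        mols, table = _two_species(kf=kon)
        faces = {f"{ax}{s}": "periodic" for ax in "xyz" for s in "+-"}
        L = 20.0 ** (1 / 3)
        n0, T = 4000, 0.1
        ratios = []
        for seed in (0, 1):
            sim = _sim(mols, table, {"A": n0, "B": n0}, (L, L, L), 1e-4, T,
                       seed=seed, faces=faces)
            sim.run()
            nT = sim.count("A", [("a", 0)])
            k_hat = (1.0 / nT - 1.0 / n0) / T
            ratios.append(k_hat / (kon_to_volume_rate(kon) / 20.0))
        # ~2200 events per seed -> MC se ~ 1.5% pooled
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02 + 3 * 0.015)

    def test_unbinding_survival_times_are_exponential(self):
        """Bond lifetimes follow Exp(k_off) (KS test on ~10^4 events)."""
        k_off = 200.0
        mols, table = _two_species(kf=500.0, kb=k_off)
        sim = _sim(mols, table, {"A": 3000, "B": 3000}, (1.0, 1.0, 1.0),
                   1e-5, 0.0, seed=7)
        sim.run(t_end=0.05)
        # only bonds born well before the end of the run: right-censoring
        # (pairs still bound at t_end) would otherwise bias lifetimes short
        birth_cut = 0.02
        births = {}
        lifetimes = []
        for e in sim.events:
            if e.direction > 0:
                if e.time <= birth_cut:
                    births[(e.i, e.j)] = e.time
                else:
                    births.pop((e.i, e.j), None)
            else:
                key = (e.i, e.j)
                if key in births:
                    lifetimes.append(e.time - births.pop(key))
        assert len(lifetimes) > 8000
        # discrete-step correction: lifetimes are multiples of dt
        stat, p = kstest(np.array(lifetimes) - 0.5e-5, "expon",
                         args=(0, 1.0 / k_off))
        assert p > 0.01

    def test_no_reaction_when_rates_zero(self):
        mols, table = _two_species(kf=0.0, kb=0.0)
        sim = _sim(mols, table, {"A": 200, "B": 200}, (0.3, 0.3, 0.3),
                   1e-5, 1e-3)
        sim.run()
        assert not sim.events

    def test_determinism_same_seed_same_events(self):
        mols, table = _two_species(kf=50.0, kb=10.0)
        logs = []
        for _ in range(2):
            sim = _sim(mols, table, {"A": 300, "B": 300}, (0.4, 0.4, 0.4),
                       1e-5, 5e-3, seed=42)
            sim.run()
            logs.append([(e.time, e.label, e.direction, e.i, e.j)
                         for e in sim.events])
        assert logs[0] == logs[1]

    def test_debug_consistency_checks_pass(self):
        mols, table = _two_species(kf=100.0, kb=50.0)
        sim = _sim(mols, table, {"A": 150, "B": 150}, (0.3, 0.3, 0.3),
                   1e-5, 2e-3, debug_checks=True)
        sim.run()  # raises AssertionError on any bond/state inconsistency
        sim.check_consistency()


class TestStepSizeGuard:
    def test_coarse_dt_warns(self):
        mols, table = _two_species(kf=1.0, kb=5000.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            _sim(mols, table, {"A": 10, "B": 10}, (1, 1, 1), 1e-4, 1e-3)
        assert any(issubclass(w.category, StepSizeWarning) for w in rec)

    def test_strict_mode_raises(self):
        mols, table = _two_species(kf=1.0, kb=5000.0)
        with pytest.raises(ValueError, match="coarse time step"):
            _sim(mols, table, {"A": 10, "B": 10}, (1, 1, 1), 1e-4, 1e-3,
                 strict=True)
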