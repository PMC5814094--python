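"""Ready-to-run model presets of the Ca2+/CaM/CaMKII family.

Every preset is a fully specified, runnable configuration: molecule
declarations, a rule file (generated from the shared :class:`RateSet` and
parsed through the rule dialect), geometry with boundary semantics, initial
counts, and the stimulus.  Desk-scale variants (volume and counts shrunk at
fixed concentrations, shorter horizons) are first-class presets so the whole
family can be exercised in minutes on one CPU.

Presets
-------
model1_ca_cam
    The 9-state Ca2+-CaM network in a 500 nm reflective cube (3000 Ca2+,
    700 apoCaM = 39.867 and 9.302 uM); the activation-limited test model
    whose trajectories are compared against the mass-action ODE oracle.
model2_ml_test
    Closed 1 um^3 box of CaM-saturated ring holoenzymes with the
    no-phospho-kinase rule; steady-state phosphorylated fractions follow the
    closed-form ring values (1/2 dimers, 2/3 trimers, -> 1 - 1/e).
model3_closed_network
    Closed full-kinetics network with monomeric CaMKII, cross-checked
    against the well-mixed SSA.
prototype_full / scheme1 / scheme2 / radius_sweep
    The 1 x 1 x 2 um cytosol slab: 5 uM CaM, 10 uM immobilized CaMKII
    subunits in 6-rings, channel-driven Ca2+ influx through the top-face
    point source, partially absorbing bottom.
reduced_fig13
    The minimal chain N0C0 -> N0C1 -> N0C2 -> N1C2 -> CaMKII binding ->
    phosphorylation (1 s^-1), monomeric CaMKII, 5 instantaneous Ca2+ pulses
    at 5 or 10 Hz; the preset that reproduces the frequency-preference
    crossover as total influx grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelBank, InfluxTrace, generate_influx, generate_voltage_trace
from .engine import (AbsorbingFace, Geometry, KinaseSpec, ModelDefinition,
                     SimConfig, Simulation)
from .rates import CAM_STATES, RateSet, default_rates
from .ring import KinaseRuleVariant, RingTemplate
from .rules import MoleculeType, SiteType, build_table, parse_rules
from .units import concentration_to_count, count_to_concentration

__all__ = [
    "Preset",
    "build_preset",
    "PRESET_NAMES",
    "molecule_declarations",
    "model1_rule_text",
    "full_network_rule_text",
    "reduced_rule_text",
    "cam_vertex_namer",
    "cam_state_observables",
    "equilibrate",
    "model1_wellmixed",
    "reduced_wellmixed",
    "full_monomer_wellmixed",
    "count_to_concentration",
    "concentration_to_count",
]

PRESET_NAMES = [
    "model1_ca_cam", "model2_ml_test", "model3_closed_network",
    "prototype_full", "reduced_fig13", "scheme1", "scheme2", "radius_sweep",
]


def molecule_declarations(rs: RateSet) -> dict:
    """The three molecule types of the network."""
    ca = MoleculeType("ca", (SiteType("b", "binding"),),
                      diffusion_cm2_s=rs.D_ca)
    cam = MoleculeType("cam", (
        SiteType("N1", "binding"), SiteType("N2", "binding"),
        SiteType("C1", "binding"), SiteType("C2", "binding"),
        SiteType("k", "binding"), SiteType("kp", "flag"),
    ), diffusion_cm2_s=rs.D_cam)
    sub = MoleculeType("sub", (
        SiteType("c", "binding"), SiteType("p", "flag"),
    ), diffusion_cm2_s=rs.D_sub, mobile=False)
    return {"ca": ca, "cam": cam, "sub": sub}


# ---------------------------------------------------------------------------
# rule files (text, parsed through the dialect)

_STEP_CONDS = {
    "C1": "C1==0, C2==0",
    "C2": "C1==1, C2==0",
    "N1": "N1==0, N2==0",
    "N2": "N1==1, N2==0",
}
_TIER_CONDS = {"free": "k==0", "K": "k==1, kp==0", "Kp": "k==1, kp==1"}
_TIER_PREFIX = {"free": "", "K": "K", "Kp": "Kp"}


def _ca_rule(step: str, tier: str, kon: float, koff: float) -> str:
    conds = f"{_STEP_CONDS[step]}, {_TIER_CONDS[tier]}"
    label = f"{_TIER_PREFIX[tier]}{step}~ca"
    return (f"cam{{{conds}}} + ca{{b==0}} <-> cam~ca{{cam.{step}=1, ca.b=1}} "
            f"kf={kon:g} kb={koff:g} label={label}")


def _state_conds(state: str) -> str:
    n, c = int(state[1]), int(state[3])
    bits = {"N1": int(n >= 1), "N2": int(n >= 2),
            "C1": int(c >= 1), "C2": int(c >= 2)}
    return ", ".join(f"{s}=={v}" for s, v in bits.items())


def model1_rule_text(rs: RateSet) -> str:
    """Sequential-lobe Ca2+ binding on free CaM: exactly 4 reversible rules."""
    lines = ["# Ca2+ <-> CaM, free tier (9-state CaM network)"]
    for step in ("C1", "C2", "N1", "N2"):
        kon, koff = rs.step_rates(step, "free")
        lines.append(_ca_rule(step, "free", kon, koff))
    return "\n".join(lines)


def full_network_rule_text(rs: RateSet) -> str:
    """The two-layer network: 12 Ca2+ rules (3 tiers) + 18 CaM-CaMKII rules."""
    lines = ["# Ca2+ <-> CaM in all three affinity tiers"]
    for tier in ("free", "K", "Kp"):
        for step in ("C1", "C2", "N1", "N2"):
            kon, koff = rs.step_rates(step, tier)
            lines.append(_ca_rule(step, tier, kon, koff))
    lines.append("# CaM <-> CaMKII subunit, per CaM loading state")
    for state in CAM_STATES:
        kon, koff = rs.cam_k_rates(state, phosphorylated=False)
        lines.append(
            f"cam{{{_state_conds(state)}, k==0}} + sub{{c==0, p==0}} <-> "
            f"cam~sub{{cam.k=1, sub.c=1}} kf={kon:g} kb={koff:g} "
            f"label=K~{state}")
        kon, koff = rs.cam_k_rates(state, phosphorylated=True)
        lines.append(
            f"cam{{{_state_conds(state)}, k==0}} + sub{{c==0, p==1}} <-> "
            f"cam~sub{{cam.k=1, cam.kp=1, sub.c=1}} kf={kon:g} kb={koff:g} "
            f"label=Kp~{state}")
    return "\n".join(lines)


#: rate constants of the reduced chain (chosen once for the preset; the
#: frequency-crossover phenomenon, not absolute counts, is the target).
#: C-site retention (~70 ms) sits between the 10 Hz and 5 Hz inter-pulse
#: intervals, which is what makes the chain a high-pass Ca2+ detector at
#: sub-saturating influx.
REDUCED_RATES = {
    "C1": (2.0, 15.0),
    "C2": (30.0, 15.0),
    "N1": (100.0, 400.0),
    "K": (30.0, 2.0),
    "phospho": 1.0,
    "ca_efflux": 80.0,  # s^-1, well-mixed stand-in for bottom-face escape
}

#: per-pulse influx ladder of the frequency-dependence experiment
#: (full-scale ion counts; scaled presets multiply by their volume scale)
REDUCED_INFLUX_LADDER = (5000, 10000, 25000, 50000)


def reduced_rule_text(params: dict | None = None) -> str:
    p = {**REDUCED_RATES, **(params or {})}
    lines = ["# reduced chain: N0C0 -> N0C1 -> N0C2 -> N1C2 -> K binding"]
    lines.append(
        f"cam{{C1==0, C2==0, N1==0, k==0}} + ca{{b==0}} <-> "
        f"cam~ca{{cam.C1=1, ca.b=1}} kf={p['C1'][0]:g} kb={p['C1'][1]:g} label=C1~ca")
    lines.append(
        f"cam{{C1==1, C2==0, N1==0, k==0}} + ca{{b==0}} <-> "
        f"cam~ca{{cam.C2=1, ca.b=1}} kf={p['C2'][0]:g} kb={p['C2'][1]:g} label=C2~ca")
    lines.append(
        f"cam{{C1==1, C2==1, N1==0, N2==0, k==0}} + ca{{b==0}} <-> "
        f"cam~ca{{cam.N1=1, ca.b=1}} kf={p['N1'][0]:g} kb={p['N1'][1]:g} label=N1~ca")
    lines.append(
        f"cam{{N1==1, N2==0, C1==1, C2==1, k==0}} + sub{{c==0, p==0}} <-> "
        f"cam~sub{{cam.k=1, sub.c=1}} kf={p['K'][0]:g} kb={p['K'][1]:g} label=K~N1C2")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# observables / naming


def cam_vertex_namer(molecules: dict):
    cam = molecules["cam"]
    idx = [cam.site_index(s) for s in ("N1", "N2", "C1", "C2", "k", "kp")]

    def namer(tname: str, state) -> str | None:
        if tname != "cam":
            return None
        n = int(state[idx[0]]) + int(state[idx[1]])
        c = int(state[idx[2]]) + int(state[idx[3]])
        prefix = "" if not state[idx[4]] else ("Kp" if state[idx[5]] else "K")
        return f"{prefix}N{n}C{c}"

    return namer


def cam_state_observables(free_only: bool = True) -> list:
    """Counts of the 9 CaM loading states (free CaM when ``free_only``)."""
    obs = []
    for state in CAM_STATES:
        n, c = int(state[1]), int(state[3])
        conds = [("N1", int(n >= 1)), ("N2", int(n >= 2)),
                 ("C1", int(c >= 1)), ("C2", int(c >= 2))]
        if free_only:
            conds.append(("k", 0))
        obs.append((state, "cam", conds))
    return obs


# ---------------------------------------------------------------------------
# presets


@dataclass
class Preset:
    """A runnable configuration; ``simulation(seed)`` builds the engine."""

    name: str
    model: ModelDefinition
    geometry: Geometry
    dt: float
    t_end: float
    record_interval: float = 1e-3
    influx: InfluxTrace | None = None
    rate_set: RateSet | None = None
    rule_text: str = ""
    notes: dict = field(default_factory=dict)

    def simulation(self, seed: int = 0, strict: bool = False,
                   debug_checks: bool = False,
                   t_end: float | None = None) -> Simulation:
        cfg = SimConfig(dt=self.dt,
                        t_end=self.t_end if t_end is None else t_end,
                        record_interval=self.record_interval, seed=seed,
                        strict=strict, debug_checks=debug_checks,
                        influx_source=self.influx)
        sim = Simulation(self.model, self.geometry, cfg)
        binder = self.notes.get("post_init")
        if binder is not None:
            binder(sim)
        return sim


def _pulse_influx(dt: float, t_end: float, freq_hz: float, n_pulses: int,
                  ions_per_pulse: int) -> InfluxTrace:
    """Instantaneous pulses aligned to the simulation step grid."""
    n_steps = int(round(t_end / dt))
    ions = np.zeros(n_steps, dtype=np.int64)
    for k in range(n_pulses):
        idx = int(round(k / freq_hz / dt))
        if idx < n_steps:
            ions[idx] += ions_per_pulse
    times_ms = np.arange(n_steps) * dt * 1e3
    return InfluxTrace(times_ms, ions, {"freq_hz": freq_hz,
                                        "ions_per_pulse": ions_per_pulse})


def _channel_influx(dt: float, t_end: float, freq_hz: float,
                    n_channels: int, seed: int,
                    thin: float = 1.0) -> InfluxTrace:
    """Stochastic channel-gated influx resampled onto the step grid.

    ``thin`` < 1 subsamples the entering ions binomially — the desk-scale
    equivalent of shrinking the membrane patch with the channel density
    (and hence per-channel statistics) unchanged.
    """
    trace = generate_voltage_trace(burst_interval_hz=freq_hz)
    bank = ChannelBank(n_channels=n_channels)
    flux = generate_influx(trace, bank, seed=seed)
    n_steps = int(round(t_end / dt))
    ions = np.zeros(n_steps, dtype=np.int64)
    bin_steps = flux.times_ms * 1e-3 / dt
    rng = np.random.default_rng(seed + 777)
    for t_idx, n in zip(bin_steps.astype(int), flux.ions):
        if 0 <= t_idx < n_steps and n > 0:
            n = int(n) if thin >= 1.0 else int(rng.binomial(int(n), thin))
            ions[t_idx] += n
    times_ms = np.arange(n_steps) * dt * 1e3
    return InfluxTrace(times_ms, ions, flux.meta)


def _saturating_cam_binder(sim: Simulation) -> None:
    """Bind one fully loaded CaM to every subunit (saturating-CaM setup)."""
    model = sim.model
    cam = model.molecules["cam"]
    sub = model.molecules["sub"]
    cam_sl = sim.type_slice["cam"]
    sub_sl = sim.type_slice["sub"]
    cam_ids = np.nonzero(sim.alive[cam_sl])[0] + cam_sl.start
    sub_ids = np.nonzero(sim.alive[sub_sl])[0] + sub_sl.start
    if cam_ids.size < sub_ids.size:
        raise ValueError("not enough CaM to saturate the subunits")
    k_idx = cam.site_index("k")
    c_idx = sub.site_index("c")
    for s_loaded in ("N1", "N2", "C1", "C2"):
        sim.state[cam_ids, cam.site_index(s_loaded)] = 1
    for ci, si in zip(cam_ids, sub_ids):
        ci, si = int(ci), int(si)
        sim.state[ci, k_idx] = 1
        sim.state[si, c_idx] = 1
        sim.bond_partner[ci, k_idx] = si
        sim.bond_site[ci, k_idx] = c_idx
        sim.bond_partner[si, c_idx] = ci
        sim.bond_site[si, c_idx] = k_idx
        root = int(sim.root[si])
        sim.root[ci] = root
        sim.pos[ci] = sim.pos[si]
        sim.offset[ci] = sim.offset[si]
        sim._members.setdefault(root, [m for m in sim._cluster_members(root)]) \
            .append(ci)


def build_preset(name: str, rate_set: RateSet | None = None,
                 scale: float = 1.0, seed: int = 0, **overrides) -> Preset:
    """Build one of the shipped presets, with optional overrides.

    ``scale`` shrinks the volume and all counts at fixed concentrations
    (desk-scale testing).  Common overrides: ``cam_uM``, ``ca_D_factor``,
    ``influx_multiplier``, ``ring_radius_nm``, ``variant``, ``freq_hz``,
    ``ions_per_pulse``, ``dt``, ``t_end``, ``absorb_prob``, ``n_subunits``.
    """
    rs = rate_set or default_rates()
    if overrides.get("cam_uM", 1) < 0 or scale <= 0:
        raise ValueError("invalid override")
    if "ca_D_factor" in overrides:
        rs = replace(rs, D_ca=rs.D_ca * overrides["ca_D_factor"])
    builder = _BUILDERS.get(name)
    if builder is None:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return builder(rs, scale, seed, overrides)


def _scaled_dims(base: tuple, scale: float) -> tuple:
    f = scale ** (1.0 / 3.0)
    return tuple(d * f for d in base)


def _build_model1(rs, scale, seed, ov):
    mols = molecule_declarations(rs)
    text = model1_rule_text(rs)
    table = build_table(parse_rules(text, mols), mols)
    dims = _scaled_dims((0.5, 0.5, 0.5), scale)
    n_ca = int(round(3000 * scale))
    n_cam = int(round(700 * scale))
    model = ModelDefinition(
        molecules=mols, table=table,
        initial_counts={"ca": n_ca, "cam": n_cam},
        vertex_namer=cam_vertex_namer(mols),
        observables=cam_state_observables() + [("ca_free", "ca", [("b", 0)])],
    )
    return Preset("model1_ca_cam", model, Geometry(dims),
                  dt=ov.get("dt", 1e-6), t_end=ov.get("t_end", 0.05),
                  rate_set=rs, rule_text=text)


def _build_model2(rs, scale, seed, ov):
    n_sub = ov.get("n_subunits", 6)
    total = int(round(ov.get("total_subunits", 6000) * scale))
    n_rings = max(1, total // n_sub)
    mols = molecule_declarations(rs)
    table = build_table([], mols)
    tpl = RingTemplate(n_subunits=n_sub,
                       ring_radius_nm=ov.get("ring_radius_nm", 8.0),
                       variant=KinaseRuleVariant.ml_no_phospho_kinase)
    kin = KinaseSpec(variant=KinaseRuleVariant.ml_no_phospho_kinase,
                     rates={s: ov.get("k_p", 1.0) for s in CAM_STATES})
    model = ModelDefinition(
        molecules=mols, table=table,
        initial_counts={"cam": n_rings * n_sub},
        rings=[(tpl, n_rings)], kinase=kin,
        observables=[("phospho", "sub", [("p", 1)]),
                     ("cam_bound", "sub", [("c", 1)])],
    )
    preset = Preset("model2_ml_test", model, Geometry(_scaled_dims((1, 1, 1), scale)),
                    dt=ov.get("dt", 1e-3), t_end=ov.get("t_end", 8.0),
                    record_interval=ov.get("record_interval", 0.05),
                    rate_set=rs)
    preset.notes["post_init"] = _saturating_cam_binder
    return preset


def _build_model3(rs, scale, seed, ov):
    mols = molecule_declarations(rs)
    text = full_network_rule_text(rs)
    table = build_table(parse_rules(text, mols), mols)
    dims = _scaled_dims((1.0, 1.0, 1.0), scale)
    vol = dims[0] * dims[1] * dims[2]
    cam_uM = ov.get("cam_uM", 5.0)
    model = ModelDefinition(
        molecules=mols, table=table,
        initial_counts={
            "ca": int(round(ov.get("ca_count", 14448) * scale)),
            "cam": concentration_to_count(cam_uM, vol),
            "sub": concentration_to_count(ov.get("sub_uM", 10.0), vol),
        },
        kinase=KinaseSpec(rates=dict(rs.phospho), neighbor_gated=False),
        vertex_namer=cam_vertex_namer(mols),
        observables=[("phospho", "sub", [("p", 1)]),
                     ("cam_bound", "sub", [("c", 1)]),
                     ("ca_free", "ca", [("b", 0)])],
    )
    return Preset("model3_closed_network", model, Geometry(dims),
                  dt=ov.get("dt", 1e-6), t_end=ov.get("t_end", 0.1),
                  rate_set=rs, rule_text=text)


def _prototype_like(name, variant, rs, scale, seed, ov):
    mols = molecule_declarations(rs)
    text = full_network_rule_text(rs)
    table = build_table(parse_rules(text, mols), mols)
    dims = _scaled_dims((1.0, 1.0, 2.0), scale)
    vol = dims[0] * dims[1] * dims[2]
    cam_uM = ov.get("cam_uM", 5.0)
    sub_uM = ov.get("sub_uM", 10.0)
    n_rings = max(1, concentration_to_count(sub_uM, vol) // 6)
    tpl = RingTemplate(n_subunits=6,
                       ring_radius_nm=ov.get("ring_radius_nm", 8.0),
                       variant=variant)
    dt = ov.get("dt", 1e-6)
    t_end = ov.get("t_end", 2.2)
    freq = ov.get("freq_hz", 5.0)
    mult = ov.get("influx_multiplier", 1)
    if ov.get("no_influx", False):
        influx = None
    else:
        influx = _channel_influx(dt, t_end, freq,
                                 n_channels=int(round(16 * mult)), seed=seed,
                                 thin=scale if ov.get("scale_influx", True) else 1.0)
    counts = {"cam": concentration_to_count(cam_uM, vol)}
    if ov.get("ca_count", 0):
        counts["ca"] = int(round(ov["ca_count"] * scale))
    model = ModelDefinition(
        molecules=mols, table=table,
        initial_counts=counts,
        rings=[(tpl, n_rings)],
        kinase=KinaseSpec(variant=variant, rates=dict(rs.phospho)),
        vertex_namer=cam_vertex_namer(mols),
        observables=[("phospho", "sub", [("p", 1)]),
                     ("cam_bound", "sub", [("c", 1)]),
                     ("ca_free", "ca", [("b", 0)]),
                     ("N0C0_free", "cam", [("N1", 0), ("N2", 0), ("C1", 0),
                                           ("C2", 0), ("k", 0)])],
    )
    if ov.get("no_influx", False):
        geo = Geometry(dims)  # closed: fully reflective, Ca2+ conserved
    else:
        geo = Geometry(dims, {"z-": AbsorbingFace(frozenset({"ca"}),
                                                  ov.get("absorb_prob", 0.2))})
    return Preset(name, model, geo, dt=dt, t_end=t_end, influx=influx,
                  rate_set=rs, rule_text=text)


def _build_prototype(rs, scale, seed, ov):
    return _prototype_like("prototype_full",
                           ov.get("variant", KinaseRuleVariant.default_neighbor),
                           rs, scale, seed, ov)


def _build_scheme1(rs, scale, seed, ov):
    return _prototype_like("scheme1", KinaseRuleVariant.scheme1_NxC2_only,
                           rs, scale, seed, ov)


def _build_scheme2(rs, scale, seed, ov):
    return _prototype_like("scheme2", KinaseRuleVariant.scheme2_N2Cx_only,
                           rs, scale, seed, ov)


def _build_radius_sweep(rs, scale, seed, ov):
    ov = {"ring_radius_nm": ov.get("ring_radius_nm", 8.0), **ov}
    return _prototype_like("radius_sweep",
                           KinaseRuleVariant.default_neighbor,
                           rs, scale, seed, ov)


def _build_reduced(rs, scale, seed, ov):
    mols = molecule_declarations(rs)
    params = {**REDUCED_RATES, **ov.get("reduced_rates", {})}
    text = reduced_rule_text(params)
    table = build_table(parse_rules(text, mols), mols)
    dims = _scaled_dims((1.0, 1.0, 2.0), scale)
    vol = dims[0] * dims[1] * dims[2]
    dt = ov.get("dt", 5e-5)
    freq = ov.get("freq_hz", 5.0)
    n_pulses = ov.get("n_pulses", 5)
    t_end = ov.get("t_end", (n_pulses - 1) / freq + 0.45)
    ions = int(round(ov.get("ions_per_pulse", 20000) * scale))
    influx = _pulse_influx(dt, t_end, freq, n_pulses, ions)
    model = ModelDefinition(
        molecules=mols, table=table,
        initial_counts={
            "cam": concentration_to_count(ov.get("cam_uM", 5.0), vol),
            "sub": concentration_to_count(ov.get("sub_uM", 10.0), vol),
        },
        kinase=KinaseSpec(rates={"N1C2": params["phospho"]},
                          neighbor_gated=False),
        vertex_namer=cam_vertex_namer(mols),
        observables=[("phospho", "sub", [("p", 1)]),
                     ("cam_bound", "sub", [("c", 1)]),
                     ("ca_free", "ca", [("b", 0)]),
                     ("N0C0", "cam", [("C1", 0), ("N1", 0), ("k", 0)])],
    )
    geo = Geometry(dims, {"z-": AbsorbingFace(frozenset({"ca"}),
                                              ov.get("absorb_prob", 0.2))})
    preset = Preset("reduced_fig13", model, geo, dt=dt, t_end=t_end,
                    influx=influx, rate_set=rs, rule_text=text)
    preset.notes["reduced_params"] = params
    return preset


_BUILDERS = {
    "model1_ca_cam": _build_model1,
    "model2_ml_test": _build_model2,
    "model3_closed_network": _build_model3,
    "prototype_full": _build_prototype,
    "reduced_fig13": _build_reduced,
    "scheme1": _build_scheme1,
    "scheme2": _build_scheme2,
    "radius_sweep": _build_radius_sweep,
}


# ---------------------------------------------------------------------------
# equilibration


def equilibrate(preset: Preset, n_trials: int = 5, t_pre: float | None = None,
                seed: int = 0, drift_sigmas: float = 3.0):
    """Pre-run a closed preset to a stationary initial condition.

    Runs ``n_trials`` replicate simulations without influx, tests that each
    observable's mean over the last 20% of the pre-run window agrees with the
    preceding 20% within ``drift_sigmas`` standard errors, and returns the
    last trial's :class:`Simulation` (its state is the snapshot) together
    with a report of the equilibrated observable means.
    """
    t_pre = preset.t_end if t_pre is None else t_pre
    report: dict = {"observables": {}, "stationary": True, "trials": n_trials}
    sims = []
    series = []
    for k in range(n_trials):
        cfg = SimConfig(dt=preset.dt, t_end=t_pre,
                        record_interval=preset.record_interval,
                        seed=seed + k, influx_source=None)
        sim = Simulation(preset.model, preset.geometry, cfg)
        binder = preset.notes.get("post_init")
        if binder is not None:
            binder(sim)
        sim.run()
        sims.append(sim)
        series.append(np.array([r[1:] for r in sim.records], dtype=float))
    arr = np.stack(series)  # (trials, times, obs)
    n_t = arr.shape[1]
    last = arr[:, int(0.8 * n_t):, :]
    prev = arr[:, int(0.6 * n_t): int(0.8 * n_t), :]
    names = [name for name, _, _ in preset.model.observables]
    for i, name in enumerate(names):
        m_last = last[..., i].mean()
        m_prev = prev[..., i].mean()
        se = last[..., i].mean(axis=1).std(ddof=1) / math.sqrt(n_trials) \
            if n_trials > 1 else 0.0
        stationary = abs(m_last - m_prev) <= drift_sigmas * max(se, 1.0)
        report["observables"][name] = {
            "mean": m_last, "prev_mean": m_prev, "se": se,
            "stationary": bool(stationary)}
        report["stationary"] = report["stationary"] and bool(stationary)
    return sims[-1], report


# ---------------------------------------------------------------------------
# well-mixed oracle models (shared rate constants, independent machinery)


def model1_wellmixed(rs: RateSet, volume_um3: float):
    """Mass-action expansion of the 9-state Ca2+-CaM network.

    Species: free Ca2+ plus the nine CaM loading states.  Returns
    (model, species_names) where the reaction rates already carry the
    per-pair volume conversion.
    """
    from .oracles import Reaction, WellMixedModel

    species = ["ca"] + CAM_STATES
    model = WellMixedModel(species, [], volume_um3)
    idx = model.index
    rxns = []
    for state in CAM_STATES:
        n, c = int(state[1]), int(state[3])
        for step, (lo, hi) in (("N1", (0, 1)), ("N2", (1, 2)),
                               ("C1", (0, 1)), ("C2", (1, 2))):
            cur = n if step[0] == "N" else c
            if cur != lo:
                continue
            new = f"N{hi}C{c}" if step[0] == "N" else f"N{n}C{hi}"
            kon, koff = rs.step_rates(step, "free")
            rxns.append(Reaction(f"{step}~ca+@{state}",
                                 (idx["ca"], idx[state]), (idx[new],),
                                 model.bimolecular_rate(kon)))
            rxns.append(Reaction(f"{step}~ca-@{state}",
                                 (idx[new],), (idx["ca"], idx[state]), koff))
    model.reactions = rxns
    return model, species


def reduced_wellmixed(volume_um3: float, params: dict | None = None):
    """The reduced chain as a well-mixed model (with Ca2+ efflux)."""
    from .oracles import Reaction, WellMixedModel

    p = {**REDUCED_RATES, **(params or {})}
    species = ["ca", "N0C0", "N0C1", "N0C2", "N1C2", "K", "KN1C2", "KpN1C2"]
    model = WellMixedModel(species, [], volume_um3)
    i = model.index
    b = model.bimolecular_rate
    rxns = [
        Reaction("C1~ca+", (i["ca"], i["N0C0"]), (i["N0C1"],), b(p["C1"][0])),
        Reaction("C1~ca-", (i["N0C1"],), (i["ca"], i["N0C0"]), p["C1"][1]),
        Reaction("C2~ca+", (i["ca"], i["N0C1"]), (i["N0C2"],), b(p["C2"][0])),
        Reaction("C2~ca-", (i["N0C2"],), (i["ca"], i["N0C1"]), p["C2"][1]),
        Reaction("N1~ca+", (i["ca"], i["N0C2"]), (i["N1C2"],), b(p["N1"][0])),
        Reaction("N1~ca-", (i["N1C2"],), (i["ca"], i["N0C2"]), p["N1"][1]),
        Reaction("K~N1C2+", (i["N1C2"], i["K"]), (i["KN1C2"],), b(p["K"][0])),
        Reaction("K~N1C2-", (i["KN1C2"],), (i["N1C2"], i["K"]), p["K"][1]),
        Reaction("KN1C2~p", (i["KN1C2"],), (i["KpN1C2"],), p["phospho"]),
        Reaction("ca_out", (i["ca"],), (), p["ca_efflux"]),
    ]
    model.reactions = rxns
    return model, species


def full_monomer_wellmixed(rs: RateSet, volume_um3: float):
    """Full-kinetics network with monomeric CaMKII as a class-count model.

    CaM classes carry the joint information of bound pairs: a CaM with the
    K (Kp) attachment bit set stands for a CaM-subunit (CaM-phospho-subunit)
    pair, so pair counts are exact without tracking explicit dimer species.
    """
    from .oracles import Reaction, WellMixedModel

    species = (["ca", "K_free", "Kp_free"]
               + CAM_STATES
               + ["K" + s for s in CAM_STATES]
               + ["Kp" + s for s in CAM_STATES])
    model = WellMixedModel(species, [], volume_um3)
    i = model.index
    b = model.bimolecular_rate
    rxns = []
    for tier, prefix in (("free", ""), ("K", "K"), ("Kp", "Kp")):
        for state in CAM_STATES:
            n, c = int(state[1]), int(state[3])
            for step, (lo, hi) in (("N1", (0, 1)), ("N2", (1, 2)),
                                   ("C1", (0, 1)), ("C2", (1, 2))):
                cur = n if step[0] == "N" else c
                if cur != lo:
                    continue
                new = f"N{hi}C{c}" if step[0] == "N" else f"N{n}C{hi}"
                kon, koff = rs.step_rates(step, tier)
                rxns.append(Reaction(f"{prefix}{step}~ca+@{state}",
                                     (i["ca"], i[prefix + state]),
                                     (i[prefix + new],), b(kon)))
                rxns.append(Reaction(f"{prefix}{step}~ca-@{state}",
                                     (i[prefix + new],),
                                     (i["ca"], i[prefix + state]), koff))
    for state in CAM_STATES:
        kon, koff = rs.cam_k_rates(state, False)
        rxns.append(Reaction(f"K~{state}+", (i[state], i["K_free"]),
                             (i["K" + state],), b(kon)))
        rxns.append(Reaction(f"K~{state}-", (i["K" + state],),
                             (i[state], i["K_free"]), koff))
        kon, koff = rs.cam_k_rates(state, True)
        rxns.append(Reaction(f"Kp~{state}+", (i[state], i["Kp_free"]),
                             (i["Kp" + state],), b(kon)))
        rxns.append(Reaction(f"Kp~{state}-", (i["Kp" + state],),
                             (i[state], i["Kp_free"]), koff))
        rxns.append(Reaction(f"K{state}~p", (i["K" + state],),
                             (i["Kp" + state],), rs.phospho[state]))
    model.reactions = rxns
    return model, species
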