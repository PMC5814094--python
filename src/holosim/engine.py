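"""Brownian-dynamics engine with site-level reaction execution.

One iteration of the fixed-step scheme:

1. optional Ca2+ influx (particles activated at the source point);
2. diffusion: every free mobile particle takes an isotropic Gaussian step
   (per-axis std sqrt(2 D dt)); a bound cluster moves as a rigid unit with
   the smallest diffusion coefficient among its members; clusters containing
   an immobilized member (e.g. a CaMKII ring) do not move;
3. boundary handling: reflective faces mirror, periodic faces wrap, a
   partially absorbing face removes listed free species with a sticking
   probability and reflects everything else;
4. bimolecular reactions: colliding pairs closer than the calibrated binding
   radius react; when several rules share the reactant pair the branch is
   selected proportionally to the forward rates (single uniform draw);
5. unimolecular reactions (flag flips, unbindings) fire as competing risks
   with exact exponential per-step probabilities; unbinding separates the
   partners by the binding radius along a random direction;
6. neighbor-conditional autophosphorylation on ring complexes.

Reactions never delete particles: state bits, bonds and positions are
mutated in place, which keeps per-molecule reaction histories intact and
makes conservation checks exact.  Every reaction occurrence is appended to
an event log (time, edge label, direction, source vertex).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ring as ring_mod
from .calibrate import binding_radius
from .ring import KinaseRuleVariant, RingTemplate
from .rules import MoleculeType, ReactionRule, RuleTable, conditions_hold

__all__ = [
    "Geometry",
    "AbsorbingFace",
    "SimConfig",
    "EventRecord",
    "ModelDefinition",
    "KinaseSpec",
    "Simulation",
    "StepSizeWarning",
]


class StepSizeWarning(UserWarning):
    """The configured dt is coarse for the model's rates or geometry."""


@dataclass(frozen=True)
class AbsorbingFace:
    """Partial absorption of listed species at one box face."""

    species: frozenset
    probability: float  # sticking probability per boundary encounter

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("absorption probability must be in [0, 1]")


@dataclass
class Geometry:
    """Axis-aligned box with per-face boundary behavior.

    Faces are named ``x-,x+,y-,y+,z-,z+``; ``z+`` (z = Lz) is the membrane
    ("top") face.  A face's behavior is "reflective", "periodic", or an
    :class:`AbsorbingFace` (absorbing for its species, reflective for all
    others).  Periodic behavior must be declared on both faces of an axis.
    """

    dims: tuple[float, float, float]
    faces: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("box dimensions must be positive")
        for ax in "xyz":
            lo = self.faces.get(ax + "-", "reflective")
            hi = self.faces.get(ax + "+", "reflective")
            if ("periodic" in (lo, hi)) and lo != hi:
                raise ValueError(f"periodic boundaries must pair on axis {ax}")

    @property
    def volume_um3(self) -> float:
        return self.dims[0] * self.dims[1] * self.dims[2]

    def face(self, name: str):
        return self.faces.get(name, "reflective")


@dataclass
class KinaseSpec:
    """Native neighbor-conditional autophosphorylation on ring subunits.

    ``rates`` maps the bound CaM's Ca2+-loading state name (e.g. "N2C2") to
    a first-order phosphorylation rate (s^-1).  Site names refer to the
    subunit's CaM-binding site and phospho flag, the CaM's lobe sites and
    the mirror flags CaM carries about its attachment.
    """

    subunit_type: str = "sub"
    cam_type: str = "cam"
    variant: KinaseRuleVariant = KinaseRuleVariant.default_neighbor
    rates: dict = field(default_factory=dict)
    #: False models monomeric CaMKII: no left-neighbor requirement
    neighbor_gated: bool = True
    sub_cam_site: str = "c"
    sub_p_site: str = "p"
    cam_sites: tuple[str, str, str, str] = ("N1", "N2", "C1", "C2")
    cam_attach_site: str = "k"
    cam_attach_p_site: str = "kp"


@dataclass
class ModelDefinition:
    """Everything the engine needs to run one model."""

    molecules: dict  # name -> MoleculeType
    table: RuleTable
    initial_counts: dict = field(default_factory=dict)  # type -> count (non-ring)
    rings: list = field(default_factory=list)  # (RingTemplate, n_rings)
    kinase: KinaseSpec | None = None
    initial_states: dict = field(default_factory=dict)  # type -> site-name->value
    vertex_namer: object = None  # callable(type_name, state_vec) -> str | None
    observables: list = field(default_factory=list)  # (name, type, [(site, val)...])


@dataclass
class SimConfig:
    """Run settings for :class:`Simulation`."""

    dt: float = 1e-6
    t_end: float = 0.05
    record_interval: float = 1e-3
    seed: int = 0
    strict: bool = False  # escalate step-size warnings to errors
    debug_checks: bool = False
    influx_source: object = None  # InfluxTrace or None
    max_pairs_bruteforce: int = 4_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_interval < self.dt:
            raise ValueError("record interval must be >= dt")


@dataclass(frozen=True)
class EventRecord:
    """One reaction occurrence."""

    time: float
    label: str
    direction: int  # +1 binding / flag set, -1 unbinding
    vertex: str | None
    i: int
    j: int


class Simulation:
    """Particle state plus the stepping loop.

    Particle storage is struct-of-arrays with one contiguous block per
    molecule type (Ca2+ gets spare capacity for influx).  Bound clusters are
    tracked through a ``root`` array (every member points at the particle
    that owns the cluster's position) plus fixed in-cluster offsets, which
    keeps ring geometry rigid while bound partners co-locate exactly.
    """

    def __init__(self, model: ModelDefinition, geometry: Geometry,
                 config: SimConfig):
        self.model = model
        self.geometry = geometry
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.t = 0.0
        self.events: list[EventRecord] = []
        self._build_particles()
        self._prepare_rules()
        self._check_step_size()
        self.ca_influx_total = 0
        self.absorbed_counts: dict[str, int] = {}
        self.records: list[tuple] = []
        self._record_names = [name for name, _, _ in model.observables]

    # -- construction ------------------------------------------------------

    def _build_particles(self) -> None:
        model, geo, rng = self.model, self.geometry, self.rng
        self.type_names = list(model.molecules)
        self.type_index = {n: i for i, n in enumerate(self.type_names)}
        self.site_count = max(len(m.sites) for m in model.molecules.values())
        dims = np.asarray(geo.dims)

        counts = dict(model.initial_counts)
        influx_cap = 0
        if self.config.influx_source is not None:
            influx_cap = int(self.config.influx_source.ions.sum())
        ring_blocks = []
        for tpl, n_rings in model.rings:
            ring_blocks.append((tpl, n_rings))

        blocks = []  # (type, capacity, active)
        for name in self.type_names:
            n = int(counts.get(name, 0))
            cap = n
            if name == "ca":
                cap += influx_cap
            blocks.append((name, cap, n))

        total_ring = sum(tpl.n_subunits * nr for tpl, nr in ring_blocks)
        n_cap = sum(c for _, c, _ in blocks) + total_ring
        self.pos = np.zeros((n_cap, 3))
        self.offset = np.zeros((n_cap, 3))
        self.type_id = np.zeros(n_cap, dtype=np.int16)
        self.state = np.zeros((n_cap, self.site_count), dtype=np.uint8)
        self.bond_partner = np.full((n_cap, self.site_count), -1, dtype=np.int64)
        self.bond_site = np.full((n_cap, self.site_count), -1, dtype=np.int16)
        self.alive = np.zeros(n_cap, dtype=bool)
        self.root = np.arange(n_cap, dtype=np.int64)
        self.root_D = np.zeros(n_cap)  # effective cluster D, valid at roots
        self.ring_id = np.full(n_cap, -1, dtype=np.int64)
        self.ring_pos = np.full(n_cap, -1, dtype=np.int16)
        self.left_idx = np.full(n_cap, -1, dtype=np.int64)
        self._members: dict[int, list[int]] = {}

        off = 0
        self.type_slice: dict[str, slice] = {}
        self.type_active: dict[str, int] = {}
        for name, cap, active in blocks:
            sl = slice(off, off + cap)
            self.type_slice[name] = sl
            self.type_active[name] = active
            mol = model.molecules[name]
            self.type_id[sl] = self.type_index[name]
            self.state[sl, : len(mol.sites)] = mol.default_state_vector()
            init = self.model.initial_states.get(name)
            if init:
                for sname, val in init.items():
                    self.state[sl, mol.site_index(sname)] = val
            self.alive[off: off + active] = True
            self.pos[sl] = rng.random((cap, 3)) * dims
            self.root_D[sl] = mol.diffusion_um2_s
            off += cap

        # rings
        self.ring_templates: list[RingTemplate] = []
        ring_counter = 0
        for tpl, n_rings in ring_blocks:
            mol = model.molecules[tpl.subunit_type]
            r = tpl.effective_radius_um
            if any(d < 2 * r for d in geo.dims):
                raise ValueError("ring complex does not fit inside the box")
            for _ in range(n_rings):
                n = tpl.n_subunits
                sl = slice(off, off + n)
                center = r + rng.random(3) * (dims - 2 * r)
                phase = rng.random() * 2 * np.pi
                pts = ring_mod.ring_positions(tpl, center, phase)
                self.pos[sl] = pts
                self.type_id[sl] = self.type_index[tpl.subunit_type]
                self.state[sl, : len(mol.sites)] = mol.default_state_vector()
                init = self.model.initial_states.get(tpl.subunit_type)
                if init:
                    for sname, val in init.items():
                        self.state[sl, mol.site_index(sname)] = val
                self.alive[sl] = True
                ids = np.arange(off, off + n)
                self.ring_id[sl] = ring_counter
                self.ring_pos[sl] = np.arange(n)
                self.left_idx[sl] = np.roll(ids, 1)  # left neighbor = (i-1) mod n
                d_eff = mol.diffusion_um2_s if tpl.mobile else 0.0
                anchor = off
                self.root[sl] = anchor
                self.root_D[anchor] = d_eff
                self.offset[sl] = pts - pts[0]
                self._members[anchor] = list(ids)
                ring_counter += 1
                off += n
            self.ring_templates.append(tpl)
            start = off - tpl.n_subunits * n_rings
            existing = self.type_slice.get(tpl.subunit_type)
            if existing is not None and existing.stop > existing.start:
                raise ValueError(
                    f"molecule {tpl.subunit_type} cannot be both a free "
                    "species and a ring subunit in one model")
            self.type_slice[tpl.subunit_type] = slice(start, off)
            self.type_active[tpl.subunit_type] = off - start
        self.n_cap = n_cap
        self._ca_next = self.type_slice["ca"].start + self.type_active.get("ca", 0) \
            if "ca" in self.type_slice else None

    def _prepare_rules(self) -> None:
        """Precompute per-type unary-rule matrices and pair channels."""
        model = self.model
        table = model.table
        mols = model.molecules
        dt = self.config.dt

        # pair channels: (typeA, typeB) with any order-2 rule
        self.pair_channels = []
        for pair in table.pair_types:
            names = sorted(pair)
            a, b = (names[0], names[-1])
            self.pair_channels.append((a, b))
        self._pair_entry: dict[tuple, tuple] = {}  # key -> (cands, ksum, r3)
        self._channel_rmax: dict[tuple, float] = {}
        for (a, b) in self.pair_channels:
            # exact maximum combined branch rate over all concrete state
            # pairs (state spaces are tiny: 2^n_sites per molecule)
            d_mut = (mols[a].diffusion_um2_s + mols[b].diffusion_um2_s)
            ksum_max = 0.0
            for sa in _all_states(mols[a], self.site_count):
                for sb in _all_states(mols[b], self.site_count):
                    cands = table.scan(a, sa, b, sb)
                    ksum_max = max(ksum_max, sum(r.k_f for r in cands))
            rmax = binding_radius(ksum_max, d_mut, dt) if ksum_max > 0 and d_mut > 0 else 0.0
            self._channel_rmax[(a, b)] = rmax

        # candidate pre-filter: if every rule of a channel requires the same
        # binding site of a type to be free, particles with that site
        # occupied can never react in this channel
        self._channel_filter: dict[tuple, dict] = {}
        for (a, b) in self.pair_channels:
            filt: dict[str, int] = {}
            for tname in {a, b}:
                mol = mols[tname]
                per_rule_free: list[set[int]] = []
                for rule in table.binary:
                    rp = {r.molecule for r in rule.reactants}
                    if rp != {a, b} and not (a == b and rp == {a}):
                        continue
                    for pat in rule.reactants:
                        if pat.molecule != tname:
                            continue
                        per_rule_free.append({
                            mol.site_index(c.site) for c in pat.conditions
                            if c.target == "self" and c.value == 0
                            and mol.sites[mol.site_index(c.site)].kind == "binding"})
                common = set.intersection(*per_rule_free) if per_rule_free else set()
                if common:
                    filt[tname] = min(common)
            self._channel_filter[(a, b)] = filt

        # unary directed ops per molecule type
        # op = (self_cond(S,), assign(list), kind, rate, label, extra)
        self._unary: dict[str, dict] = {}
        for tname, mol in mols.items():
            ops = []
            for rule in table.unary:
                if rule.reactants[0].molecule != tname:
                    continue
                # forward
                if rule.k_f > 0:
                    ops.append(self._make_flag_op(rule, mol, forward=True))
                if rule.k_b > 0:
                    ops.append(self._make_flag_op(rule, mol, forward=False))
            for rule in table.binary:
                if rule.k_b <= 0:
                    continue
                if rule.reactants[0].molecule != tname:
                    continue
                ops.append(self._make_unbind_op(rule, mols))
            if ops:
                S = self.site_count
                R = len(ops)
                self_cond = np.full((R, S), -1, dtype=np.int16)
                partner_cond = np.full((R, S), -1, dtype=np.int16)
                bond_follow = np.full(R, -1, dtype=np.int16)
                rates = np.zeros(R)
                for i, op in enumerate(ops):
                    self_cond[i] = op["self_cond"]
                    partner_cond[i] = op["partner_cond"]
                    bond_follow[i] = op["bond_follow"]
                    rates[i] = op["rate"]
                self._unary[tname] = {
                    "ops": ops,
                    "self_cond": self_cond,
                    "partner_cond": partner_cond,
                    "bond_follow": bond_follow,
                    "rates": rates,
                    "p_scale": rates,  # competing-risk hazards
                }
        self._prepare_kinase()
        self._prepare_boundaries()

    def _prepare_boundaries(self) -> None:
        geo = self.geometry
        self._dims_arr = np.asarray(geo.dims, dtype=float)
        self._periodic_axes = []
        self._reflect_axes = []
        self._absorbing_faces = []
        for ax in range(3):
            lo = geo.face("xyz"[ax] + "-")
            hi = geo.face("xyz"[ax] + "+")
            if lo == "periodic":
                self._periodic_axes.append(ax)
            else:
                self._reflect_axes.append(ax)
            for side, face in ((0, lo), (1, hi)):
                if isinstance(face, AbsorbingFace):
                    type_ok = np.array([n in face.species
                                        for n in self.type_names])
                    self._absorbing_faces.append((ax, side, face, type_ok))

    def _make_flag_op(self, rule: ReactionRule, mol: MoleculeType, forward: bool):
        S = self.site_count
        self_cond = np.full(S, -1, dtype=np.int16)
        partner_cond = np.full(S, -1, dtype=np.int16)
        has_partner_conds = False
        for c in rule.reactants[0].conditions:
            if c.target == "self":
                self_cond[mol.site_index(c.site)] = c.value
            elif c.target == "partner":
                has_partner_conds = True
        assigns = [(mol.site_index(a.site), a.value) for a in rule.assignments]
        if not forward:
            # reverse: conditions are the post-state, assignments invert
            for idx, val in assigns:
                self_cond[idx] = val
            assigns = [(idx, 1 - val) for idx, val in assigns]
        bond_follow = -1
        if has_partner_conds:
            # partner conditions follow the bond on the (unique) binding site
            # the rule requires occupied
            bound_sites = [
                mol.site_index(c.site) for c in rule.reactants[0].conditions
                if c.target == "self" and c.value == 1
                and mol.sites[mol.site_index(c.site)].kind == "binding"]
            if len(bound_sites) != 1:
                raise ValueError(
                    f"rule {rule.label!r}: partner conditions on a unary rule "
                    "need exactly one occupied binding site to follow")
            bond_follow = bound_sites[0]
            # partner conditions are expressed on the bonded molecule's sites;
            # the partner molecule type is whatever the bond points at, and
            # site indices are resolved against the first other molecule type
            # that has all named sites
            partner_sites = [c for c in rule.reactants[0].conditions
                             if c.target == "partner"]
            target_mol = self._partner_type_for(mol, partner_sites)
            for c in partner_sites:
                partner_cond[target_mol.site_index(c.site)] = c.value
        return {
            "kind": "flag",
            "self_cond": self_cond,
            "partner_cond": partner_cond,
            "bond_follow": bond_follow,
            "assigns": assigns,
            "rate": rule.k_f if forward else rule.k_b,
            "label": rule.label,
            "direction": 1 if forward else -1,
            "rule": rule,
        }

    def _partner_type_for(self, mol: MoleculeType, conds) -> MoleculeType:
        names = {c.site for c in conds}
        for other in self.model.molecules.values():
            if other.name != mol.name and names <= set(other.site_names):
                return other
        raise ValueError(
            f"no molecule type has sites {sorted(names)} for partner conditions")

    def _make_unbind_op(self, rule: ReactionRule, mols: dict):
        """Reverse of a binding rule, evaluated from the first reactant."""
        S = self.site_count
        rp0, rp1 = rule.reactants
        m0, m1 = mols[rp0.molecule], mols[rp1.molecule]
        self_cond = np.full(S, -1, dtype=np.int16)
        partner_cond = np.full(S, -1, dtype=np.int16)
        for c in rp0.conditions:
            if c.target == "self":
                self_cond[m0.site_index(c.site)] = c.value
            elif c.target == "partner":
                partner_cond[m1.site_index(c.site)] = c.value
        for c in rp1.conditions:
            if c.target == "self":
                partner_cond[m1.site_index(c.site)] = c.value
            elif c.target == "partner":
                self_cond[m0.site_index(c.site)] = c.value
        # post-binding state: apply assignments
        for a in rule.assignments:
            if a.target == rp0.molecule:
                self_cond[m0.site_index(a.site)] = a.value
            elif a.target == rp1.molecule:
                partner_cond[m1.site_index(a.site)] = a.value
        site0, site1 = rule.bond_sites(mols)
        return {
            "kind": "unbind",
            "self_cond": self_cond,
            "partner_cond": partner_cond,
            "bond_follow": m0.site_index(site0),
            "sites": (m0.site_index(site0), m1.site_index(site1)),
            "assigns": None,
            "rate": rule.k_b,
            "label": rule.label,
            "direction": -1,
            "rule": rule,
        }

    def _prepare_kinase(self) -> None:
        ks = self.model.kinase
        self._kin = None
        if ks is None:
            return
        mols = self.model.molecules
        sub = mols[ks.subunit_type]
        cam = mols[ks.cam_type]
        idx_c = sub.site_index(ks.sub_cam_site)
        idx_p = sub.site_index(ks.sub_p_site)
        cam_site_idx = [cam.site_index(s) for s in ks.cam_sites]
        # rate lookup over the 16 raw lobe-bit patterns
        rate_by_code = np.zeros(16)
        for code in range(16):
            n1, n2, c1, c2 = ((code >> i) & 1 for i in range(4))
            name = f"N{n1 + n2}C{c1 + c2}"
            rate_by_code[code] = ks.rates.get(name, 0.0)
        self._kin = {
            "spec": ks, "idx_c": idx_c, "idx_p": idx_p,
            "cam_site_idx": np.array(cam_site_idx),
            "idx_cam_kp": cam.site_index(ks.cam_attach_p_site),
            "rate_by_code": rate_by_code,
            "sub_slice": self.type_slice[ks.subunit_type],
        }

    def _check_step_size(self) -> None:
        dt = self.config.dt
        msgs = []
        for rule in self.model.table.rules:
            if rule.k_b * dt > 0.1:
                msgs.append(f"k_b*dt = {rule.k_b * dt:.3g} for rule {rule.label}")
            if rule.order == 1 and rule.k_f * dt > 0.1:
                msgs.append(f"k_f*dt = {rule.k_f * dt:.3g} for rule {rule.label}")
        if self._kin is not None:
            kmax = float(self._kin["rate_by_code"].max())
            if kmax * dt > 0.1:
                msgs.append(f"kinase rate*dt = {kmax * dt:.3g}")
        min_dim = min(self.geometry.dims)
        for mol in self.model.molecules.values():
            rms = math.sqrt(2.0 * mol.diffusion_um2_s * dt)
            if rms > min_dim / 10.0:
                msgs.append(
                    f"rms step {rms * 1e3:.1f} nm of {mol.name} exceeds "
                    f"box/10 ({min_dim * 100:.1f} nm)")
        if msgs:
            text = "coarse time step: " + "; ".join(msgs)
            if self.config.strict:
                raise ValueError(text)
            warnings.warn(text, StepSizeWarning, stacklevel=3)

    # -- queries -----------------------------------------------------------

    def count(self, type_name: str, conditions: list | None = None) -> int:
        sl = self.type_slice[type_name]
        mask = self.alive[sl]
        if conditions:
            mol = self.model.molecules[type_name]
            for site, val in conditions:
                mask = mask & (self.state[sl, mol.site_index(site)] == val)
        return int(mask.sum())

    def ca_ledger(self) -> tuple[int, int, int, int]:
        """(initial, influx, absorbed, current) for Ca2+; balances exactly."""
        sl = self.type_slice["ca"]
        initial = self.model.initial_counts.get("ca", 0)
        absorbed = self.absorbed_counts.get("ca", 0)
        current = int(self.alive[sl].sum())
        return initial, self.ca_influx_total, absorbed, current

    def check_consistency(self) -> None:
        """Bond symmetry and site-bit/bond agreement (debug invariant)."""
        alive_ids = np.nonzero(self.alive)[0]
        for i in alive_ids:
            mol = self.model.molecules[self.type_names[self.type_id[i]]]
            for s, site in enumerate(mol.sites):
                j = self.bond_partner[i, s]
                if site.kind == "binding":
                    has_bond = j >= 0
                    if bool(self.state[i, s]) != has_bond:
                        raise AssertionError(
                            f"site bit/bond mismatch on particle {i} site {site.name}")
                    if has_bond:
                        s2 = self.bond_site[i, s]
                        if self.bond_partner[j, s2] != i:
                            raise AssertionError(
                                f"asymmetric bond {i}<->{j}")
                        if not np.allclose(self.pos[i], self.pos[j] - self.offset[j] + self.offset[i]):
                            raise AssertionError(
                                f"bound pair {i},{j} positions out of sync")

    # -- cluster bookkeeping ----------------------------------------------

    def _cluster_members(self, root: int) -> list[int]:
        return self._members.get(root, [root])

    def _merge_clusters(self, i: int, j: int) -> None:
        """After a new bond i-j, merge clusters and co-locate."""
        ri, rj = int(self.root[i]), int(self.root[j])
        if ri == rj:
            return
        di, dj = self.root_D[ri], self.root_D[rj]
        win, lose, attach_w, attach_l = (
            (ri, rj, i, j) if (di, ri) <= (dj, rj) else (rj, ri, j, i))
        members_l = self._cluster_members(lose)
        members_w = self._cluster_members(win)
        # place the losing cluster so the two newly bonded particles overlap
        shift = (self.pos[attach_w] - self.pos[attach_l])
        for m in members_l:
            self.root[m] = win
            self.pos[m] = self.pos[m] + shift
            self.offset[m] = self.pos[m] - self.pos[win] + self.offset[win]
        self._members[win] = members_w + members_l
        self._members.pop(lose, None)
        self.root_D[win] = min(self.root_D[win], self.root_D[lose])

    def _split_cluster(self, i: int, j: int, sep: float) -> None:
        """After removing bond i-j, recompute components and separate them."""
        old_root = int(self.root[i])
        members = self._cluster_members(old_root)
        # fast path: one side is a leaf (no remaining bonds, not in a ring)
        if (self.ring_id[j] < 0 and (self.bond_partner[j] < 0).all()):
            comp_j = [j]
            comp_i = [m for m in members if m != j]
        elif (self.ring_id[i] < 0 and (self.bond_partner[i] < 0).all()):
            comp_i = [i]
            comp_j = [m for m in members if m != i]
        else:
            comp_i = self._component(i, members)
            comp_j = [m for m in members if m not in comp_i]
        mols = self.model.molecules
        for comp in (comp_i, comp_j):
            if not comp:
                continue
            in_ring = [m for m in comp if self.ring_id[m] >= 0]
            if in_ring:
                new_root = min(in_ring)
                mol = mols[self.type_names[self.type_id[new_root]]]
                tpl = self.ring_templates[0] if self.ring_templates else None
                d_eff = 0.0 if tpl is None or not tpl.mobile else mol.diffusion_um2_s
            else:
                d_eff, new_root = min(
                    (mols[self.type_names[self.type_id[m]]].diffusion_um2_s, m)
                    for m in comp)
            base = self.offset[new_root].copy()
            for m in comp:
                self.root[m] = new_root
                self.offset[m] = self.offset[m] - base
            self.root_D[new_root] = d_eff
            if len(comp) > 1:
                self._members[new_root] = comp
            else:
                self._members.pop(new_root, None)
        if old_root not in (self.root[i], self.root[j]):
            self._members.pop(old_root, None)
        # separate: displace the more mobile component by the unbinding radius
        ri, rj = int(self.root[i]), int(self.root[j])
        direction = self.rng.normal(size=3)
        direction /= np.linalg.norm(direction) + 1e-300
        mover = rj if self.root_D[rj] >= self.root_D[ri] else ri
        for m in self._cluster_members(mover):
            self.pos[m] = self.pos[m] + direction * sep

    def _component(self, start: int, members: list[int]) -> list[int]:
        member_set = set(members)
        seen = {start}
        stack = [start]
        while stack:
            m = stack.pop()
            for s in range(self.site_count):
                p = self.bond_partner[m, s]
                if p >= 0 and p in member_set and p not in seen:
                    seen.add(int(p))
                    stack.append(int(p))
            # ring co-membership keeps subunits in one cluster
            if self.ring_id[m] >= 0:
                for o in members:
                    if o not in seen and self.ring_id[o] == self.ring_id[m]:
                        seen.add(o)
                        stack.append(o)
        return [m for m in members if m in seen]

    # -- stepping ----------------------------------------------------------

    def run(self, t_end: float | None = None) -> None:
        t_end = self.config.t_end if t_end is None else t_end
        dt = self.config.dt
        n_steps = int(round((t_end - self.t) / dt))
        rec_every = max(1, int(round(self.config.record_interval / dt)))
        if not self.records:
            self._record()
        for k in range(n_steps):
            self.step()
            if (k + 1) % rec_every == 0:
                self._record()
            if self.config.debug_checks:
                self.check_consistency()

    def _record(self) -> None:
        row = [self.t]
        for name, tname, conds in self.model.observables:
            row.append(self.count(tname, conds))
        self.records.append(tuple(row))

    def records_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["time"] + self._record_names)

    def _emit(self, label: str, direction: int, vertex, i: int, j: int) -> None:
        self.events.append(EventRecord(self.t, label, direction, vertex, i, j))

    def step(self) -> None:
        dt = self.config.dt
        self.t += dt
        self._influx_step()
        self._diffuse()
        self._boundaries()
        used = self._bimolecular()
        self._unimolecular(used)
        self._kinase_step(used)

    # influx

    def _influx_step(self) -> None:
        trace = self.config.influx_source
        if trace is None:
            return
        # the influx trace must be aligned to the simulation step grid
        step_idx = int(round(self.t / self.config.dt)) - 1
        if step_idx >= trace.ions.size:
            return
        n_ions = int(trace.ions[step_idx])
        if n_ions <= 0:
            return
        self._inject_ca(n_ions)

    def _inject_ca(self, n_ions: int, where: np.ndarray | None = None) -> None:
        sl = self.type_slice["ca"]
        start = self._ca_next
        end = start + n_ions
        if end > sl.stop:
            raise RuntimeError("ca capacity exhausted")
        if where is None:
            dims = self.geometry.dims
            where = np.array([dims[0] / 2, dims[1] / 2, dims[2] - 1e-3])
        self.pos[start:end] = where
        self.alive[start:end] = True
        self.ca_influx_total += n_ions
        self._ca_next = end

    # diffusion

    def _diffuse(self) -> None:
        dt = self.config.dt
        alive = self.alive
        is_root = self.root == np.arange(self.n_cap)
        mobile = alive & is_root & (self.root_D > 0)
        idx = np.nonzero(mobile)[0]
        if idx.size:
            sig = np.sqrt(2.0 * self.root_D[idx] * dt)
            self.pos[idx] += self.rng.normal(size=(idx.size, 3)) * sig[:, None]
        # synchronize members with their cluster root (vectorized gather);
        # root rows are unchanged because offset[root] == 0
        av = np.nonzero(self.alive & (self.root != np.arange(self.n_cap)))[0]
        if av.size:
            r = self.root[av]
            self.pos[av] = self.pos[r] + self.offset[av] - self.offset[r]

    # boundaries

    def _boundaries(self) -> None:
        dims = self._dims_arr
        idx = np.nonzero(self.alive)[0]
        P = self.pos[idx]
        # absorption first (uses unfolded positions to detect crossings)
        for ax, side, face, type_ok in self._absorbing_faces:
            out = P[:, ax] < 0.0 if side == 0 else P[:, ax] > dims[ax]
            if not out.any():
                continue
            cand = np.nonzero(out)[0]
            gids = idx[cand]
            free = (type_ok[self.type_id[gids]]
                    & (self.ring_id[gids] < 0)
                    & (self.bond_partner[gids] < 0).all(axis=1))
            cand = cand[free]
            if cand.size == 0:
                continue
            stick = self.rng.random(cand.size) < face.probability
            gone = idx[cand[stick]]
            if gone.size:
                self.alive[gone] = False
                for i in gone:
                    n = self.type_names[self.type_id[i]]
                    self.absorbed_counts[n] = self.absorbed_counts.get(n, 0) + 1
        for ax in self._periodic_axes:
            P[:, ax] = np.mod(P[:, ax], dims[ax])
        for ax in self._reflect_axes:
            x = np.mod(P[:, ax], 2.0 * dims[ax])
            P[:, ax] = np.where(x > dims[ax], 2.0 * dims[ax] - x, x)
        self.pos[idx] = P

    # bimolecular

    def _pair_lookup(self, tname_a: str, ia: int, tname_b: str, ib: int):
        key = (tname_a, self.state[ia].tobytes(), tname_b, self.state[ib].tobytes())
        entry = self._pair_entry.get(key)
        if entry is None:
            mols = self.model.molecules
            cands, ksum = self.model.table.lookup(
                tname_a, self.state[ia], tname_b, self.state[ib])
            cands = [c for c in cands if c.k_f > 0]
            ksum = sum(c.k_f for c in cands)
            if ksum > 0:
                da = mols[tname_a].diffusion_um2_s
                db = mols[tname_b].diffusion_um2_s
                r3 = binding_radius(ksum, da + db, self.config.dt)
            else:
                r3 = 0.0
            entry = (cands, ksum, r3)
            self._pair_entry[key] = entry
            key2 = (tname_b, self.state[ib].tobytes(), tname_a, self.state[ia].tobytes())
            self._pair_entry[key2] = entry
        return entry

    def _candidate_indices(self, tname: str, free_site: int | None = None) -> np.ndarray:
        sl = self.type_slice[tname]
        mask = self.alive[sl]
        if free_site is not None:
            mask = mask & (self.state[sl, free_site] == 0)
        return np.nonzero(mask)[0] + sl.start

    def _bimolecular(self) -> np.ndarray:
        used = np.zeros(self.n_cap, dtype=bool)
        geo = self.geometry
        periodic = [geo.face(ax + "-") == "periodic" for ax in "xyz"]
        for (a, b) in self.pair_channels:
            rmax = self._channel_rmax[(a, b)]
            if rmax <= 0:
                continue
            filt = self._channel_filter[(a, b)]
            ia = self._candidate_indices(a, filt.get(a))
            ib = self._candidate_indices(b, filt.get(b)) if b != a else ia
            if ia.size == 0 or ib.size == 0:
                continue
            pairs = self._find_pairs(ia, ib, rmax, periodic, same=(a == b))
            if pairs.shape[0] == 0:
                continue
            order = self.rng.permutation(pairs.shape[0])
            for pi in order:
                i, j, d = pairs[pi, 0], pairs[pi, 1], pairs[pi, 2]
                i, j = int(i), int(j)
                if used[i] or used[j] or not (self.alive[i] and self.alive[j]):
                    continue
                if self.root[i] == self.root[j]:
                    continue
                cands, ksum, r3 = self._pair_lookup(a, i, b, j)
                if not cands or d >= r3:
                    continue
                u = 1.0 - self.rng.random()
                rule = cands[0] if len(cands) == 1 else _select(cands, u, ksum)
                self._apply_binding(rule, a, i, b, j)
                used[i] = used[j] = True
        return used

    def _find_pairs(self, ia: np.ndarray, ib: np.ndarray, rmax: float,
                    periodic: list, same: bool) -> np.ndarray:
        pa = self.pos[ia]
        pb = self.pos[ib]
        if ia.size * ib.size <= self.config.max_pairs_bruteforce:
            if any(periodic):
                diff = pa[:, None, :] - pb[None, :, :]
                for ax in range(3):
                    if periodic[ax]:
                        L = self.geometry.dims[ax]
                        diff[..., ax] -= L * np.round(diff[..., ax] / L)
                d2 = np.einsum("ijk,ijk->ij", diff, diff)
            else:
                d2 = ((pa * pa).sum(axis=1)[:, None]
                      + (pb * pb).sum(axis=1)[None, :]
                      - 2.0 * (pa @ pb.T))
            ii, jj = np.nonzero(d2 < rmax * rmax)
            if same:
                keep = ii < jj
                ii, jj = ii[keep], jj[keep]
            out = np.empty((ii.size, 3))
            out[:, 0] = ia[ii]
            out[:, 1] = ib[jj]
            out[:, 2] = np.sqrt(np.maximum(d2[ii, jj], 0.0))
            return out
        from scipy.spatial import cKDTree

        boxsize = None
        if any(periodic):
            if all(periodic):
                boxsize = self.geometry.dims
            else:
                raise NotImplementedError(
                    "mixed periodic boundaries need the brute-force pair path")
        tree = cKDTree(np.mod(pb, self.geometry.dims) if boxsize is not None else pb,
                       boxsize=boxsize)
        qpos = np.mod(pa, self.geometry.dims) if boxsize is not None else pa
        groups = tree.query_ball_point(qpos, rmax)
        rows = []
        for k, lst in enumerate(groups):
            for m in lst:
                if same and ia[k] >= ib[m]:
                    continue
                d = np.linalg.norm(pa[k] - pb[m])
                rows.append((ia[k], ib[m], d))
        return np.asarray(rows, dtype=float).reshape(-1, 3)

    def _apply_binding(self, rule: ReactionRule, tname_i: str, i: int,
                       tname_j: str, j: int) -> None:
        mols = self.model.molecules
        rp0, rp1 = rule.reactants
        # map rule reactants onto (i, j)
        if rp0.molecule == tname_i:
            pid = {rp0.molecule: i, rp1.molecule: j}
        else:
            pid = {rp0.molecule: j, rp1.molecule: i}
        if rp0.molecule == rp1.molecule:
            pid = None  # homodimer rules: positional mapping
        vertex = self._vertex_of(rule, i, j)
        for a in rule.assignments:
            if pid is None:
                tgt = i if a.target == rp0.molecule else j
            else:
                tgt = pid[a.target]
            mol = mols[self.type_names[self.type_id[tgt]]]
            self.state[tgt, mol.site_index(a.site)] = a.value
        site0, site1 = rule.bond_sites(mols)
        p0 = pid[rp0.molecule] if pid else i
        p1 = pid[rp1.molecule] if pid else j
        m0 = mols[rp0.molecule]
        m1 = mols[rp1.molecule]
        s0, s1 = m0.site_index(site0), m1.site_index(site1)
        self.bond_partner[p0, s0] = p1
        self.bond_site[p0, s0] = s1
        self.bond_partner[p1, s1] = p0
        self.bond_site[p1, s1] = s0
        self._merge_clusters(p0, p1)
        self._emit(rule.label, +1, vertex, p0, p1)

    def _vertex_of(self, rule: ReactionRule, i: int, j: int):
        namer = self.model.vertex_namer
        if namer is None:
            return None
        for idx in (i, j):
            tname = self.type_names[self.type_id[idx]]
            v = namer(tname, self.state[idx])
            if v is not None:
                return v
        return None

    # unimolecular

    def _unimolecular(self, used: np.ndarray) -> None:
        dt = self.config.dt
        for tname, pack in self._unary.items():
            sl = self.type_slice[tname]
            ids = np.nonzero(self.alive[sl] & ~used[sl])[0] + sl.start
            if ids.size == 0:
                continue
            st = self.state[ids]  # (n, S)
            sc = pack["self_cond"]  # (R, S)
            ok = ((sc[None, :, :] < 0) | (st[:, None, :] == sc[None, :, :])).all(axis=2)
            pc = pack["partner_cond"]
            bf = pack["bond_follow"]
            follows = bf >= 0
            if follows.any():
                partner_idx = self.bond_partner[ids[:, None], np.maximum(bf, 0)[None, :]]
                valid = follows[None, :] & (partner_idx >= 0)
                pst = self.state[np.maximum(partner_idx, 0)]  # (n, R, S)
                pok = ((pc[None, :, :] < 0) | (pst == pc[None, :, :])).all(axis=2)
                ok &= np.where(follows[None, :], valid & pok, True)
            haz = ok * pack["rates"][None, :]
            tot = haz.sum(axis=1)
            fire_mask = tot > 0
            if not fire_mask.any():
                continue
            u = self.rng.random(ids.size)
            p_any = -np.expm1(-tot * dt)
            firing = np.nonzero(u < p_any)[0]
            for row in firing:
                pid = int(ids[row])
                if used[pid]:
                    continue
                cum = np.cumsum(haz[row])
                r_idx = int(np.searchsorted(cum, self.rng.random() * tot[row]))
                r_idx = min(r_idx, len(pack["ops"]) - 1)
                op = pack["ops"][r_idx]
                self._apply_unary(op, pid, used)

    def _apply_unary(self, op: dict, pid: int, used: np.ndarray) -> None:
        namer = self.model.vertex_namer
        tname = self.type_names[self.type_id[pid]]
        if op["kind"] == "flag":
            vertex = namer(tname, self.state[pid]) if namer else None
            if op["direction"] < 0:
                # net accounting references the forward edge's source vertex
                post = self.state[pid].copy()
                for idx, val in op["assigns"]:
                    post[idx] = val
                vertex = namer(tname, post) if namer else None
            for idx, val in op["assigns"]:
                self.state[pid, idx] = val
            used[pid] = True
            self._emit(op["label"], op["direction"], vertex, pid, -1)
            return
        # unbinding
        s0, s1 = op["sites"]
        partner = int(self.bond_partner[pid, s0])
        if partner < 0 or used[partner]:
            return
        self.bond_partner[pid, s0] = -1
        self.bond_site[pid, s0] = -1
        self.bond_partner[partner, s1] = -1
        self.bond_site[partner, s1] = -1
        mols = self.model.molecules
        mol_p = mols[tname]
        mol_q = mols[self.type_names[self.type_id[partner]]]
        if mol_p.sites[s0].kind == "binding":
            self.state[pid, s0] = 0
        if mol_q.sites[s1].kind == "binding":
            self.state[partner, s1] = 0
        # clear any dependent flag assignments of the forward rule
        rule = op["rule"]
        for a in rule.assignments:
            for who, mol in ((pid, mol_p), (partner, mol_q)):
                if a.target == self.type_names[self.type_id[who]]:
                    idx = mol.site_index(a.site)
                    if idx not in (s0 if who == pid else s1,):
                        self.state[who, idx] = 1 - a.value if a.value in (0, 1) else 0
        vertex = None
        if namer is not None:
            vertex = namer(tname, self.state[pid]) or namer(
                self.type_names[self.type_id[partner]], self.state[partner])
        sep = self._unbind_radius(rule, pid, partner)
        self._split_cluster(pid, partner, sep)
        used[pid] = used[partner] = True
        self._emit(op["label"], -1, vertex, pid, partner)

    def _unbind_radius(self, rule: ReactionRule, i: int, j: int) -> float:
        tname_i = self.type_names[self.type_id[i]]
        tname_j = self.type_names[self.type_id[j]]
        _, _, r3 = self._pair_lookup(tname_i, i, tname_j, j)
        if r3 <= 0:
            mols = self.model.molecules
            d = mols[tname_i].diffusion_um2_s + mols[tname_j].diffusion_um2_s
            r3 = binding_radius(max(rule.k_f, 1e-3), max(d, 1.0), self.config.dt)
        return r3

    # kinase

    def _kinase_step(self, used: np.ndarray) -> None:
        kin = self._kin
        if kin is None:
            return
        dt = self.config.dt
        sl = kin["sub_slice"]
        ids = np.nonzero(self.alive[sl])[0] + sl.start
        if ids.size == 0:
            return
        variant = kin["spec"].variant
        if kin["spec"].neighbor_gated:
            in_ring = self.ring_id[ids] >= 0
            if not in_ring.any():
                return
            ids = ids[in_ring]
            left = self.left_idx[ids]
            c_left = self.state[left, kin["idx_c"]].astype(bool)
            p_left = self.state[left, kin["idx_p"]].astype(bool)
            if variant is KinaseRuleVariant.ml_no_phospho_kinase:
                kin_ok = c_left & ~p_left
            else:
                kin_ok = c_left | p_left
        else:
            kin_ok = np.ones(ids.size, dtype=bool)
        c = self.state[ids, kin["idx_c"]].astype(bool)
        p = self.state[ids, kin["idx_p"]].astype(bool)
        eligible = c & ~p & kin_ok & ~used[ids]
        if not eligible.any():
            return
        rows = np.nonzero(eligible)[0]
        cam_ids = self.bond_partner[ids[rows], kin["idx_c"]]
        cam_states = self.state[cam_ids][:, kin["cam_site_idx"]]
        codes = (cam_states * np.array([1, 2, 4, 8])).sum(axis=1)
        nlobe = cam_states[:, 0] + cam_states[:, 1]
        clobe = cam_states[:, 2] + cam_states[:, 3]
        if variant is KinaseRuleVariant.scheme1_NxC2_only:
            scheme_ok = clobe == 2
        elif variant is KinaseRuleVariant.scheme2_N2Cx_only:
            scheme_ok = nlobe == 2
        else:
            scheme_ok = np.ones(rows.size, dtype=bool)
        rates = kin["rate_by_code"][codes] * scheme_ok
        pfire = -np.expm1(-rates * dt)
        u = self.rng.random(rows.size)
        hit = np.nonzero(u < pfire)[0]
        for h in hit:
            sub_id = int(ids[rows[h]])
            cam_id = int(cam_ids[h])
            if used[sub_id]:
                continue
            self.state[sub_id, kin["idx_p"]] = 1
            self.state[cam_id, kin["idx_cam_kp"]] = 1
            used[sub_id] = True
            vertex = f"KN{nlobe[h]}C{clobe[h]}"
            self._emit(f"{vertex}~p", +1, vertex, sub_id, cam_id)


def _all_states(mol: MoleculeType, site_count: int):
    """All binary state vectors of one molecule type (padded to site_count)."""
    n = len(mol.sites)
    for code in range(1 << n):
        v = np.zeros(site_count, dtype=np.uint8)
        for s in range(n):
            v[s] = (code >> s) & 1
        yield v


def _select(cands, u, ksum):
    acc = 0.0
    for rule in cands:
        acc += rule.k_f / ksum
        if u <= acc + 1e-15:
            return rule
    return cands[-1]
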