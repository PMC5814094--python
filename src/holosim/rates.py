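"""Default kinetic parameters and the microscopic-reversibility machinery.

No single measured table covers this exact three-tier, nine-state scheme,
so this module ships a literature-style default set and constructs it
*exactly* on the detailed-balance manifold:

* CaM binds Ca2+ with independent lobes and cooperative (sequential) binding
  within a lobe: N1 before N2, C1 before C2.  N sites are fast and weak, C
  sites slower and tighter.
* Ca2+ affinity rises when CaM is bound to a CaMKII subunit and rises again
  when that subunit is phosphorylated (implemented as tier-wise unbinding
  slowdowns with unchanged on-rates).
* CaM-CaMKII affinity is anchored at the apoCaM value; the affinity of every
  other CaM loading state is then *derived* from the thermodynamic cycle
  (bind Ca2+ then CaMKII versus CaMKII then Ca2+), which makes every closed
  loop of the two-layer network detailed-balanced by construction.
* Per-state phosphorylation rates peak for fully loaded CaM and satisfy the
  N/C exchange symmetry k(N2C0~p) = k(N0C2~p), k(N2C1~p) = k(N1C2~p) so the
  two restricted schemes are rate-matched.

Everything lives in one editable object so a measured table can be dropped
in; :func:`check_reversibility` audits any replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = ["RateSet", "default_rates", "check_reversibility",
           "ReversibilityReport"]

CAM_STATES = [f"N{n}C{c}" for n in range(3) for c in range(3)]

#: the lobe transition each binding step performs: state -> state
STEPS = {"N1": (0, 1), "N2": (1, 2), "C1": (0, 1), "C2": (1, 2)}


@dataclass
class RateSet:
    """All rate constants of the Ca2+/CaM/CaMKII network.

    Bimolecular rates are uM^-1 s^-1, unimolecular s^-1, diffusion cm^2/s.
    """

    # free-CaM lobe steps: name -> (k_on, k_off)
    ca_steps: dict = field(default_factory=lambda: {
        "C1": (4.0, 40.0),     # Kd 10 uM
        "C2": (10.0, 10.0),    # Kd  1 uM (cooperative tightening)
        "N1": (100.0, 1000.0),  # Kd 10 uM, fast
        "N2": (150.0, 750.0),  # Kd  5 uM
    })
    # Ca2+ unbinding slowdown when CaM sits on K / phosphorylated K
    tier_koff_factor: dict = field(default_factory=lambda: {
        "free": 1.0, "K": 1.0 / 3.0, "Kp": 1.0 / 10.0})
    # CaM <-> CaMKII binding, anchored at apoCaM
    cam_k_on: float = 2.0
    cam_k_kd_apo: float = 30.0   # uM
    cam_kp_on: float = 2.0
    cam_kp_kd_apo: float = 3.0   # uM (trapping: tighter and much slower off)
    # per-CaM-state phosphorylation rates (s^-1), N/C scheme-symmetric
    phospho: dict = field(default_factory=lambda: {
        "N0C0": 0.02, "N0C1": 0.05, "N1C0": 0.05, "N1C1": 0.1,
        "N0C2": 0.5, "N2C0": 0.5, "N1C2": 1.0, "N2C1": 1.0, "N2C2": 1.5})
    # diffusion coefficients (cm^2/s); CaMKII is immobilized in the presets
    D_ca: float = 2.2e-6
    D_cam: float = 1.0e-7
    D_sub: float = 0.0

    # -- derived quantities -------------------------------------------------

    def step_rates(self, step: str, tier: str) -> tuple[float, float]:
        """(k_on, k_off) of one lobe step in one tier."""
        kon, koff = self.ca_steps[step]
        return kon, koff * self.tier_koff_factor[tier]

    def n_bound(self, state: str) -> int:
        return int(state[1]) + int(state[3])

    def _tier_affinity_gain(self, state: str, tier: str) -> float:
        """Product of (Kd_free / Kd_tier) over the occupied lobe steps."""
        gain = 1.0
        n, c = int(state[1]), int(state[3])
        for step, count in (("N1", n >= 1), ("N2", n >= 2),
                            ("C1", c >= 1), ("C2", c >= 2)):
            if count:
                kon_f, koff_f = self.step_rates(step, "free")
                kon_t, koff_t = self.step_rates(step, tier)
                gain *= (koff_f / kon_f) / (koff_t / kon_t)
        return gain

    def cam_k_rates(self, state: str, phosphorylated: bool) -> tuple[float, float]:
        """(k_on, k_off) of CaM in ``state`` binding a (phospho-)subunit.

        The off-rate follows from the cycle closure: the more Ca2+ the bound
        tier stabilizes, the tighter CaM holds on to the subunit.
        """
        tier = "Kp" if phosphorylated else "K"
        kon = self.cam_kp_on if phosphorylated else self.cam_k_on
        kd_apo = self.cam_kp_kd_apo if phosphorylated else self.cam_k_kd_apo
        kd = kd_apo / self._tier_affinity_gain(state, tier)
        return kon, kon * kd


def default_rates() -> RateSet:
    return RateSet()


# ---------------------------------------------------------------------------
# reversibility audit


@dataclass
class ReversibilityReport:
    cycles_checked: int
    violations: list  # (cycle description, residual |prod K_eq - 1|)

    @property
    def ok(self) -> bool:
        return not self.violations


def _network_edges(rs: RateSet):
    """Thermodynamic edges (u, v, ln K_assoc, ligand) of the 2-layer network.

    Vertices are CaM species names, prefixed K/Kp when subunit-bound; each
    edge consumes one ligand ("ca" or "K"/"Kp").  Phosphorylation is
    irreversible and therefore not part of any closed equilibrium loop.
    """
    edges = []
    for tier, prefix in (("free", ""), ("K", "K"), ("Kp", "Kp")):
        for state in CAM_STATES:
            n, c = int(state[1]), int(state[3])
            for step, (lo, hi) in STEPS.items():
                lobe = step[0]
                cur = n if lobe == "N" else c
                if cur != lo:
                    continue
                new = f"N{hi}C{c}" if lobe == "N" else f"N{n}C{hi}"
                kon, koff = rs.step_rates(step, tier)
                edges.append((prefix + state, prefix + new,
                              math.log(kon / koff), "ca"))
    for state in CAM_STATES:
        for phospho, prefix, ligand in ((False, "K", "K"), (True, "Kp", "Kp")):
            kon, koff = rs.cam_k_rates(state, phospho)
            edges.append((state, prefix + state, math.log(kon / koff), ligand))
    return edges


def check_reversibility(rs: RateSet, rel_tol: float = 1e-6) -> ReversibilityReport:
    """Audit every independent closed loop for detailed balance.

    For each cycle of the association network the product of equilibrium
    constants must equal 1.  Ligand stoichiometry cancels automatically
    around any closed walk here because the number of bound Ca2+ ions and
    the K/Kp attachment are functions of the vertex, so the product is
    dimensionless.  Report-only: violations are listed with the cycle and
    the residual, nothing is modified.
    """
    edges = _network_edges(rs)
    g = nx.Graph()
    lnk = {}
    for u, v, w, _ligand in edges:
        g.add_edge(u, v)
        lnk[(u, v)] = w
        lnk[(v, u)] = -w
    violations = []
    cycles = nx.cycle_basis(g)
    for cyc in cycles:
        total = 0.0
        for i in range(len(cyc)):
            u, v = cyc[i], cyc[(i + 1) % len(cyc)]
            total += lnk[(u, v)]
        residual = abs(math.expm1(total))
        if residual > rel_tol:
            violations.append((" -> ".join(cyc + [cyc[0]]), residual))
    return ReversibilityReport(cycles_checked=len(cycles), violations=violations)
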