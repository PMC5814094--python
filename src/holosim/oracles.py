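"""Independent reference computations used to validate the particle engine.

* a deterministic mass-action ODE integrator over an expanded (small)
  species network;
* a statistically exact well-mixed stochastic sampler (direct-method SSA)
  over the same network, with support for timed injections (Ca2+ pulses);
* the exact continuous-time Markov chain for directional ring
  autophosphorylation under saturating CaM (the closed-form fractions 1/2,
  2/3, -> 1 - 1/e for growing rings);
* the encounter/activation decomposition 1/k_on = 1/k_enc + 1/k_a used to
  classify reactions as activation- or diffusion-limited.

The expanded networks are small by construction; expansion refuses state
spaces beyond a guard so the combinatorial explosion the particle engine
avoids can never sneak in through the back door.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .units import MOLEC_PER_UM3_PER_UM, volume_rate_to_kon

__all__ = [
    "Reaction",
    "WellMixedModel",
    "ode_trajectories",
    "ssa_trajectories",
    "ring_phospho_steady_fraction",
    "ring_phospho_sampled_fraction",
    "RegimeReport",
    "regime_classify",
]

MAX_SPECIES = 10_000


@dataclass(frozen=True)
class Reaction:
    """A directed mass-action reaction over species indices.

    ``rate`` is the microscopic rate: s^-1 for unimolecular reactions and
    the per-pair rate (k_on / (N_A' V)) for bimolecular ones, so propensities
    are ``rate * n_i`` or ``rate * n_i * n_j`` in molecule counts.
    """

    name: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise ValueError("reactions are unimolecular or bimolecular")
        if self.rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class WellMixedModel:
    """Expanded species list + mass-action reactions in one volume."""

    species: list
    reactions: list
    volume_um3: float

    def __post_init__(self) -> None:
        if len(self.species) > MAX_SPECIES:
            raise ValueError(
                f"expanded network has {len(self.species)} species; refusing "
                f"(guard {MAX_SPECIES})")
        self.index = {s: i for i, s in enumerate(self.species)}

    def bimolecular_rate(self, kon_uM_s: float) -> float:
        """Convert k_on (uM^-1 s^-1) to the per-pair microscopic rate."""
        return kon_uM_s / (MOLEC_PER_UM3_PER_UM * self.volume_um3)


def _stoichiometry(model: WellMixedModel) -> np.ndarray:
    S = np.zeros((len(model.species), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for r in rxn.reactants:
            S[r, j] -= 1
        for p in rxn.products:
            S[p, j] += 1
    return S


def ode_trajectories(model: WellMixedModel, y0, t_grid) -> np.ndarray:
    """Deterministic mass-action trajectories in molecule counts.

    Stiff-safe (LSODA); returns an array of shape (len(t_grid), n_species).
    """
    y0 = np.asarray(y0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    S = _stoichiometry(model)
    r1 = np.array([r.reactants[0] for r in model.reactions])
    r2 = np.array([r.reactants[1] if len(r.reactants) == 2 else -1
                   for r in model.reactions])
    k = np.array([r.rate for r in model.reactions])

    def rhs(_t, y):
        v = k * y[r1]
        bi = r2 >= 0
        v[bi] *= y[r2[bi]]
        return S @ v

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=1e-8, atol=1e-8)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def ssa_trajectories(model: WellMixedModel, y0, t_end: float,
                     seed: int | np.random.Generator = 0,
                     record_times=None,
                     injections=None) -> np.ndarray:
    """One exact SSA (direct method) path, sampled at ``record_times``.

    ``injections`` is an optional list of ``(time, species_index, amount)``
    triples (e.g. instantaneous Ca2+ pulses).  Returns counts with shape
    (len(record_times), n_species).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = [float(v) for v in y0]
    n_sp = len(y)
    rxns = [(r.rate, r.reactants, r.products) for r in model.reactions]
    if record_times is None:
        record_times = np.linspace(0.0, t_end, 101)
    record_times = np.asarray(record_times, dtype=float)
    out = np.zeros((record_times.size, n_sp))
    inj = sorted(injections or [], key=lambda x: x[0])
    inj_i = 0
    rec_i = 0
    t = 0.0

    # pre-drawn random blocks keep the per-event cost low
    BLK = 16384
    exp_block = rng.exponential(size=BLK)
    uni_block = rng.random(size=BLK)
    bi = 0

    while True:
        a = []
        total = 0.0
        for rate, reac, _ in rxns:
            if rate == 0.0:
                a.append(0.0)
                continue
            if len(reac) == 1:
                prop = rate * y[reac[0]]
            else:
                i, j = reac
                if i == j:
                    prop = rate * y[i] * (y[i] - 1.0) * 0.5
                else:
                    prop = rate * y[i] * y[j]
            a.append(prop)
            total += prop
        if bi >= BLK - 2:
            exp_block = rng.exponential(size=BLK)
            uni_block = rng.random(size=BLK)
            bi = 0
        t_next = t + (exp_block[bi] / total if total > 0 else math.inf)
        bi += 1
        t_event = min(t_next,
                      inj[inj_i][0] if inj_i < len(inj) else math.inf,
                      t_end)
        while rec_i < record_times.size and record_times[rec_i] <= t_event + 1e-15:
            out[rec_i] = y
            rec_i += 1
        if inj_i < len(inj) and t_event == inj[inj_i][0] and t_event < t_next:
            _, sp, amount = inj[inj_i]
            y[sp] += amount
            inj_i += 1
            t = t_event
            continue
        if t_next >= t_end:
            break
        t = t_next
        u = uni_block[bi] * total
        bi += 1
        acc = 0.0
        for idx, prop in enumerate(a):
            acc += prop
            if u <= acc:
                _, reac, prod = rxns[idx]
                for r in reac:
                    y[r] -= 1.0
                for p in prod:
                    y[p] += 1.0
                break
    while rec_i < record_times.size:
        out[rec_i] = y
        rec_i += 1
    return out


# ---------------------------------------------------------------------------
# exact ring phosphorylation chain


@lru_cache(maxsize=32)
def ring_phospho_steady_fraction(n: int) -> float:
    """Expected steady-state phosphorylated fraction of an n-ring.

    Saturating CaM, equal per-subunit rates, and the rule that a subunit is
    eligible only while its left neighbor is CaM-bound and *unphosphorylated*
    (a phosphorylated subunit cannot act as a kinase).  The process jams when
    every unphosphorylated subunit has a phosphorylated left neighbor; the
    absorbed fraction is computed exactly over the 2^n configurations
    (embedded jump chain is uniform over eligible subunits because rates are
    equal).  Gives 1/2 for n = 2, 2/3 for n = 3, -> 1 - 1/e for large n.
    """
    if n < 2:
        raise ValueError("rings have at least 2 subunits")
    if n > 16:
        raise ValueError("exact chain limited to n <= 16; sample instead")

    from functools import lru_cache as _lc

    @_lc(maxsize=None)
    def expect(config: int) -> float:
        eligible = [i for i in range(n)
                    if not (config >> i) & 1
                    and not (config >> ((i - 1) % n)) & 1]
        if not eligible:
            return float(bin(config).count("1"))
        return sum(expect(config | (1 << i)) for i in eligible) / len(eligible)

    return expect(0) / n


def ring_phospho_sampled_fraction(n: int, n_rings: int = 2000,
                                  seed: int = 0) -> float:
    """Monte-Carlo estimate of the jamming fraction for large rings."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_rings):
        p = np.zeros(n, dtype=bool)
        while True:
            eligible = np.nonzero(~p & ~np.roll(p, 1))[0]
            if eligible.size == 0:
                break
            p[rng.choice(eligible)] = True
        total += int(p.sum())
    return total / (n * n_rings)


# ---------------------------------------------------------------------------
# regime classification


@dataclass(frozen=True)
class RegimeReport:
    """Encounter/activation decomposition of one bimolecular rate."""

    k_on: float          # uM^-1 s^-1
    k_enc: float         # uM^-1 s^-1
    k_a: float           # uM^-1 s^-1 (inf if diffusion-limited)
    ratio: float         # k_a / k_on
    classification: str  # "activation-limited" | "diffusion-limited"


def regime_classify(k_on_uM_s: float, D_mutual_um2_s: float,
                    sigma_enc_nm: float = 5.0,
                    threshold: float = 10.0) -> RegimeReport:
    """Classify a reaction by 1/k_on = 1/k_enc + 1/k_a.

    ``k_enc = 4 pi sigma_enc D`` (Smoluchowski encounter rate, converted to
    uM^-1 s^-1).  Activation-limited when the intrinsic rate is within
    ``threshold`` of the observed one (k_a/k_on < threshold); if
    ``k_on >= k_enc`` the decomposition has no positive solution and the
    reaction is flagged diffusion-limited outright.
    """
    if k_on_uM_s <= 0 or D_mutual_um2_s <= 0 or sigma_enc_nm <= 0:
        raise ValueError("positive rate, diffusion and encounter radius required")
    k_enc = volume_rate_to_kon(4.0 * math.pi * sigma_enc_nm * 1e-3 * D_mutual_um2_s)
    if k_on_uM_s >= k_enc:
        return RegimeReport(k_on_uM_s, k_enc, math.inf, math.inf,
                            "diffusion-limited")
    k_a = 1.0 / (1.0 / k_on_uM_s - 1.0 / k_enc)
    ratio = k_a / k_on_uM_s
    cls = "activation-limited" if ratio < threshold else "diffusion-limited"
    return RegimeReport(k_on_uM_s, k_enc, k_a, ratio, cls)
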