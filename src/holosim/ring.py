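"""Ring-complex geometry, neighbor-conditional phosphorylation and necklace
combinatorics.

A CaMKII holoenzyme is modeled as a ring of identical subunits placed at
fixed, equally spaced positions on a circle.  Autophosphorylation is
directional: subunit ``i`` can only be phosphorylated by its left neighbor
``(i - 1) mod n`` (direction chosen once; the converse convention is a pure
relabeling).  The number of rotationally distinct ring states is counted with
the classical necklace formula, which is what makes expanded-network
approaches infeasible for rings with many per-subunit states.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KinaseRuleVariant",
    "RingTemplate",
    "ring_positions",
    "left_neighbor",
    "phospho_condition",
    "necklace_count",
    "enumerate_ring_species",
]


class KinaseRuleVariant(enum.Enum):
    """Which neighbor condition gates autophosphorylation.

    default_neighbor
        The left neighbor must be *activated*: CaM-bound or phosphorylated
        (autonomous subunits keep kinase activity).
    ml_no_phospho_kinase
        The left neighbor must be CaM-bound AND unphosphorylated.  Under
        saturating CaM this reduces to the closed-form steady-state fractions
        of Michalski & Loew (1/2 for dimers, 2/3 for trimers, -> 1 - 1/e).
    scheme1_NxC2_only
        As default, but the substrate's bound CaM must have a fully loaded
        C lobe (states NxC2).
    scheme2_N2Cx_only
        As default, but the substrate's bound CaM must have a fully loaded
        N lobe (states N2Cx).
    """

    default_neighbor = "default_neighbor"
    ml_no_phospho_kinase = "ml_no_phospho_kinase"
    scheme1_NxC2_only = "scheme1_NxC2_only"
    scheme2_N2Cx_only = "scheme2_N2Cx_only"


@dataclass
class RingTemplate:
    """Geometry and composition of one ring complex.

    ``neighbor_distance`` defaults to the ring radius: for the canonical
    6-subunit ring the chord between adjacent subunits equals the radius
    exactly, and for the radius sweep neighbor spacing is set equal to the
    radius by convention (only geometrically exact at n = 6; documented
    limitation).
    """

    n_subunits: int = 6
    ring_radius_nm: float = 8.0
    subunit_type: str = "sub"
    mobile: bool = False
    variant: KinaseRuleVariant = KinaseRuleVariant.default_neighbor
    neighbor_distance_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_subunits < 2:
            raise ValueError("a ring needs at least 2 subunits")
        if self.ring_radius_nm <= 0:
            raise ValueError("ring radius must be positive")
        if self.neighbor_distance_nm is None:
            self.neighbor_distance_nm = self.ring_radius_nm

    @property
    def effective_radius_um(self) -> float:
        """Circumradius (um) of the polygon with the requested neighbor spacing."""
        n = self.n_subunits
        chord = self.neighbor_distance_nm * 1e-3
        return chord / (2.0 * math.sin(math.pi / n))


def ring_positions(template: RingTemplate, center: np.ndarray,
                   phase: float = 0.0) -> np.ndarray:
    """Positions (um) of the subunits of one ring, in index order.

    Subunits sit on a circle in the plane z = center_z.  The left neighbor of
    subunit ``i`` is subunit ``(i - 1) mod n``.
    """
    n = template.n_subunits
    r = template.effective_radius_um
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    pos = np.empty((n, 3))
    pos[:, 0] = center[0] + r * np.cos(ang)
    pos[:, 1] = center[1] + r * np.sin(ang)
    pos[:, 2] = center[2]
    return pos


def left_neighbor(i: int, n: int) -> int:
    return (i - 1) % n


def phospho_condition(cam_bound: bool, phospho: bool,
                      left_cam_bound: bool, left_phospho: bool,
                      variant: KinaseRuleVariant,
                      cam_state: tuple[int, int] | None = None) -> bool:
    """Is a subunit currently eligible for autophosphorylation?

    Parameters describe the subunit itself and its left neighbor.
    ``cam_state`` is the (n_lobe, c_lobe) Ca2+ loading of the bound CaM,
    needed only for the scheme variants.
    """
    if not cam_bound or phospho:
        return False
    if variant is KinaseRuleVariant.ml_no_phospho_kinase:
        kinase_ok = left_cam_bound and not left_phospho
    else:
        kinase_ok = left_cam_bound or left_phospho
    if not kinase_ok:
        return False
    if variant is KinaseRuleVariant.scheme1_NxC2_only:
        return cam_state is not None and cam_state[1] == 2
    if variant is KinaseRuleVariant.scheme2_N2Cx_only:
        return cam_state is not None and cam_state[0] == 2
    return True


def necklace_count(n: int, k: int) -> int:
    """Number of length-``n`` strings over ``k`` symbols up to rotation.

    Burnside's lemma over the cyclic group gives
    ``(1/n) * sum_{d | n} phi(d) * k^(n/d)``.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    total = 0
    for d in range(1, n + 1):
        if n % d == 0:
            total += _euler_phi(d) * k ** (n // d)
    return total // n


def _euler_phi(m: int) -> int:
    result = m
    p = 2
    mm = m
    while p * p <= mm:
        if mm % p == 0:
            while mm % p == 0:
                mm //= p
            result -= result // p
        p += 1
    if mm > 1:
        result -= result // mm
    return result


def enumerate_ring_species(n: int, k: int) -> list[tuple[int, ...]]:
    """All rotation classes of ring states, as lexicographically minimal
    rotation representatives.

    Brute-force over the ``k**n`` strings; guarded so it is only used as a
    cross-check of :func:`necklace_count` at small sizes.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    if k ** n > 10 ** 7:
        raise ValueError("state space too large to enumerate")
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for code in range(k ** n):
        digits = []
        c = code
        for _ in range(n):
            digits.append(c % k)
            c //= k
        s = tuple(digits)
        rep = min(s[i:] + s[:i] for i in range(n))
        if rep not in seen:
            seen.add(rep)
            out.append(rep)
    return out
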