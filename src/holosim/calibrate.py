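"""Binding-radius calibration for fixed-time-step Brownian dynamics.

In a fixed-step particle scheme a bimolecular reaction fires when two
reactants end a step closer than the binding radius ``sigma_b``.  The rate
constant that such a scheme actually realizes depends on ``sigma_b``, the
time step ``dt`` and the mutual diffusion coefficient ``D`` through the
steady-state depletion of the pair-correlation around a reactive target.
Calibration inverts that relation: given a requested mass-action ``k_on``,
find the ``sigma_b`` whose realized rate equals it.

The realized per-step rate is computed from the steady state of the
absorb-then-diffuse map acting on the radial pair density m(r) = 4*pi*r^2
u(r) (u -> 1 far away):

    m'(r) = integral  p(r | r') * [r' >= sigma_b] * m(r') dr'

where p is the radial transition density of an isotropic Gaussian step with
per-axis standard deviation s = sqrt(2 D dt).  The steady state is the
solution of a small linear system (the far field acts as a fixed reservoir),
and the realized rate is the absorbed volume per step divided by dt.

Limiting behavior (used as cross-checks):

* large steps (s >> sigma_b): depletion is negligible and the rate is the
  swept volume, k' = (4/3) pi sigma_b^3 / dt;
* small steps (s << sigma_b): the map converges to the Smoluchowski
  diffusion-limited rate k' = 4 pi sigma_b D.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .units import kon_to_volume_rate

__all__ = ["binding_radius", "realized_rate_per_step"]

_cache: dict[tuple, float] = {}


def _radial_cdf(r: np.ndarray, rp: np.ndarray) -> np.ndarray:
    """P(new radius < r | old radius rp) for a unit-variance Gaussian step.

    The standard radial result for isotropic 3D diffusion:
    F(r|r') = Phi(r-r') - Phi(-r-r')
              - (1/(r' sqrt(2 pi))) (exp(-(r-r')^2/2) - exp(-(r+r')^2/2)).
    """
    from scipy.special import ndtr

    a = r - rp
    b = r + rp
    return (ndtr(a) - ndtr(-b)
            - (np.exp(-0.5 * a ** 2) - np.exp(-0.5 * b ** 2))
            / (rp * np.sqrt(2.0 * np.pi)))


def _radial_kernel(x: np.ndarray, h: float) -> np.ndarray:
    """Transition matrix K[i, j] = P(land in bin i | start at x_j).

    ``x`` are midpoints of radial bins of width ``h`` (lengths in units of
    the per-axis rms step).  Destination bins are integrated exactly via the
    radial CDF, which matters near r = 0 where the density grows like r^2.
    """
    lo = (x - 0.5 * h)[:, None]
    hi = (x + 0.5 * h)[:, None]
    xj = x[None, :]
    return _radial_cdf(hi, xj) - _radial_cdf(lo, xj)


def realized_rate_per_step(b: float, n_per_unit: int = 24) -> float:
    """Dimensionless absorbed volume per step, Phi(b).

    ``b = sigma_b / s``.  The realized volumetric rate is
    ``k' = Phi(b) * s^3 / dt``.  Phi(b) -> (4/3) pi b^3 for b -> 0 and
    Phi(b) -> 2 pi b for b -> infinity (Smoluchowski in these units).

    The depletion tail around an absorber decays like 1/r, so the reservoir
    (the region held at the uniform profile) is placed several absorber radii
    out and the residual truncation is removed with the standard
    finite-reservoir correction 1/Phi_inf = 1/Phi_R - 1/(2 pi R) inverted for
    the infinite domain.
    """
    if b <= 0:
        return 0.0
    span = 4.0 * b + 6.0
    buffer_end = span + 4.0
    # the pair density varies on the unit (rms-step) scale, so a coarse grid
    # suffices everywhere; an absorber smaller than a bin is handled by
    # fractional (volume-weighted) absorption of the straddling bin
    h = 1.0 / n_per_unit
    n = int(math.ceil(buffer_end / h))
    x = (np.arange(n) + 0.5) * h
    K = _radial_kernel(x, h)
    interior = x <= span
    lo = x - 0.5 * h
    hi = x + 0.5 * h
    # per-bin mass of the uniform far-field profile (u = 1)
    m_ff = (4.0 * np.pi / 3.0) * (hi ** 3 - lo ** 3)

    # fraction of each bin's volume lying inside the absorber radius
    vol_in = np.clip(np.minimum(hi, b) ** 3 - lo ** 3, 0.0, None)
    vol_in[lo >= b] = 0.0
    frac = vol_in / (hi ** 3 - lo ** 3)

    idx_int = np.nonzero(interior)[0]
    idx_buf = np.nonzero(~interior)[0]
    Ki = K[np.ix_(idx_int, idx_int)] * (1.0 - frac[idx_int])[None, :]
    rhs = K[np.ix_(idx_int, idx_buf)] @ m_ff[idx_buf]
    A = np.eye(idx_int.size) - Ki
    m = np.linalg.solve(A, rhs)
    phi_r = float(np.sum(m * frac[idx_int]))
    # finite-reservoir correction (reservoir edge at the start of the buffer)
    inv = 1.0 / phi_r + 1.0 / (2.0 * math.pi * span)
    return 1.0 / inv


def binding_radius(k_on_uM_s: float, D_mutual_um2_s: float, dt_s: float) -> float:
    """Binding radius (um) realizing mass-action rate ``k_on`` at step ``dt``.

    ``D_mutual`` is the sum of the reactants' diffusion coefficients
    (um^2/s).  Results are cached on rounded inputs; ``k_on = 0`` maps to a
    zero radius.  Raises for non-finite inputs or for ``k_on > 0`` with two
    immobile reactants.
    """
    if not (math.isfinite(k_on_uM_s) and math.isfinite(D_mutual_um2_s)
            and math.isfinite(dt_s)):
        raise ValueError("non-finite calibration input")
    if k_on_uM_s < 0 or D_mutual_um2_s < 0 or dt_s <= 0:
        raise ValueError("k_on, D must be >= 0 and dt > 0")
    if k_on_uM_s == 0.0:
        return 0.0
    if D_mutual_um2_s == 0.0:
        raise ValueError("bimolecular rule between two immobile reactants")

    key = (round(k_on_uM_s, 9), round(D_mutual_um2_s, 9), round(dt_s, 15))
    hit = _cache.get(key)
    if hit is not None:
        return hit

    k_vol = kon_to_volume_rate(k_on_uM_s)  # um^3 / s
    s = math.sqrt(2.0 * D_mutual_um2_s * dt_s)  # per-axis rms step, um
    phi_target = k_vol * dt_s / s ** 3

    # Phi(b) <= (4/3) pi b^3 (depletion only lowers the swept density), so
    # the swept-volume radius is a true lower bound; expand upward from the
    # larger of the two limit radii.
    b_sweep = (3.0 * phi_target / (4.0 * math.pi)) ** (1.0 / 3.0)
    b_smol = phi_target / (2.0 * math.pi)
    lo = 0.999 * b_sweep
    hi = 1.5 * max(b_sweep, b_smol)

    def f(b: float) -> float:
        return realized_rate_per_step(b) - phi_target

    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 12:
        lo *= 0.5
        hi *= 2.0
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:
        raise RuntimeError("failed to bracket binding radius")
    b = brentq(f, lo, hi, xtol=1e-12, rtol=1e-6)
    sigma = b * s
    _cache[key] = sigma
    return sigma
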