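"""Unit conventions and conversions.

Internal units used throughout the package:

* length   micrometre (um)
* time     second (s)
* diffusion coefficient  um^2 s^-1  (inputs in cm^2 s^-1 are converted;
  1 cm^2 s^-1 = 1e8 um^2 s^-1)
* concentration  micromolar (uM)
* bimolecular rate constant  uM^-1 s^-1 externally, um^3 s^-1 internally

The Avogadro constant is fixed at the rounded three-significant-figure
value 6.02e23 mol^-1, so count<->concentration conversions match hand
calculations to their printed precision (3000 molecules in a 500 nm cube
= 39.867 uM).
"""

from __future__ import annotations

AVOGADRO = 6.02e23  # mol^-1 (rounded; see module docstring)

#: number of molecules per um^3 at 1 uM: N_A * 1e-6 mol/L * 1e-15 L/um^3
MOLEC_PER_UM3_PER_UM = AVOGADRO * 1e-21  # = 602.0

CM2_TO_UM2 = 1e8

ELEMENTARY_CHARGE = 1.602176634e-19  # C
FARADAY = 96485.33212  # C mol^-1


def count_to_concentration(count: float, volume_um3: float) -> float:
    """Convert a molecule count in a volume (um^3) to a concentration in uM."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    return count / (MOLEC_PER_UM3_PER_UM * volume_um3)


def concentration_to_count(conc_um: float, volume_um3: float) -> int:
    """Convert a concentration in uM to the nearest integer molecule count."""
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    return int(round(conc_um * MOLEC_PER_UM3_PER_UM * volume_um3))


def kon_to_volume_rate(kon_uM_s: float) -> float:
    """Convert a bimolecular rate constant from uM^-1 s^-1 to um^3 s^-1.

    The per-pair microscopic rate in a volume V (um^3) is this value / V.
    """
    return kon_uM_s / MOLEC_PER_UM3_PER_UM


def volume_rate_to_kon(k_um3_s: float) -> float:
    """Inverse of :func:`kon_to_volume_rate`."""
    return k_um3_s * MOLEC_PER_UM3_PER_UM
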