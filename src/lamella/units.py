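"""Mapping between reduced DPD units and physical (SI) units.

The simulation itself runs entirely in reduced units (cutoff r_c = 1,
thermal energy k_B T = 1, bead mass m = 1).  The physical scale follows
from the coarse-graining choice: one water bead lumps ``WATERS_PER_BEAD``
water molecules, and the reduced number density ``rho`` beads / r_c^3 is
matched to the mass density of liquid water at room temperature.
"""

from __future__ import annotations

import math

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23
#: Molar mass of water, kg/mol.
WATER_MOLAR_MASS_KG = 18.015e-3
#: Mass density of water at 298 K, kg/m^3.
WATER_DENSITY_KG_M3 = 997.0
#: Number of water molecules lumped into one W bead.
WATERS_PER_BEAD = 4
#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23


def bead_mass_kg(waters_per_bead: int = WATERS_PER_BEAD) -> float:
    """Physical mass of one DPD bead, in kg.

    Each bead stands for ``waters_per_bead`` water molecules (all bead
    species share this mass by the equal-volume coarse-graining
    convention), so the mass is ``n * M_w / N_A``.
    """
    return waters_per_bead * WATER_MOLAR_MASS_KG / N_AVOGADRO


def cutoff_length_m(rho: float = 3.0, waters_per_bead: int = WATERS_PER_BEAD) -> float:
    """Physical size of the cutoff radius r_c, in metres.

    Obtained by matching the simulated mass density (``rho`` beads per
    r_c^3, each of mass :func:`bead_mass_kg`) to the real density of
    water: ``rho * m_bead / r_c^3 = rho_water``.
    """
    return (rho * bead_mass_kg(waters_per_bead) / WATER_DENSITY_KG_M3) ** (1.0 / 3.0)


def energy_scale_j(temperature_k: float = 298.0) -> float:
    """Physical value of one reduced energy unit (k_B T), in joules."""
    return K_BOLTZMANN * temperature_k


def time_scale_s(
    rho: float = 3.0,
    temperature_k: float = 298.0,
    waters_per_bead: int = WATERS_PER_BEAD,
) -> float:
    """Physical duration of one reduced time unit, in seconds.

    The intrinsic DPD time is ``r_c * sqrt(m / k_B T)``.
    """
    m = bead_mass_kg(waters_per_bead)
    rc = cutoff_length_m(rho, waters_per_bead)
    return rc * math.sqrt(m / energy_scale_j(temperature_k))
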