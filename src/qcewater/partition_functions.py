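"""Per-cluster partition functions (rigid rotor / harmonic oscillator).

Each cluster contributes a product q = q_trans * q_rot * q_vib * q_elec.
Everything is computed and returned in log space: cluster q values span
hundreds of orders of magnitude (interaction energies of -250 kJ/mol alone
give factors of e^100), so raw q would overflow immediately.

Conventions
-----------
* Interaction energies are treated as ZPE-exclusive (pure electronic), the
  usual convention for tabulated cluster interaction energies, so q_vib
  includes the zero-point factor by default; ``include_zpe=False`` flips the
  convention for data sets whose energies already contain the ZPE.
* No frequency scaling by default; pass ``freq_scale`` to apply a uniform
  harmonic scale factor.
* All clusters are treated as nonlinear tops (true for every water cluster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cluster_model import Cluster
from .constants import (ATOMIC_MASS, BOLTZMANN, CM_TO_KELVIN, GAS_CONSTANT,
                        PLANCK)

__all__ = [
    "PartitionTerms",
    "thermal_wavelength",
    "q_translational",
    "q_rotational",
    "q_vibrational",
    "q_electronic",
    "ln_cluster_partition",
]


@dataclass(frozen=True)
class PartitionTerms:
    """Log-space partition function of one cluster, split by mode."""

    ln_q_trans: float
    ln_q_rot: float
    ln_q_vib: float
    ln_q_elec: float

    @property
    def ln_q_total(self) -> float:
        return self.ln_q_trans + self.ln_q_rot + self.ln_q_vib + self.ln_q_elec


def thermal_wavelength(mass_amu: float, T: float) -> float:
    """Thermal de Broglie wavelength Λ = h / sqrt(2π m k_B T), in Å."""
    m = mass_amu * ATOMIC_MASS
    return PLANCK / math.sqrt(2.0 * math.pi * m * BOLTZMANN * T) * 1e10


def q_translational(mass_amu: float, T: float, free_volume_L: float) -> float:
    """ln q_trans = ln[(2π m k_B T / h²)^{3/2} · V_free].

    ``free_volume_L`` is the exclusion-corrected volume available to the
    cluster's centre of mass, in litres per system (the solver supplies
    V - V_ex for one mole of monomers).
    """
    if mass_amu <= 0 or T <= 0 or free_volume_L <= 0:
        raise ValueError("mass, temperature and free volume must be positive")
    lam = thermal_wavelength(mass_amu, T) * 1e-10  # m
    return math.log(free_volume_L * 1e-3) - 3.0 * math.log(lam)


def q_rotational(rot_constants_GHz, sigma: int, T: float) -> float:
    """ln q_rot of a classical nonlinear top.

    q_rot = (sqrt(π)/σ) · sqrt(T³ / (Θ_A Θ_B Θ_C)) with Θ_X = h B_X / k_B.
    """
    a, b, c = rot_constants_GHz
    if min(a, b, c) <= 0 or sigma < 1 or T <= 0:
        raise ValueError("rotational constants must be positive, sigma >= 1, T > 0")
    theta = [PLANCK * bx * 1e9 / BOLTZMANN for bx in (a, b, c)]
    return (0.5 * math.log(math.pi) - math.log(sigma)
            + 0.5 * (3.0 * math.log(T) - sum(math.log(t) for t in theta)))


def q_vibrational(frequencies_cm, T: float, include_zpe: bool = True,
                  freq_scale: float = 1.0) -> float:
    """ln q_vib of independent harmonic oscillators.

    Per mode: -x/2 (zero-point factor, if included) - ln(1 - e^{-x}) with
    x = h c ν / k_B T.
    """
    nu = np.asarray(frequencies_cm, dtype=float) * freq_scale
    if nu.size and nu.min() <= 0:
        raise ValueError(f"nonpositive frequency {nu.min()} cm^-1 (imaginary mode?)")
    if T <= 0:
        raise ValueError("T must be positive")
    x = CM_TO_KELVIN * nu / T
    ln_q = -np.log1p(-np.exp(-x)).sum()
    if include_zpe:
        ln_q -= 0.5 * x.sum()
    return float(ln_q)


def q_electronic(interaction_energy_kJmol: float, n_monomers: int,
                 a_mf: float, molar_volume_L: float, T: float) -> float:
    """ln q_elec = -(ΔE_i - a_mf n_i / V_m) / (R T).

    The mean-field van der Waals term a_mf n_i / V_m (a_mf in J·L/mol²,
    V_m in L per mole of monomers) lowers each cluster's energy in
    proportion to the monomer density, mimicking attractive inter-cluster
    interactions.
    """
    if molar_volume_L <= 0 or T <= 0:
        raise ValueError("molar volume and temperature must be positive")
    de = interaction_energy_kJmol * 1e3 - a_mf * n_monomers / molar_volume_L
    return -de / (GAS_CONSTANT * T)


def ln_cluster_partition(cluster: Cluster, T: float, free_volume_L: float,
                         molar_volume_L: float, a_mf: float,
                         monomer_mass_amu: float,
                         include_zpe: bool = True,
                         freq_scale: float = 1.0) -> PartitionTerms:
    """Assemble the full log partition function of one cluster."""
    mass = cluster.n_monomers * monomer_mass_amu
    return PartitionTerms(
        ln_q_trans=q_translational(mass, T, free_volume_L),
        ln_q_rot=q_rotational(cluster.rotational_constants,
                              cluster.symmetry_number, T),
        ln_q_vib=q_vibrational(cluster.frequencies, T,
                               include_zpe=include_zpe, freq_scale=freq_scale),
        ln_q_elec=q_electronic(cluster.interaction_energy, cluster.n_monomers,
                               a_mf, molar_volume_L, T),
    )
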