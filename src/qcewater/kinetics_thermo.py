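"""Thermochemistry and Eyring kinetics for cluster reactions.

Utilities for turning stationary-point energies (electronic E and
standard-state Gibbs energy G(0), in hartree) into reaction free-energy
profiles, equilibrium constants and Eyring rate constants.  Equilibrium
constants are handled in log space throughout: the gas-phase heterolytic
dissociation of a water molecule (ΔG(0) ≈ 389 kcal/mol) corresponds to
K ~ 1e-285, far below the double-precision underflow threshold for a naive
exp() evaluation chain.

The packaged pentamer fixture (``pentamer_profile()``) holds the stationary
points of the rate-limiting cyclic-pentamer → ion-pair isomerization:
W5c (cyclic minimum) → W5p (propellane-like bridged minimum) → W5x‡
(double-proton-transfer transition state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .constants import (BOLTZMANN, CAL_TO_J, GAS_CONSTANT,
                        HARTREE_TO_KCALMOL, HARTREE_TO_KJMOL, PLANCK)

__all__ = [
    "StationaryPoint",
    "ReactionProfile",
    "convert_energy",
    "equilibrium_constant",
    "reaction_barriers",
    "eyring_rate",
    "enhancement_orders",
    "load_profile_csv",
    "pentamer_profile",
]

LN10 = math.log(10.0)

_TO_KCAL = {
    "hartree": HARTREE_TO_KCALMOL,
    "kcal/mol": 1.0,
    "kJ/mol": 1.0 / CAL_TO_J,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between hartree, kcal/mol and kJ/mol (CODATA factors)."""
    for unit in (from_unit, to_unit):
        if unit not in _TO_KCAL:
            raise ValueError(f"unknown energy unit {unit!r}; "
                             f"accepted: {sorted(_TO_KCAL)}")
    return value * _TO_KCAL[from_unit] / _TO_KCAL[to_unit]


def equilibrium_constant(dG_kcal: float, T: float) -> tuple[float, float]:
    """(K, pK) from ΔG via K = exp(-ΔG/RT).

    pK = ΔG / (RT ln 10) is computed directly in log space, so it stays
    finite and exact even where K itself underflows to 0.0 (|ΔG| up to
    ~1000 kcal/mol poses no problem).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    ln_k = -dG_kcal * 1e3 * CAL_TO_J / (GAS_CONSTANT * T)
    pk = -ln_k / LN10
    try:
        k = math.exp(ln_k)
    except OverflowError:
        k = math.inf
    return k, pk


def eyring_rate(dG_activation_kcal: float, T: float) -> float:
    """Transition-state-theory rate k = (k_B T / h) exp(-ΔG‡/RT), in 1/s.

    Transmission coefficient fixed at 1.
    """
    k_eq, _ = equilibrium_constant(dG_activation_kcal, T)
    return BOLTZMANN * T / PLANCK * k_eq


def enhancement_orders(K_num: float, K_den: float,
                       log10_inputs: bool = False) -> float:
    """Orders of magnitude between two equilibrium constants, log10(K_num/K_den).

    With ``log10_inputs=True`` the arguments are taken as log10 K (or -pK)
    values directly, which avoids underflow for extreme constants.
    """
    if log10_inputs:
        return K_num - K_den
    if K_num <= 0 or K_den <= 0:
        raise ValueError("equilibrium constants must be positive "
                         "(use log10_inputs=True for log-space values)")
    return math.log10(K_num) - math.log10(K_den)


@dataclass(frozen=True)
class StationaryPoint:
    """A minimum or transition state: electronic E and Gibbs G(0), hartree."""

    label: str
    E: float
    G0: float
    kind: str = "minimum"   # "minimum" | "transition_state"

    def __post_init__(self) -> None:
        if self.kind not in ("minimum", "transition_state"):
            raise ValueError(f"kind must be minimum|transition_state, got {self.kind!r}")


@dataclass(frozen=True)
class ReactionProfile:
    """Ordered stationary points along one reaction pathway."""

    points: tuple[StationaryPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a profile needs at least two stationary points")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]


def reaction_barriers(profile: ReactionProfile) -> pd.DataFrame:
    """Per-step energy and free-energy differences in kcal/mol.

    Each row is the step from one stationary point to the next; ΔE and
    ΔG(0) are successive differences (positive uphill), so a step ending in
    a transition state reads directly as the activation barrier ΔE‡ / ΔG‡
    referenced to the preceding point.  Adding any constant to all energies
    leaves the table unchanged.
    """
    rows = []
    for a, b in zip(profile.points, profile.points[1:]):
        rows.append({
            "from": a.label,
            "to": b.label,
            "dE_kcal_per_mol": (b.E - a.E) * HARTREE_TO_KCALMOL,
            "dG0_kcal_per_mol": (b.G0 - a.G0) * HARTREE_TO_KCALMOL,
            "is_activation": b.kind == "transition_state",
        })
    return pd.DataFrame(rows)


def load_profile_csv(path: str | Path) -> ReactionProfile:
    """Read a stationary-point CSV (label, E_hartree, G0_hartree, kind)."""
    frame = pd.read_csv(path)
    required = {"label", "E_hartree", "G0_hartree", "kind"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    points = tuple(
        StationaryPoint(r.label, float(r.E_hartree), float(r.G0_hartree), r.kind)
        for r in frame.itertuples()
    )
    return ReactionProfile(points)


def pentamer_profile() -> ReactionProfile:
    """Packaged W5c → W5p → W5x‡ pentamer isomerization profile
    (B3LYP/6-311++G** stationary-point energies)."""
    ref = resources.files("qcewater").joinpath("data/pentamer_profile.csv")
    with resources.as_file(ref) as path:
        return load_profile_csv(path)
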