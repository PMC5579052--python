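"""Temperature sweeps and derived observables: densities, phase transitions,
monomer-normalized populations, and the ionic product K_W(T).

K_W is evaluated from the converged cluster amounts as the diagonal sum

    K_W = Σ_i n_i(H3O+) n_i(OH-) N_i² / V²      [mol²/L²]

over the ion-pair clusters, with N_i in moles of cluster per mole of
monomers and V the molar volume in L per mole of monomers, so the result is
directly comparable with the experimental 1e-14 mol²/L² scale.  An optional
``mode="product"`` evaluates the conventional product of total ion
concentrations (Σ n_i(H3O+) N_i / V)·(Σ n_i(OH-) N_i / V) instead; the two
coincide whenever a single ion-pair cluster dominates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_model import ClusterSet
from .qce_core import (ConvergenceError, QCEParameters, StateResult,
                       equilibrium_state)

logger = logging.getLogger(__name__)

__all__ = [
    "Isobar",
    "KwPoint",
    "compute_isobar",
    "transition_temperature",
    "monomer_normalized_populations",
    "ion_product",
    "kw_curve",
    "kw_table",
    "EXPERIMENTAL_PKW",
]

#: experimental pK_W of liquid water at the two calibration-adjacent
#: temperatures commonly quoted for comparison plots
EXPERIMENTAL_PKW = {274.0: 14.93, 373.0: 11.98}

#: minimum relative jump in V(T) between neighbouring grid points that
#: qualifies as a gas/liquid phase transition
TRANSITION_JUMP = 0.5


@dataclass
class KwPoint:
    """Ionic product at one temperature; pKw = -lg Kw (inf when Kw = 0)."""

    T: float          # K
    Kw: float         # mol²/L²
    pKw: float

    @classmethod
    def from_kw(cls, T: float, kw: float) -> "KwPoint":
        return cls(T=T, Kw=kw, pKw=-math.log10(kw) if kw > 0 else math.inf)


@dataclass
class Isobar:
    """Converged states on an ascending temperature grid at one pressure."""

    pressure: float               # Pa
    entries: list[StateResult]
    transition_temperature: float | None = None

    def __post_init__(self) -> None:
        temps = [s.T for s in self.entries]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("isobar entries must be strictly increasing in T")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.T for s in self.entries])

    @property
    def molar_volumes(self) -> np.ndarray:
        return np.array([s.molar_volume for s in self.entries])

    def densities(self, molar_mass: float) -> np.ndarray:
        """Mass densities in g/cm³ (molar mass in g per mole of monomers)."""
        return molar_mass / self.molar_volumes * 1e-3

    def to_frame(self, molar_mass: float | None = None) -> pd.DataFrame:
        """Tabular view: T, V, density, phase and per-cluster populations."""
        rows = {}
        rows["T_K"] = self.temperatures
        rows["molar_volume_L_per_mol"] = self.molar_volumes
        if molar_mass is not None:
            rows["density_g_per_cm3"] = self.densities(molar_mass)
        rows["phase"] = [s.phase for s in self.entries]
        rows["gibbs_energy_kJ_per_mol"] = [s.gibbs_energy for s in self.entries]
        frame = pd.DataFrame(rows)
        pops = pd.DataFrame(
            [s.populations_by_label for s in self.entries],
            index=frame.index,
        ).rename(columns=lambda l: f"N[{l}]")
        return pd.concat([frame, pops], axis=1)


def compute_isobar(cs: ClusterSet, params: QCEParameters, T_grid,
                   p: float, **solver_kwargs) -> Isobar:
    """Converge every temperature of an ascending grid at pressure ``p``.

    Each branch is warm-started from its own converged state at the previous
    grid point, which keeps the branch identity stable across the sweep.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.ndim != 1 or T_grid.size == 0 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be a nonempty ascending 1-D grid")
    from .qce_core import converge_state

    entries: list[StateResult] = []
    warm: dict[str, StateResult] = {}
    for T in T_grid:
        branches: dict[str, StateResult] = {}
        for branch in ("gas", "liquid"):
            prev = warm.get(branch)
            try:
                if prev is not None:
                    st = converge_state(cs, params, T, p, prev.molar_volume,
                                        populations0=prev.populations,
                                        **solver_kwargs)
                else:
                    st = converge_state(cs, params, T, p, branch,
                                        **solver_kwargs)
                st.phase = "gas-like" if branch == "gas" else "liquid-like"
                branches[branch] = st
            except ConvergenceError as exc:
                logger.warning("isobar: %s branch dropped at T=%.2f K (%s)",
                               branch, T, exc)
        if not branches:
            raise ConvergenceError(
                f"no branch converged at T={T} K, p={p} Pa")
        warm = branches
        best = min(branches.values(), key=lambda s: s.gibbs_energy)
        if len(branches) == 2:
            gas, liq = branches["gas"], branches["liquid"]
            if abs(gas.gibbs_energy - liq.gibbs_energy) <= 1e-12:
                logger.info("G tie at T=%.2f K; preferring liquid-like", T)
                best = liq
        entries.append(best)
    isobar = Isobar(pressure=p, entries=entries)
    isobar.transition_temperature = transition_temperature(
        isobar, cs=cs, params=params, **solver_kwargs)
    return isobar


def transition_temperature(isobar: Isobar, cs: ClusterSet | None = None,
                           params: QCEParameters | None = None,
                           refine_to: float = 0.01,
                           **solver_kwargs) -> float | None:
    """Phase-transition temperature from the largest jump in V(T).

    Looks for the largest relative molar-volume jump between adjacent grid
    points; jumps below 50 % do not qualify (result ``None``).  When the
    cluster set and parameters are supplied, the bracketing interval is
    refined by bisection on the Gibbs-energy crossing of the two branches
    until it is narrower than ``refine_to`` (K); on equal jumps the lower-T
    one is chosen (warning logged).
    """
    if len(isobar.entries) < 2:
        return None
    V = isobar.molar_volumes
    T = isobar.temperatures
    jumps = np.abs(np.diff(V)) / np.minimum(V[:-1], V[1:])
    best = int(np.argmax(jumps))
    if jumps[best] < TRANSITION_JUMP:
        return None
    ties = np.flatnonzero(np.isclose(jumps, jumps[best], rtol=1e-12))
    if ties.size > 1:
        logger.warning("equal volume jumps at %s; choosing the lowest T",
                       [f"{T[k]:.1f}-{T[k + 1]:.1f} K" for k in ties])
        best = int(ties[0])
    lo_state, hi_state = isobar.entries[best], isobar.entries[best + 1]
    t_lo, t_hi = T[best], T[best + 1]
    if cs is None or params is None:
        return 0.5 * (t_lo + t_hi)
    from .qce_core import converge_state

    warm = {"lo": lo_state, "hi": hi_state}
    while t_hi - t_lo > refine_to:
        t_mid = 0.5 * (t_lo + t_hi)
        sides = {}
        for side in ("lo", "hi"):
            ref = warm[side]
            try:
                sides[side] = converge_state(
                    cs, params, t_mid, isobar.pressure, ref.molar_volume,
                    populations0=ref.populations, **solver_kwargs)
            except ConvergenceError:
                pass
        if not sides:  # cannot refine further; return the bracket midpoint
            break
        if len(sides) == 1:
            dense_is_stable = "lo" in sides
        else:
            dense_is_stable = (sides["lo"].gibbs_energy
                               <= sides["hi"].gibbs_energy)
        if dense_is_stable:
            t_lo = t_mid
            if "lo" in sides:
                warm["lo"] = sides["lo"]
        else:
            t_hi = t_mid
            if "hi" in sides:
                warm["hi"] = sides["hi"]
    return 0.5 * (t_lo + t_hi)


def monomer_normalized_populations(state: StateResult) -> dict[str, float]:
    """pop_i = n_i N_i / Σ_j n_j N_j: fraction of monomers bound in cluster i."""
    weighted = state.stoichiometries * state.populations
    total = weighted.sum()
    return dict(zip(state.labels, (weighted / total).tolist()))


def ion_product(state: StateResult, cs: ClusterSet,
                mode: str = "diagonal") -> KwPoint:
    """Ionic product K_W of one converged state.

    ``mode="diagonal"`` (default): K_W = Σ_i n_i(H3O+) n_i(OH-) N_i² / V².
    ``mode="product"``: product of the total hydronium and hydroxide
    concentrations.  Both in mol²/L².
    """
    if mode not in ("diagonal", "product"):
        raise ValueError(f"mode must be 'diagonal' or 'product', got {mode!r}")
    V = state.molar_volume
    n_h3o = np.array([c.n_hydronium for c in cs.clusters], dtype=float)
    n_oh = np.array([c.n_hydroxide for c in cs.clusters], dtype=float)
    N = state.populations
    if mode == "diagonal":
        kw = float((n_h3o * n_oh) @ (N ** 2)) / V ** 2
    else:
        kw = float(n_h3o @ N) * float(n_oh @ N) / V ** 2
    return KwPoint.from_kw(state.T, kw)


def kw_curve(isobar: Isobar, cs: ClusterSet,
             mode: str = "diagonal") -> list[KwPoint]:
    """One KwPoint per isobar entry."""
    return [ion_product(s, cs, mode=mode) for s in isobar.entries]


def kw_table(isobar: Isobar, cs: ClusterSet,
             mode: str = "diagonal") -> pd.DataFrame:
    """CSV-ready table: T_K, Kw, pKw (+ experimental reference where known)."""
    points = kw_curve(isobar, cs, mode=mode)
    frame = pd.DataFrame({
        "T_K": [pt.T for pt in points],
        "Kw_mol2_L2": [pt.Kw for pt in points],
        "pKw": [pt.pKw for pt in points],
    })
    frame["pKw_experimental"] = [
        EXPERIMENTAL_PKW.get(round(t), np.nan) for t in frame["T_K"]
    ]
    return frame
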