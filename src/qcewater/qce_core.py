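"""Self-consistent cluster-equilibrium solver at fixed (T, p).

The model: a system of N_total moles of monomers distributed over clusters
i with stoichiometries n_i.  Minimising the Helmholtz energy of the ideal
cluster mixture under the mass constraint Σ n_i N_i = N_total gives the
mass-action conditions

    ln N_i = ln q_i + n_i (ln N_1 - ln q_1)        (particle counts)

coupled to a van der Waals equation of state for the volume: the
translational free volume is V - V_ex with V_ex = b_xv Σ N_i v_i, and a
mean-field attraction -a_mf n_i / V enters each cluster's electronic
energy.  Pressure balance then yields the cubic

    p V²(V - V_ex) - RT (Σ N_i) V² + a_mf N_mono V - a_mf N_mono V_ex = 0.

Populations and volume are iterated to a damped fixed point.  Two starting
branches (gas-like: V = RT/p; liquid-like: V slightly above the packed
cluster volume) are followed independently; the physical phase at (T, p) is
the converged branch of minimal Gibbs energy, with the denser (liquid-like)
branch preferred on exact ties.

All population algebra is carried out in log space: cluster q values span
hundreds of orders of magnitude and would overflow any direct evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .cluster_model import ClusterSet
from .constants import (A3_TO_L_PER_MOL, ATOMIC_MASS, AVOGADRO, BOLTZMANN,
                        GAS_CONSTANT, PLANCK)
from .partition_functions import q_rotational, q_vibrational

logger = logging.getLogger(__name__)

__all__ = [
    "QCEParameters",
    "StateResult",
    "ConvergenceError",
    "solve_populations",
    "volume_roots",
    "converge_state",
    "equilibrium_state",
    "helmholtz_energy",
    "gibbs_energy",
]

LN_AVOGADRO = math.log(AVOGADRO)


class ConvergenceError(RuntimeError):
    """The fixed-point iteration failed; carries the last residuals."""


@dataclass(frozen=True)
class QCEParameters:
    """The two empirical van der Waals corrections of the cluster model.

    a_mf : mean-field attraction, J·L/mol² (per monomer, ∝ 1/V energy term)
    b_xv : exclusion-volume scale, dimensionless multiplier on Σ N_i v_i
    """

    a_mf: float = 0.0
    b_xv: float = 0.0

    def __post_init__(self) -> None:
        if self.a_mf < 0:
            raise ValueError("a_mf must be >= 0")
        if self.b_xv < 0:
            raise ValueError("b_xv must be >= 0")


@dataclass
class StateResult:
    """One converged (T, p) state of the cluster equilibrium."""

    T: float                      # K
    p: float                      # Pa
    molar_volume: float           # L per mole of monomers
    populations: np.ndarray       # moles of cluster i per mole of monomers
    labels: list[str]
    stoichiometries: np.ndarray   # n_i, monomers per cluster i
    phase: str                    # "gas-like" | "liquid-like"
    gibbs_energy: float           # kJ per mole of monomers
    helmholtz_energy: float       # kJ per mole of monomers
    converged: bool
    iterations: int
    exclusion_volume: float = 0.0  # L per mole of monomers

    @property
    def populations_by_label(self) -> dict[str, float]:
        return dict(zip(self.labels, self.populations.tolist()))

    def to_record(self) -> dict:
        """JSON-serialisable record of this state."""
        return {
            "T_K": self.T, "p_Pa": self.p,
            "molar_volume_L_per_mol": self.molar_volume,
            "phase": self.phase,
            "gibbs_energy_kJ_per_mol": self.gibbs_energy,
            "helmholtz_energy_kJ_per_mol": self.helmholtz_energy,
            "converged": self.converged, "iterations": self.iterations,
            "populations": self.populations_by_label,
        }


# ----------------------------------------------------------------------
# populations
# ----------------------------------------------------------------------

def solve_populations(ln_q: np.ndarray, n: np.ndarray, N_total: float = 1.0,
                      x0: float | None = None) -> np.ndarray:
    """Solve the mass-action system for cluster amounts (moles).

    Given log partition functions ``ln_q`` (monomer first) and
    stoichiometries ``n``, finds N_i with ln Ñ_i = ln q_i + n_i(ln Ñ_1 -
    ln q_1) (Ñ = particle count) and Σ n_i N_i = N_total.  The constraint is
    strictly increasing in ln Ñ_1, so the root is unique; it is bracketed
    and polished with Brent's method in log space.
    """
    ln_q = np.asarray(ln_q, dtype=float)
    n = np.asarray(n, dtype=float)
    if n[0] != 1:
        raise ValueError("the first cluster must be the monomer (n=1)")
    if N_total <= 0:
        raise ValueError("N_total must be positive")
    ln_ntot = math.log(N_total) + LN_AVOGADRO
    c = np.log(n) + ln_q - n * ln_q[0]

    def g(x: float) -> float:
        return logsumexp(c + n * x) - ln_ntot

    hi = ln_ntot  # monomer term alone already reaches N_total here
    lo = None
    if x0 is not None and x0 < hi and g(x0) < 0:
        lo = x0
    if lo is None:
        lo = hi - 50.0
        for _ in range(200):
            if g(lo) < 0:
                break
            lo -= 50.0
        else:
            raise ConvergenceError("no bracket for ln N_1: pathological q values")
    x = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    ln_pops = ln_q + n * (x - ln_q[0]) - LN_AVOGADRO
    return np.exp(ln_pops)


# ----------------------------------------------------------------------
# volume
# ----------------------------------------------------------------------

def volume_roots(populations: np.ndarray, cluster_volumes_A3: np.ndarray,
                 n: np.ndarray, params: QCEParameters, T: float,
                 p: float) -> np.ndarray:
    """Real positive roots (L per mole of monomers) of the vdW volume cubic.

    Roots not exceeding the exclusion volume are discarded; the result is
    sorted ascending (dense root first).
    """
    populations = np.asarray(populations, dtype=float)
    v_L = np.asarray(cluster_volumes_A3, dtype=float) * A3_TO_L_PER_MOL
    n = np.asarray(n, dtype=float)
    ntot = populations.sum()
    n_mono = float(n @ populations)
    vex = params.b_xv * float(populations @ v_L)
    p_L = p * 1e-3  # J/L
    rt = GAS_CONSTANT * T
    if params.a_mf == 0.0:
        return np.array([vex + rt * ntot / p_L])
    coeffs = [p_L, -(p_L * vex + rt * ntot),
              params.a_mf * n_mono, -params.a_mf * n_mono * vex]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) <= 1e-8 * np.abs(roots.real)].real
    good = np.sort(real[real > vex * (1.0 + 1e-12)])
    if good.size == 0:
        raise ConvergenceError(
            f"no admissible volume root at T={T} K, p={p} Pa (V_ex={vex:.4g} L/mol)"
        )
    return good


# ----------------------------------------------------------------------
# fixed point
# ----------------------------------------------------------------------

class _ThermalContext:
    """Per-temperature precomputation of the V-independent ln q pieces."""

    def __init__(self, cs: ClusterSet, params: QCEParameters, T: float,
                 include_zpe: bool, freq_scale: float):
        self.T = T
        self.params = params
        self.n = np.array([c.n_monomers for c in cs.clusters], dtype=float)
        self.v_A3 = np.array([c.volume for c in cs.clusters], dtype=float)
        self.v_L = self.v_A3 * A3_TO_L_PER_MOL
        rt = GAS_CONSTANT * T
        base = np.empty(len(cs.clusters))
        for i, c in enumerate(cs.clusters):
            m = c.n_monomers * cs.monomer.mass * ATOMIC_MASS
            ln_t = 1.5 * math.log(2.0 * math.pi * m * BOLTZMANN * T / PLANCK ** 2)
            base[i] = (ln_t
                       + q_rotational(c.rotational_constants, c.symmetry_number, T)
                       + q_vibrational(c.frequencies, T, include_zpe=include_zpe,
                                       freq_scale=freq_scale)
                       - c.interaction_energy * 1e3 / rt)
        self.base = base
        self.amf_n_over_rt = params.a_mf * self.n / rt

    def ln_q(self, V: float, vex: float) -> np.ndarray:
        vfree = V - vex
        if vfree <= 0:
            vfree = 1e-12 * V  # transient overshoot; damping pulls V back out
        return self.base + math.log(vfree * 1e-3) + self.amf_n_over_rt / V


def _free_energies(ctx: _ThermalContext, pops: np.ndarray, V: float,
                   vex: float, p: float) -> tuple[float, float]:
    """Helmholtz and Gibbs energy, kJ per mole of monomers (Stirling)."""
    ln_q = ctx.ln_q(V, vex)
    mask = pops > 0
    npart = pops[mask] * AVOGADRO
    a = -GAS_CONSTANT * ctx.T * float(
        pops[mask] @ (ln_q[mask] - np.log(npart) + 1.0))
    g = a + p * 1e-3 * V
    return a * 1e-3, g * 1e-3


def converge_state(cs: ClusterSet, params: QCEParameters, T: float, p: float,
                   initial_volume: float | str = "gas", *,
                   populations0: np.ndarray | None = None,
                   N_total: float = 1.0, damping: float = 0.5,
                   tol: float = 1e-10, max_iter: int = 500,
                   include_zpe: bool = True, freq_scale: float = 1.0,
                   ) -> StateResult:
    """Converge one branch of the (populations ↔ volume) fixed point.

    ``initial_volume`` is a preset ("gas": V₀ = RT/p; "liquid": V₀ = 1.1 ×
    packed cluster volume) or an explicit volume in L per mole of monomers.
    Raises :class:`ConvergenceError` if the damped iteration has not
    converged after ``max_iter`` sweeps.
    """
    ctx = _ThermalContext(cs, params, T, include_zpe, freq_scale)
    p_L = p * 1e-3
    v_ideal = GAS_CONSTANT * T * N_total / p_L
    packed = params.b_xv * ctx.v_L[0] * N_total
    if initial_volume == "gas":
        V = v_ideal
    elif initial_volume == "liquid":
        V = 1.1 * packed if packed > 0 else 0.5 * v_ideal
    else:
        V = float(initial_volume)
        if V <= 0:
            raise ValueError("initial volume must be positive")
    phase = "liquid-like" if V < 0.5 * v_ideal else "gas-like"

    pops = populations0
    if pops is None:
        pops = np.zeros(len(cs.clusters))
        pops[0] = N_total
    x = None
    rel_dv = rel_dx = math.inf
    for it in range(1, max_iter + 1):
        vex = params.b_xv * float(pops @ ctx.v_L)
        ln_q = ctx.ln_q(V, vex)
        pops = solve_populations(ln_q, ctx.n, N_total, x0=x)
        x_new = math.log(pops[0]) + LN_AVOGADRO
        vex = params.b_xv * float(pops @ ctx.v_L)
        roots = volume_roots(pops, ctx.v_A3, ctx.n, params, T, p)
        v_target = roots[np.argmin(np.abs(np.log(roots) - math.log(V)))]
        v_new = V + damping * (v_target - V)
        rel_dv = abs(v_new - V) / V
        rel_dx = abs(x_new - x) if x is not None else math.inf
        V, x = v_new, x_new
        if rel_dv <= tol and rel_dx <= tol:
            break
    else:
        raise ConvergenceError(
            f"no fixed point after {max_iter} iterations at T={T} K, p={p} Pa "
            f"({phase} start): rel dV={rel_dv:.2e}, rel d(ln N1)={rel_dx:.2e}"
        )

    vex = params.b_xv * float(pops @ ctx.v_L)
    a_kj, g_kj = _free_energies(ctx, pops, V, vex, p)
    return StateResult(
        T=T, p=p, molar_volume=V, populations=pops, labels=cs.labels,
        stoichiometries=ctx.n.copy(), phase=phase, gibbs_energy=g_kj,
        helmholtz_energy=a_kj, converged=True, iterations=it,
        exclusion_volume=vex,
    )


def equilibrium_state(cs: ClusterSet, params: QCEParameters, T: float,
                      p: float, *, warm: dict[str, StateResult] | None = None,
                      **kwargs) -> StateResult:
    """Best converged state at (T, p): both branches tried, minimal G wins.

    ``warm`` optionally carries the previous converged state per branch
    (e.g. the neighbouring grid point of an isobar) to warm-start the
    iteration.  Ties in G (within 1e-12 kJ/mol) resolve to the denser
    liquid-like branch, with a log notice.
    """
    branches: dict[str, StateResult] = {}
    for branch in ("gas", "liquid"):
        prev = warm.get(branch) if warm else None
        try:
            if prev is not None:
                st = converge_state(cs, params, T, p, prev.molar_volume,
                                    populations0=prev.populations, **kwargs)
            else:
                st = converge_state(cs, params, T, p, branch, **kwargs)
            st.phase = "gas-like" if branch == "gas" else "liquid-like"
            branches[branch] = st
        except ConvergenceError as exc:
            logger.warning("branch %s dropped at T=%s K: %s", branch, T, exc)
    if not branches:
        raise ConvergenceError(f"no branch converged at T={T} K, p={p} Pa")
    if len(branches) == 1:
        return next(iter(branches.values()))
    gas, liq = branches["gas"], branches["liquid"]
    if abs(gas.gibbs_energy - liq.gibbs_energy) <= 1e-12:
        logger.info("G tie at T=%s K; preferring liquid-like branch", T)
        return liq
    return liq if liq.gibbs_energy < gas.gibbs_energy else gas


def helmholtz_energy(state: StateResult, cs: ClusterSet, params: QCEParameters,
                     include_zpe: bool = True, freq_scale: float = 1.0) -> float:
    """Recompute A (kJ per mole of monomers) from a converged state."""
    ctx = _ThermalContext(cs, params, state.T, include_zpe, freq_scale)
    a, _ = _free_energies(ctx, state.populations, state.molar_volume,
                          state.exclusion_volume, state.p)
    return a


def gibbs_energy(state: StateResult, cs: ClusterSet, params: QCEParameters,
                 include_zpe: bool = True, freq_scale: float = 1.0) -> float:
    """Recompute G = A + pV (kJ per mole of monomers) from a converged state."""
    a = helmholtz_energy(state, cs, params, include_zpe, freq_scale)
    return a + state.p * 1e-3 * state.molar_volume * 1e-3
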