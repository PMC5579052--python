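# Methods

This note documents the model implemented in `qcewater`, the choices made
where the design was genuinely open, and what the packaged synthetic data
can and cannot establish.

## Cluster model and partition functions

A QCE system is one mole of monomers (H2O) distributed over a fixed set of
clusters. Each cluster contributes a canonical partition function assembled
from four factors, all handled in log space (`partition_functions`):

* **Translation** — ln q_trans = (3/2) ln(2π m k_B T / h²) + ln V_free,
  with m the cluster mass and V_free = V − V_ex the exclusion-corrected
  volume of the system. Cluster q values span hundreds of orders of
  magnitude, so raw (non-logarithmic) arithmetic would overflow long before
  any physically interesting state is reached.
* **Rotation** — classical nonlinear rigid top,
  q_rot = (√π/σ)·√(T³/(Θ_A Θ_B Θ_C)), Θ_X = hB_X/k_B. All water clusters
  are nonlinear; atomic or linear records are rejected with a clear message
  rather than silently mis-treated.
* **Vibration** — independent harmonic oscillators. Interaction energies
  are taken as ZPE-exclusive (pure electronic), the usual convention for
  tabulated cluster interaction energies, so the zero-point factor
  e^(−hcν/2k_BT) is included in q_vib by default; `include_zpe=False`
  flips the convention for data sets whose energies already contain ZPE.
  No frequency scaling is applied by default; a uniform `freq_scale` is
  available. Low-frequency modes are kept harmonic (no free-rotor
  interpolation) — a documented limitation.
* **Electronic** — ln q_elec = −(ΔE_i − a_mf·n_i/V)/(RT). The mean-field
  term a_mf·n_i/V (a_mf in J·L/mol², V in L per mole of monomers) lowers
  every cluster's energy in proportion to the monomer density and is one
  of the two empirical parameters.

Canonical internal units: kJ/mol, cm⁻¹, GHz, Å³, amu, K, Pa. Unit
conversion happens only at the I/O boundary (accepted energy tags:
hartree, kJ/mol, kcal/mol; 1 hartree = 2625.4996 kJ/mol = 627.5095
kcal/mol). Physical constants are pinned to CODATA 2018 in one shared
table (`constants`).

## Self-consistent solution

Minimising the Helmholtz energy of the ideal cluster mixture under mass
conservation Σ n_i N_i = N_total yields mass-action conditions
ln N_i = ln q_i + n_i(ln N_1 − ln q_1) in particle counts. The constraint
function is strictly increasing in ln N_1, so the root is unique; it is
bracketed and polished with Brent's method in log space to a relative
residual below 1e−12. Amounts enter the Stirling form of the mixing
entropy as dimensionless particle counts (moles × Avogadro), consistently
between the population solver and the free energies.

The volume satisfies the van der Waals pressure balance

    p V²(V − V_ex) − RT(Σ N_i)V² + a_mf N_mono V − a_mf N_mono V_ex = 0,

V_ex = b_xv Σ N_i v_i. Populations and volume are iterated to a damped
fixed point (damping 0.5 on volume updates, configurable); convergence
requires relative changes in both V and ln N_1 below 1e−10 within 500
iterations, and non-convergence is reported with the last residuals, never
silently accepted. Both a gas-like start (V = RT/p) and a liquid-like
start (V = 1.1 × packed monomer volume) are always attempted; branches
keep their identity along a temperature sweep via warm starts, and the
converged branch of minimal Gibbs energy G = A + pV is the reported phase.
Exact ties (within 1e−12 kJ/mol) resolve to the denser liquid-like branch,
with a log notice. These thresholds and the iteration scheme are
engineering choices of this implementation.

Phase transitions are located as the largest relative jump of V(T)
between adjacent grid points (threshold 50%), refined by bisection on the
Gibbs-energy crossing of the two branches to a 0.01 K bracket. Equal
jumps resolve to the lower temperature, with a warning.

## The ionic product

K_W is evaluated from the converged amounts of the net-neutral ion-pair
clusters as the diagonal sum

    K_W = Σ_i n_i(H3O⁺) n_i(OH⁻) N_i² / V²   [mol²/L²],

with N_i in moles of cluster per mole of monomers and V the molar volume
in L per mole of monomers — the unit choice that makes the 1e−14 mol²/L²
experimental scale directly comparable. When two or more ion-pair
clusters are populated this diagonal form differs from the product of the
total ion concentrations; both are provided (`mode="diagonal"` is the
default, `mode="product"` the conventional alternative) and they coincide
whenever a single ion-pair cluster dominates. pK_W of an ion-pair-free
state is reported as +inf, never raised as an error.

## Parameter calibration

The two parameters are determined from two standard-state references: the
liquid density at T_ref (water: 0.99705 g/cm³ at 298.15 K) and the boiling
temperature of the isobar (373.15 K at 1 atm). The objective is
w_ρ·((ρ−ρ_ref)/ρ_ref)² + w_T·((T_b−T_b,ref)/T_b,ref)², with a fixed 1e6
penalty when no transition exists (skipped when w_T = 0, which makes the
fit density-only). The search is a deterministic coarse lattice over the
bounds box (default 20×20) followed by Nelder–Mead refinement from the
best cell.

Default bounds: a_mf ∈ [0, 500] J·L/mol², b_xv ∈ [0.1, 2.0]. The a_mf
scale is set by the existence condition for a dense liquid root of the
volume cubic: the mean-field internal pressure a_mf·N_mono/V² must reach
the 1 GPa range typical of a cohesive liquid at V ≈ 0.018 L/mol, which
requires a_mf of order 10²; boxes far below that admit no liquid branch
at all on water-like cluster sets.

The packaged synthetic fixture (seed 1) calibrates to
a_mf = 448.8 J·L/mol², b_xv = 1.477 against the water references; the
rounded pair (450.0, 1.48) is used as the fixture's reference
parameterization throughout the examples and gives ρ(298 K) = 0.995
g/cm³ and T_b = 373.3 K.

## Synthetic cluster sets

`synthetic_cluster_set(seed, max_size, ip_destabilization)` emulates the
canonical 18-cluster water topology: a monomer; a dimer; Grotthus-ordered
rings (n hydrogen bonds) for n = 3..max_size; open-chain isomers (n−1
bonds) for n = 3, 4; and for every n ≥ 5 one ion-pair isomer whose
interaction energy is the ring's plus `ip_destabilization`. Defaults:

* hydrogen-bond energy drawn near 25 kJ/mol per bond;
* 3n intramolecular modes jittered around the monomer's bend/stretch
  frequencies, 6n−6 intermolecular modes split between translational
  (40–280 cm⁻¹) and librational (300–900 cm⁻¹) bands;
* rotational constants decaying as n^(−5/3) from the monomer's values;
* volumes ≈ n·20 Å³;
* `ip_destabilization` = 40 kJ/mol, which Boltzmann-suppresses the
  ion-pair populations into the 1e−7 mol/L concentration regime and hence
  pK_W values in the physically relevant 12–20 window — the regime the
  solver must resolve.

The generator is a pure function of its arguments; the destabilization
enters only additively in the ion-pair energies, so two sets differing
only in that argument are identical cluster for cluster otherwise (the
property behind the monotonicity tests).

What the fixture does *not* emulate: many-body cooperativity beyond the
per-bond energy scale, isomer families at fixed n beyond one ring/chain
pair, polycyclic cage motifs, anharmonicity, and any quantitative
correspondence with quantum-chemistry cluster data. Consequently, tests
passing on the fixture establish the correctness and stability of the
*machinery* (solver invariants, calibration recovery, response
properties), not quantitative pK_W predictions for real water; those
require externally computed cluster energetics loaded through the
manifest format.

## Molecular volumes

Cluster volumes are integrated as the union of Bondi vdW spheres (H 1.20
Å, O 1.52 Å, …) on a regular grid, default spacing 0.05 Å (single-sphere
error well below 0.5%, converging as spacing → 0). A solvent-excluded
surface is deliberately not computed: only consistent *relative* volumes
matter to the equation of state, because any uniform scale error is
absorbed by the fitted b_xv. An "inflated" mode adds a probe radius
(conventionally 1.4 Å) to every sphere for users who want a
probe-extended envelope.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes that still exercise every code path: the
full 18-cluster fixture at 1 K resolution for the conservation sweep;
coarser 4–12 K grids anchored on the reference temperatures for the
calibration harnesses (a 6×6 coarse lattice and Nelder–Mead refinement
for the recovery experiment); ≤ 3-cluster systems for the brute-force
population oracle.

## Known limitations

* Harmonic vibrations throughout; low-frequency cluster modes are the
  largest source of model error for free energies.
* Single-component systems only; no T-dependent a_mf/b_xv.
* The diagonal K_W sum and the ion-concentration product differ when
  several ion-pair clusters are simultaneously populated; both are
  reported but the choice is a convention, not a derived result.
* No reading of quantum-chemistry program output; users transcribe
  cluster records into the manifest format.
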