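"""Physical constants (CODATA 2018) and unit-conversion factors.

Single shared table: every module imports from here so that partition
functions, equation-of-state algebra and kinetics use identical values.
"""

# --- CODATA 2018 exact / recommended values (SI) ---
PLANCK = 6.62607015e-34           # J s
BOLTZMANN = 1.380649e-23          # J / K
AVOGADRO = 6.02214076e23          # 1 / mol
GAS_CONSTANT = BOLTZMANN * AVOGADRO   # J / (mol K)  = 8.31446261815324
SPEED_OF_LIGHT_CM = 2.99792458e10     # cm / s
ATOMIC_MASS = 1.66053906660e-27       # kg per amu

# hc/k_B in cm K — converts a wavenumber to a vibrational temperature
CM_TO_KELVIN = PLANCK * SPEED_OF_LIGHT_CM / BOLTZMANN   # ≈ 1.43877688 cm K

# --- energy units ---
HARTREE_TO_KJMOL = 2625.4996      # kJ/mol per hartree
HARTREE_TO_KCALMOL = 627.5095     # kcal/mol per hartree
CAL_TO_J = 4.184                  # thermochemical calorie
KCALMOL_TO_KJMOL = CAL_TO_J       # kJ/mol per kcal/mol

# --- pressure / volume ---
ATM = 101325.0                    # Pa
PA_TO_J_PER_L = 1.0e-3            # 1 Pa = 1e-3 J/L (p·V[L] in J needs p in J/L)
A3_TO_L_PER_MOL = AVOGADRO * 1.0e-27  # Å³/particle → L/mol

# --- reference data for water ---
WATER_MOLAR_MASS = 18.0153        # g/mol
WATER_DENSITY_298 = 0.99705       # g/cm³ at 298.15 K, 1 atm
WATER_BOILING_T = 373.15          # K at 1 atm
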