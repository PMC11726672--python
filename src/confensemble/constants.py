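"""Pinned physical constants (CODATA 2018) and unit conversions.

All thermochemistry in this package flows through these values so that
results are reproducible bit-for-bit across environments regardless of
the CODATA revision shipped by the numerics stack.
"""

# SI defining constants (exact since the 2019 redefinition)
PLANCK_J_S = 6.62607015e-34  # h, J s
BOLTZMANN_J_K = 1.380649e-23  # k_B, J K^-1
AVOGADRO = 6.02214076e23  # N_A, mol^-1
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # c, cm s^-1

# CODATA 2018 measured constants
ATOMIC_MASS_KG = 1.66053906660e-27  # u -> kg

# Unit conversions
ATM_PA = 101325.0  # atm -> Pa (exact)
CAL_J = 4.184  # thermochemical calorie (exact)
HARTREE_TO_KCAL = 627.5095  # E_h -> kcal mol^-1 (pinned, field convention)

# Gas constant on the thermochemistry scale
R_KCAL = 1.9872041e-3  # kcal mol^-1 K^-1
R_CAL = 1.9872041  # cal mol^-1 K^-1

# hc*N_A: energy of one wavenumber, kcal mol^-1 per cm^-1
CM1_TO_KCAL = (
    PLANCK_J_S * SPEED_OF_LIGHT_CM_S * AVOGADRO / (CAL_J * 1000.0)
)

PROTON_MASS_U = 1.00728  # bare proton, u

# Experimental proton reference values at 298 K (aqueous pKa cycles)
DG_SOLV_PROTON_KCAL = -265.6  # solvation free energy of H+
G_GAS_PROTON_KCAL = -6.28  # gas-phase Gibbs free energy of H+
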