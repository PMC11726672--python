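"""Aqueous pKa from a proton-based thermodynamic cycle.

The dissociation HA⁺ → A + H⁺ is decomposed into a gas-phase leg and
three solvation legs:

    ΔG_gas  = G_gas(A) + G_gas(H⁺) − G_gas(HA⁺)
    ΔΔG_sol = ΔG_sol(A) + ΔG_sol(H⁺) − ΔG_sol(HA⁺)
    ΔG_aq   = ΔG_gas + ΔΔG_sol
    pKa     = ΔG_aq / (RT ln 10)

The caller supplies component free energies computed on solution-phase
geometries (the cycle's "method 2" semantics).  The proton, having no
electrons, takes experimental reference values: ΔG_sol(H⁺) = −265.6
kcal·mol⁻¹, and G_gas(H⁺) = −6.28 kcal·mol⁻¹ at 298 K — the latter is
also available analytically from translational ideal-gas
thermodynamics (Sackur–Tetrode entropy) via
:func:`proton_gas_free_energy`.  The proton values are configuration,
not constants of the method: some sources print the gas-phase value
with a positive sign, so the default magnitude 6.28 can be overridden
with either sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    ATM_PA,
    DG_SOLV_PROTON_KCAL,
    G_GAS_PROTON_KCAL,
    PROTON_MASS_U,
    R_KCAL,
)
from .thermo import _sackur_tetrode_entropy

#: 1 bar expressed in atm — the thermodynamic-tables standard state
#: under which the canonical |G_gas(H⁺)| = 6.28 kcal·mol⁻¹ is obtained
BAR_IN_ATM = 1e5 / ATM_PA

LN10 = math.log(10.0)


@dataclass
class PkaCycleInput:
    """The six component free energies of the cycle, kcal·mol⁻¹."""

    g_gas_ha: float
    g_gas_a: float
    dg_sol_ha: float
    dg_sol_a: float
    dg_sol_h: float = DG_SOLV_PROTON_KCAL
    g_gas_h: float = G_GAS_PROTON_KCAL
    temperature: float = 310.15

    def __post_init__(self) -> None:
        vals = [
            self.g_gas_ha, self.g_gas_a, self.dg_sol_ha,
            self.dg_sol_a, self.dg_sol_h, self.g_gas_h,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all component energies must be finite")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass
class PkaResult:
    dg_gas: float
    ddg_sol: float
    dg_aq: float
    temperature: float
    pka: float | None = None


def delta_g_aq(cycle: PkaCycleInput, standard_state_correction: bool = False) -> PkaResult:
    """Combine the cycle legs into the aqueous dissociation free energy.

    ``standard_state_correction`` adds RT·ln(R'T) for the net +1 mol of
    gas-phase species created by dissociation, converting the 1 atm gas
    standard state to 1 mol·L⁻¹ (R' = 0.082057 L·atm·mol⁻¹·K⁻¹ ≈
    1.89 kcal·mol⁻¹ at 298 K).  Off by default: the cycle is then a
    plain sum of the supplied component energies.
    """
    T = cycle.temperature
    dg_gas = cycle.g_gas_a + cycle.g_gas_h - cycle.g_gas_ha
    ddg_sol = cycle.dg_sol_a + cycle.dg_sol_h - cycle.dg_sol_ha
    dg_aq = dg_gas + ddg_sol
    if standard_state_correction:
        dg_aq += R_KCAL * T * math.log(0.0820573660809596 * T)
    return PkaResult(dg_gas=dg_gas, ddg_sol=ddg_sol, dg_aq=dg_aq, temperature=T)


def pka_from_dg(dg_aq: float, temperature: float) -> float:
    """pKa = ΔG_aq / (RT ln 10)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return dg_aq / (R_KCAL * temperature * LN10)


def compute_pka(
    cycle: PkaCycleInput, standard_state_correction: bool = False
) -> PkaResult:
    """Full cycle: ΔG_aq plus the resulting pKa."""
    res = delta_g_aq(cycle, standard_state_correction=standard_state_correction)
    res.pka = pka_from_dg(res.dg_aq, cycle.temperature)
    return res


def proton_gas_free_energy(
    temperature: float = 298.15, pressure: float = BAR_IN_ATM
) -> float:
    """Gas-phase Gibbs free energy (kcal·mol⁻¹) of a bare proton.

    Translational-only ideal-gas thermodynamics for a structureless
    particle of proton mass: H = 5/2·RT and S from the Sackur–Tetrode
    equation, G = H − T·S.  ``pressure`` is in atm and defaults to the
    1 bar thermodynamic standard state, which reproduces the tabulated
    G = −6.28 kcal·mol⁻¹ at 298.15 K; pass ``1.0`` for a 1 atm state.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    h = 2.5 * R_KCAL * temperature
    s = _sackur_tetrode_entropy(PROTON_MASS_U, temperature, pressure)
    return h - temperature * s / 1000.0
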