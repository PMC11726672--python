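"""Conformer-ensemble thermochemistry.

Implements the post-processing layer that turns quantum-chemistry
outputs (electronic energies at several basis-set levels, harmonic
frequencies, rotational constants) into aqueous-phase conformer
abundances:

* rigid-rotor/harmonic-oscillator (RRHO) ideal-gas corrections with a
  uniform frequency scale factor,
* uniqueness screening of conformer ensembles by rotational constants
  and energies,
* two-point-exponent inverse-polynomial extrapolation of a DZ/TZ/QZ
  energy series to the complete-basis-set (CBS) limit,
* assembly of Gibbs free energies and Boltzmann population fractions.

The RRHO model uses symmetry number 1, a 1 atm standard state, and no
quasi-harmonic damping of low-frequency modes; the frequency scale
factor multiplies every vibrational wavenumber before both the
zero-point and the thermal terms are evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ATM_PA,
    ATOMIC_MASS_KG,
    AVOGADRO,
    BOLTZMANN_J_K,
    CM1_TO_KCAL,
    HARTREE_TO_KCAL,
    PLANCK_J_S,
    R_CAL,
    R_KCAL,
    SPEED_OF_LIGHT_CM_S,
)
from .structio import ConformerRecord, EnergyTable, Structure

logger = logging.getLogger(__name__)

#: moments of inertia smaller than this (u Å²) are treated as zero
#: (linear/planar degeneracy threshold)
_LINEAR_MOMENT_TOL = 1e-6


# ---------------------------------------------------------------------------
# Rotational constants from geometry

def rotational_constants(
    structure: Structure, masses: np.ndarray | None = None
) -> np.ndarray:
    """Principal rotational constants in GHz, sorted descending.

    Computes the inertia tensor about the center of mass and converts
    the principal moments via B = h/(8π²I).  For a linear molecule the
    moment about the axis vanishes and the corresponding constant is
    reported as ``inf``.
    """
    if structure.n_atoms < 2:
        raise ValueError("rotational constants are undefined for a single atom")
    m = structure.masses() if masses is None else np.asarray(masses, dtype=float)
    if m.shape[0] != structure.n_atoms:
        raise ValueError("need one mass per atom")
    x = structure.coords - np.average(structure.coords, weights=m, axis=0)
    # inertia tensor in u Å²
    r2 = np.sum(x * x, axis=1)
    tensor = np.eye(3) * float(np.sum(m * r2)) - np.einsum("a,ai,aj->ij", m, x, x)
    moments = np.linalg.eigvalsh(tensor)  # ascending, u Å²
    moments_si = moments * ATOMIC_MASS_KG * 1e-20  # kg m²
    out = np.empty(3)
    for i, mom in enumerate(moments_si):
        if moments[i] < _LINEAR_MOMENT_TOL:
            out[i] = np.inf
        else:
            out[i] = PLANCK_J_S / (8.0 * np.pi**2 * mom) / 1e9  # GHz
    return np.sort(out)[::-1]


# ---------------------------------------------------------------------------
# RRHO corrections

@dataclass
class ThermoCorrections:
    """RRHO thermal corrections relative to the electronic energy.

    ``h_corr``/``g_corr`` are in kcal·mol⁻¹ and include the zero-point
    energy; ``s_corr`` is the total entropy in cal·mol⁻¹·K⁻¹.
    """

    h_corr: float
    s_corr: float
    g_corr: float
    temperature: float
    pressure: float = 1.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        gap = self.g_corr - (self.h_corr - self.temperature * self.s_corr / 1000.0)
        if abs(gap) > 1e-6:
            raise ValueError(f"inconsistent corrections: G − (H − T·S) = {gap:g}")


def _sackur_tetrode_entropy(mass_u: float, T: float, pressure_atm: float) -> float:
    """Translational entropy (cal·mol⁻¹·K⁻¹) of an ideal gas particle."""
    m = mass_u * ATOMIC_MASS_KG
    p = pressure_atm * ATM_PA
    lam = (2.0 * np.pi * m * BOLTZMANN_J_K * T) ** 1.5 / PLANCK_J_S**3
    q_trans = lam * BOLTZMANN_J_K * T / p  # per-particle translational q
    return R_CAL * (math.log(q_trans) + 2.5)


def rrho_corrections(
    frequencies: np.ndarray | list[float],
    rot_constants: np.ndarray | list[float] | None,
    mass: float,
    temperature: float = 310.15,
    pressure: float = 1.0,
    scale: float = 0.971,
    drop_imaginary: bool = False,
) -> ThermoCorrections:
    """RRHO enthalpy/entropy/Gibbs corrections.

    Frequencies (cm⁻¹) are multiplied by ``scale`` before the zero-point
    and thermal vibrational terms.  ``rot_constants`` are in GHz; pass
    ``None`` (or an empty list) for an atom, and use an ``inf`` entry
    for the unbounded constant of a linear molecule.  Negative-tagged
    (imaginary) frequencies raise unless ``drop_imaginary`` is set, in
    which case they are removed with a logged warning.

    Returns corrections with H including the pV term (ideal gas, +RT)
    and the zero-point energy, at a 1 atm standard state, symmetry
    number 1.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if not mass > 0:
        raise ValueError("mass must be positive")
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs < 0):
        bad = freqs[freqs < 0]
        if not drop_imaginary:
            raise ValueError(
                f"{bad.size} imaginary frequency(ies) present (e.g. {bad[0]:.1f}i cm⁻¹); "
                "re-optimize the geometry or pass drop_imaginary=True"
            )
        logger.warning("dropping %d imaginary mode(s): %s", bad.size, bad)
        freqs = freqs[freqs >= 0]
    freqs = freqs[freqs > 0] * scale

    T = temperature
    kT = BOLTZMANN_J_K * T

    # translational: E = 3/2 RT, +RT for pV; Sackur–Tetrode entropy
    e_kcal = 1.5 * R_KCAL * T
    s_cal = _sackur_tetrode_entropy(mass, T, pressure)

    # rotational
    rot = None if rot_constants is None else np.asarray(rot_constants, dtype=float)
    if rot is not None and rot.size:
        b_hz = rot[np.isfinite(rot)] * 1e9
        if b_hz.size == 0:
            raise ValueError("all rotational constants non-finite")
        if np.any(b_hz <= 0):
            raise ValueError("rotational constants must be positive")
        if rot.size < 3 or np.any(~np.isfinite(rot)):
            # linear rotor: one finite constant (possibly doubly listed)
            b = float(b_hz[0])
            q_rot = kT / (PLANCK_J_S * b)
            e_kcal += R_KCAL * T
            s_cal += R_CAL * (math.log(q_rot) + 1.0)
        else:
            q_rot = math.sqrt(np.pi) * (kT / PLANCK_J_S) ** 1.5 / math.sqrt(
                float(np.prod(b_hz))
            )
            e_kcal += 1.5 * R_KCAL * T
            s_cal += R_CAL * (math.log(q_rot) + 1.5)

    # vibrational (harmonic oscillator per scaled mode)
    if freqs.size:
        theta = (
            PLANCK_J_S * SPEED_OF_LIGHT_CM_S * freqs / BOLTZMANN_J_K
        )  # vibrational temperatures, K
        u = theta / T
        e_kcal += float(np.sum(0.5 * freqs * CM1_TO_KCAL))  # ZPE
        e_kcal += float(np.sum(R_KCAL * theta / np.expm1(u)))
        s_cal += float(np.sum(R_CAL * (u / np.expm1(u) - np.log1p(-np.exp(-u)))))

    h_corr = e_kcal + R_KCAL * T  # +pV
    g_corr = h_corr - T * s_cal / 1000.0
    return ThermoCorrections(
        h_corr=h_corr,
        s_corr=s_cal,
        g_corr=g_corr,
        temperature=T,
        pressure=pressure,
        scale_factor=scale,
    )


# ---------------------------------------------------------------------------
# Uniqueness screening

_LEVEL_PRIORITY = ("dft", "qz", "tz", "dz")


def _comparison_energy(record: ConformerRecord, level: str | None) -> float:
    if level is not None:
        if level not in record.energies:
            raise ValueError(
                f"conformer {record.conformer_id!r} has no {level!r} energy"
            )
        return record.energies[level]
    for key in _LEVEL_PRIORITY:
        if key in record.energies:
            return record.energies[key]
    raise ValueError(f"conformer {record.conformer_id!r} has no electronic energy")


def dedup(
    ensemble: EnergyTable | list[ConformerRecord],
    rel_tol: float = 0.01,
    e_tol: float = 0.1,
    energy_level: str | None = None,
) -> tuple[EnergyTable, dict[str, str]]:
    """Screen a conformer ensemble for uniqueness.

    Two conformers are deemed identical when all three sorted rotational
    constants agree within ``rel_tol`` (relative, default 1%) *and*
    their comparison energies agree within ``e_tol`` kcal·mol⁻¹
    (default 0.1).  Records are processed in ascending energy order and
    compared greedily against already-kept representatives, so each
    duplicate group is represented by its lowest-energy member.

    ``energy_level`` picks the energy column used for the comparison;
    by default the best available level per record
    (dft > qz > tz > dz) is used.

    Returns the unique table and a ``{duplicate_id: representative_id}``
    map.
    """
    records = list(ensemble)
    for r in records:
        if r.rot_constants is None:
            raise ValueError(
                f"conformer {r.conformer_id!r} lacks rotational constants; "
                "dedup needs all three"
            )
    energies = {
        r.conformer_id: _comparison_energy(r, energy_level) * HARTREE_TO_KCAL
        for r in records
    }
    order = sorted(records, key=lambda r: energies[r.conformer_id])
    kept: list[ConformerRecord] = []
    duplicate_of: dict[str, str] = {}
    for rec in order:
        b = np.sort(rec.rot_constants)
        e = energies[rec.conformer_id]
        rep = None
        for k in kept:
            bk = np.sort(k.rot_constants)
            ok_rot = np.all(np.abs(b - bk) <= rel_tol * np.abs(bk))
            ok_e = abs(e - energies[k.conformer_id]) <= e_tol
            if ok_rot and ok_e:
                rep = k
                break
        if rep is None:
            kept.append(rec)
        else:
            duplicate_of[rec.conformer_id] = rep.conformer_id
    # preserve input order among the kept records
    kept_ids = {r.conformer_id for r in kept}
    unique = [r for r in records if r.conformer_id in kept_ids]
    logger.info("dedup: %d records -> %d unique", len(records), len(unique))
    return EnergyTable(unique), duplicate_of


# ---------------------------------------------------------------------------
# CBS extrapolation

@dataclass
class CBSSeries:
    """Inverse-polynomial complete-basis-set extrapolation of a DZ/TZ/QZ
    electronic-energy series: E(n) = E_CBS + A·n⁻ᵖ + B·n⁻ᵠ."""

    e2: float
    e3: float
    e4: float
    e_cbs: float
    coeff_a: float
    coeff_b: float
    exponents: tuple[float, float] = (4.0, 5.0)
    offset: float = 0.0

    def model(self, n: float) -> float:
        p, q = self.exponents
        x = n + self.offset
        return self.e_cbs + self.coeff_a * x ** -p + self.coeff_b * x ** -q


def cbs_extrapolate(
    e2: float,
    e3: float,
    e4: float,
    exponents: tuple[float, float] = (4.0, 5.0),
    offset: float = 0.0,
) -> CBSSeries:
    """Extrapolate energies at cardinal numbers n = 2, 3, 4 to the CBS limit.

    Solves the exactly-determined linear system
    ``E(n) = E_CBS + A·(n+offset)⁻ᵖ + B·(n+offset)⁻ᵠ`` for
    (E_CBS, A, B).  The default exponent pair (4, 5) is the
    inverse-quartic/quintic two-term form; exponents and a cardinal
    offset are configurable.
    """
    e = np.array([e2, e3, e4], dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("all three energies must be finite")
    p, q = exponents
    n = np.array([2.0, 3.0, 4.0]) + offset
    design = np.column_stack([np.ones(3), n**-p, n**-q])
    e_cbs, a, b = np.linalg.solve(design, e)
    series = CBSSeries(
        e2=e2, e3=e3, e4=e4, e_cbs=e_cbs, coeff_a=a, coeff_b=b,
        exponents=(p, q), offset=offset,
    )
    resid = max(abs(series.model(k) - v) for k, v in zip((2, 3, 4), e))
    if resid > 1e-10:
        raise ArithmeticError(f"CBS solve residual {resid:g} hartree")
    return series


# ---------------------------------------------------------------------------
# Gibbs assembly and populations

def assemble_gibbs(e_cbs: float, g_corr: float) -> float:
    """Total Gibbs free energy (kcal·mol⁻¹) from a CBS electronic energy
    (hartree) and an RRHO Gibbs correction (kcal·mol⁻¹)."""
    if not (np.isfinite(e_cbs) and np.isfinite(g_corr)):
        raise ValueError("inputs must be finite")
    return HARTREE_TO_KCAL * e_cbs + g_corr


@dataclass
class PopulationResult:
    """Relative Gibbs energies and Boltzmann population fractions."""

    table: pd.DataFrame = field(repr=False)  # conformer_id, delta_g_kcal, population
    temperature: float = 310.15

    @property
    def populations(self) -> np.ndarray:
        return self.table["population"].to_numpy()

    @property
    def delta_g(self) -> np.ndarray:
        return self.table["delta_g_kcal"].to_numpy()


def boltzmann_populations(
    gibbs: dict[str, float] | list[float] | np.ndarray,
    temperature: float = 310.15,
) -> PopulationResult:
    """Equilibrium population fractions p_i ∝ exp(−ΔG°_i/RT).

    ``gibbs`` maps conformer ids to Gibbs free energies in kcal·mol⁻¹
    (a bare sequence gets ids ``c1, c2, ...``).  ΔG° is taken relative
    to the minimum; the result table is sorted by ascending ΔG°.
    """
    if isinstance(gibbs, dict):
        ids = list(gibbs)
        g = np.array([gibbs[i] for i in ids], dtype=float)
    else:
        g = np.asarray(gibbs, dtype=float)
        ids = [f"c{i + 1}" for i in range(g.size)]
    if g.size == 0:
        raise ValueError("need at least one conformer")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    dg = g - g.min()
    w = np.exp(-dg / (R_KCAL * temperature))
    p = w / w.sum()
    df = pd.DataFrame(
        {"conformer_id": ids, "delta_g_kcal": dg, "population": p}
    ).sort_values(["delta_g_kcal", "conformer_id"], kind="stable", ignore_index=True)
    return PopulationResult(table=df, temperature=temperature)


def ensemble_free_energies(
    table: EnergyTable,
    temperature: float = 310.15,
    pressure: float = 1.0,
    scale: float = 0.971,
    cbs_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: CBS + RRHO → total Gibbs energy per conformer.

    Conformers lacking a complete DZ/TZ/QZ series fall back to their
    best single-level electronic energy (flagged in the ``cbs`` column).
    """
    rows = []
    for rec in table:
        if rec.cbs_eligible:
            series = cbs_extrapolate(
                rec.energies["dz"], rec.energies["tz"], rec.energies["qz"],
                **(cbs_kwargs or {}),
            )
            e_elec, used_cbs = series.e_cbs, True
        else:
            e_elec, used_cbs = _comparison_energy(rec, None), False
        corr = rrho_corrections(
            rec.frequencies, rec.rot_constants, rec.mass,
            temperature=temperature, pressure=pressure, scale=scale,
        )
        rows.append(
            {
                "conformer_id": rec.conformer_id,
                "e_elec_hartree": e_elec,
                "cbs": used_cbs,
                "g_corr_kcal": corr.g_corr,
                "g_total_kcal": assemble_gibbs(e_elec, corr.g_corr),
            }
        )
    return pd.DataFrame(rows)
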