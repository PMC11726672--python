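"""Synthetic fixture generators with planted ground truth.

Every analysis stage in the package can be exercised without external
downloads: these generators emit inputs in the same dialects the
readers consume (energy tables, Cα structures, pKa cycles), together
with a *truth record* carrying the planted quantities (populations,
variance fractions, group labels, target pKa) so downstream stages can
be scored directly.

Generators are pure functions of their arguments: the same seed yields
byte-identical output.  Noise is isotropic Gaussian throughout — it
exists to exercise the estimators, not to model chemistry; geometries
are synthetic point sets, not force-field structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .constants import HARTREE_TO_KCAL, R_KCAL
from .pka import LN10, PkaCycleInput
from .structio import ConformerRecord, EnergyTable, Structure
from .thermo import rrho_corrections


@dataclass
class SyntheticSpec:
    """Provenance record for a generated fixture."""

    seed: int
    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a truth sidecar as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=1, default=default))


# ---------------------------------------------------------------------------
# Conformer ensembles

def gen_conformer_ensemble(
    seed: int,
    n_unique: int = 5,
    n_dup_per_group: int = 3,
    dg_spectrum: np.ndarray | list[float] | None = None,
    cbs_truth: list[tuple[float, float, float]] | None = None,
    temperature: float = 310.15,
    scale: float = 0.971,
    mass: float = 336.47,
) -> tuple[EnergyTable, dict]:
    """Conformer energy table with planted duplicates and CBS limits.

    Each of the ``n_unique`` conformers gets distinct rotational
    constants (≥3% apart between groups, so groups never merge),
    random positive frequencies, and DZ/TZ/QZ energies generated
    *exactly* from a planted inverse-polynomial basis-set model whose
    limit is chosen so that the total Gibbs free energies reproduce
    ``dg_spectrum`` (kcal·mol⁻¹, relative to the minimum).  Duplicate
    group members jitter the rotational constants by ≤0.5% and the
    energies by ≤+0.05 kcal·mol⁻¹ around the group head, inside the
    uniqueness-screen tolerances (1%, 0.1 kcal·mol⁻¹); the jitter is
    strictly positive so the head remains the lowest-energy member.

    The defaults emulate a small drug-like ligand ensemble at
    physiological temperature.  The truth record carries the planted
    ΔG° spectrum, populations at ``temperature``, duplicate-group map,
    and per-conformer (E_CBS, A, B).
    """
    if n_unique < 1 or n_dup_per_group < 1:
        raise ValueError("counts must be positive")
    dg = (
        np.arange(n_unique, dtype=float)
        if dg_spectrum is None
        else np.asarray(dg_spectrum, dtype=float)
    )
    if dg.size != n_unique:
        raise ValueError("dg_spectrum length must equal n_unique")
    rng = np.random.default_rng(seed)
    # group-head rotational constants on a multiplicative grid: adjacent
    # conformers differ by ≥3% in every constant
    base = rng.uniform(0.8, 1.2, size=3)
    heads_rot = np.sort(base)[::-1] * (1.05 ** np.arange(n_unique))[:, None]
    freqs = [np.sort(rng.uniform(80.0, 3400.0, size=24)) for _ in range(n_unique)]
    cbs = (
        [
            (float(e), float(a), float(b))
            for e, a, b in zip(
                np.zeros(n_unique), rng.uniform(0.5, 2.0, n_unique),
                rng.uniform(-1.0, 1.0, n_unique),
            )
        ]
        if cbs_truth is None
        else [tuple(map(float, t)) for t in cbs_truth]
    )
    if len(cbs) != n_unique:
        raise ValueError("cbs_truth length must equal n_unique")

    records: list[ConformerRecord] = []
    truth_groups: dict[str, list[str]] = {}
    g_min_offset = -600000.0  # kcal·mol⁻¹ scale of a drug-like molecule
    planted_cbs = []
    for i in range(n_unique):
        corr = rrho_corrections(
            freqs[i], heads_rot[i], mass, temperature=temperature, scale=scale
        )
        # choose E_CBS so that 627.5095·E_CBS + g_corr = g_min_offset + dg[i]
        e_cbs = (g_min_offset + dg[i] - corr.g_corr) / HARTREE_TO_KCAL
        _, a, b = cbs[i]
        planted_cbs.append((e_cbs, a, b))
        head_id = f"conf{i + 1:03d}"
        truth_groups[head_id] = []
        for j in range(n_dup_per_group):
            if j == 0:
                rot = heads_rot[i]
                de = 0.0
                cid = head_id
            else:
                rot = heads_rot[i] * (1.0 + rng.uniform(-0.004, 0.004, size=3))
                de = rng.uniform(0.01, 0.045) / HARTREE_TO_KCAL  # hartree, > 0
                cid = f"{head_id}_dup{j}"
                truth_groups[head_id].append(cid)
            energies = {
                "dz": e_cbs + a * 2.0**-4 + b * 2.0**-5 + de,
                "tz": e_cbs + a * 3.0**-4 + b * 3.0**-5 + de,
                "qz": e_cbs + a * 4.0**-4 + b * 4.0**-5 + de,
                "dft": e_cbs + 0.02 + de,
            }
            records.append(
                ConformerRecord(
                    conformer_id=cid,
                    energies=energies,
                    frequencies=freqs[i].copy(),
                    rot_constants=np.sort(rot)[::-1],
                    mass=mass,
                )
            )
    w = np.exp(-(dg - dg.min()) / (R_KCAL * temperature))
    truth = {
        "spec": {"seed": seed, "kind": "conformer_ensemble",
                 "n_unique": n_unique, "n_dup_per_group": n_dup_per_group},
        "temperature": temperature,
        "scale_factor": scale,
        "delta_g_kcal": dg.tolist(),
        "populations": (w / w.sum()).tolist(),
        "duplicate_groups": truth_groups,
        "cbs_truth": [list(t) for t in planted_cbs],
        "unique_ids": [f"conf{i + 1:03d}" for i in range(n_unique)],
    }
    return EnergyTable(records), truth


# ---------------------------------------------------------------------------
# Structure ensembles

def _helix_template(n_positions: int) -> np.ndarray:
    """An ideal α-helix-like Cα trace (rise 1.5 Å, radius 2.3 Å)."""
    t = np.arange(n_positions) * 100.0 * np.pi / 180.0
    return np.column_stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_positions)]
    )


def _orthonormal_modes(rng: np.random.Generator, n_positions: int, n_modes: int) -> np.ndarray:
    """Random centered, orthonormal displacement modes (n_modes, 3P)."""
    raw = rng.standard_normal((n_modes, 3 * n_positions))
    raw = raw.reshape(n_modes, n_positions, 3)
    raw -= raw.mean(axis=1, keepdims=True)  # no net translation
    raw = raw.reshape(n_modes, -1)
    q, _ = np.linalg.qr(raw.T)
    return q.T[:n_modes]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_structure_ensemble(
    seed: int,
    n_positions: int = 60,
    n_structures: int = 12,
    mode_variances: list[float] | None = None,
    n_groups: int = 1,
    group_offset: float = 0.0,
    offset_fraction: float = 0.25,
    noise_sigma: float = 0.05,
    rigid_motions: bool = True,
) -> tuple[list[Structure], dict]:
    """Cα structure ensemble with planted collective modes and groups.

    Coordinates are ``template + Σ_k score_k·mode_k + group shift +
    isotropic noise``: modes are random orthonormal centered
    displacement directions with variances ``mode_variances`` (Å²,
    default ``[4.0, 1.0]`` — a 4:1 two-mode spectrum), group shifts
    rigidly displace the last ``offset_fraction`` of positions by
    ``group_offset`` Å per group index (a sub-domain hinge, the planted
    analogue of an activation-state split), and each structure is
    finally moved by a random rigid motion (removed later by
    superposition) unless ``rigid_motions`` is off.

    The truth record carries planted mode variance fractions, scores,
    and group labels.
    """
    if n_positions < 3:
        raise ValueError("need ≥3 positions")
    if n_structures < 2:
        raise ValueError("need ≥2 structures")
    rng = np.random.default_rng(seed)
    var = np.asarray(
        [4.0, 1.0] if mode_variances is None else mode_variances, dtype=float
    )
    template = _helix_template(n_positions)
    modes = _orthonormal_modes(rng, n_positions, var.size)
    scores = rng.standard_normal((n_structures, var.size)) * np.sqrt(var)
    scores -= scores.mean(axis=0)  # planted variance is the sample variance
    groups = np.arange(n_structures) % n_groups + 1
    sub = np.arange(int(round((1.0 - offset_fraction) * n_positions)), n_positions)
    structures = []
    for s in range(n_structures):
        disp = (scores[s] @ modes).reshape(n_positions, 3)
        coords = template + disp
        if n_groups > 1 and group_offset != 0.0:
            coords[sub] += np.array([group_offset, 0.0, 0.0]) * (groups[s] - 1)
        coords += rng.standard_normal(coords.shape) * noise_sigma
        if rigid_motions:
            coords = coords @ _random_rotation(rng).T + rng.uniform(-20, 20, 3)
        structures.append(
            Structure(
                elements=["C"] * n_positions,
                coords=coords,
                atom_names=["CA"] * n_positions,
                res_names=["ALA"] * n_positions,
                res_numbers=np.arange(1, n_positions + 1),
                chain_ids=["A"] * n_positions,
                title=f"synthetic_{s:02d}",
            )
        )
    sample_var = scores.var(axis=0, ddof=1)
    # Expected PCA proportions under the full generative model: each
    # planted mode carries its score variance plus the isotropic noise
    # floor sigma^2, and the remaining 3P-6 non-rigid degrees of freedom
    # carry sigma^2 each (superposition absorbs ~6 rigid dof).
    noise_total = (3 * n_positions - 6) * noise_sigma**2
    denom = sample_var.sum() + noise_total
    expected = (sample_var + noise_sigma**2) / denom
    truth = {
        "spec": {"seed": seed, "kind": "structure_ensemble",
                 "n_positions": n_positions, "n_structures": n_structures},
        "mode_variances": var.tolist(),
        "sample_mode_variances": sample_var.tolist(),
        "variance_fractions": (sample_var / sample_var.sum()).tolist(),
        "expected_pca_fractions": expected.tolist(),
        "scores": scores.tolist(),
        "group_labels": groups.tolist(),
        "offset_positions": sub.tolist(),
        "noise_sigma": noise_sigma,
    }
    return structures, truth


# ---------------------------------------------------------------------------
# pKa cycles

def gen_pka_inputs(
    seed: int, target_pka: float = 9.2, temperature: float = 310.15
) -> tuple[PkaCycleInput, dict]:
    """A thermodynamic cycle whose aqueous ΔG encodes ``target_pka``.

    Component energies are sampled at chemically plausible magnitudes
    (hundreds of thousands of kcal·mol⁻¹ for the molecular species,
    tens for solvation), then the solvation free energy of the
    conjugate base is adjusted so that ΔG_aq = target_pka·RT·ln10
    exactly.  The default target matches a protonated-amine ligand at
    physiological temperature.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    dg_target = target_pka * R_KCAL * temperature * LN10
    g_gas_ha = -600000.0 + rng.uniform(-1000.0, 1000.0)
    g_gas_a = g_gas_ha + rng.uniform(200.0, 240.0)  # gas-phase deprotonation
    dg_sol_ha = rng.uniform(-60.0, -40.0)
    dg_sol_h = -265.6
    g_gas_h = -6.28
    dg_sol_a = dg_target - (g_gas_a + g_gas_h - g_gas_ha) - dg_sol_h + dg_sol_ha
    cycle = PkaCycleInput(
        g_gas_ha=g_gas_ha,
        g_gas_a=g_gas_a,
        dg_sol_ha=dg_sol_ha,
        dg_sol_a=dg_sol_a,
        dg_sol_h=dg_sol_h,
        g_gas_h=g_gas_h,
        temperature=temperature,
    )
    truth = {
        "spec": {"seed": seed, "kind": "pka_inputs"},
        "target_pka": target_pka,
        "temperature": temperature,
        "dg_aq_kcal": dg_target,
    }
    return cycle, truth
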