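"""Rigid-body superposition and RMSD analysis.

Provides least-squares (Kabsch) superposition, fixed-frame RMSD, the
receptor residue-renumbering convention, per-transmembrane-helix RMSD
reports for GPCR backbone comparisons, and permutation-optimal
heavy-atom RMSD for small-molecule conformers (like-element atoms may
be relabelled, so the assignment is optimized jointly with the fit).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .structio import Structure

logger = logging.getLogger(__name__)

#: Transmembrane helix residue intervals (inclusive) in the human
#: μ-opioid receptor numbering; ``conserved`` spans the region shared
#: with the mouse receptor after its +2 renumbering.
DEFAULT_TM_RANGES: dict[str, tuple[int, int]] = {
    "conserved": (66, 349),
    "TM1": (66, 98),
    "TM2": (103, 133),
    "TM3": (138, 173),
    "TM4": (182, 207),
    "TM5": (226, 264),
    "TM6": (270, 308),
    "TM7": (313, 338),
}


def load_tm_ranges(path: str | Path | None = None) -> dict[str, tuple[int, int]]:
    """Load a helix range map from JSON, or return the built-in default."""
    if path is None:
        return dict(DEFAULT_TM_RANGES)
    raw = json.loads(Path(path).read_text())
    ranges = {k: (int(v[0]), int(v[1])) for k, v in raw.items()}
    _validate_ranges(ranges)
    return ranges


def _validate_ranges(ranges: dict[str, tuple[int, int]]) -> None:
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range {name!r} is empty: {lo}–{hi}")
    tm = sorted(
        (v for k, v in ranges.items() if k.upper().startswith("TM")),
    )
    for (a_lo, a_hi), (b_lo, b_hi) in zip(tm, tm[1:]):
        if b_lo <= a_hi:
            raise ValueError("TM intervals must be pairwise disjoint")


_validate_ranges(DEFAULT_TM_RANGES)


@dataclass
class SuperpositionResult:
    """Optimal rotation/translation of ``moving`` onto ``fixed`` and the
    residual RMSD over the paired atoms."""

    rotation: np.ndarray  # 3×3 proper rotation
    translation: np.ndarray  # Å
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rmsd_fixed(
    a: Structure | np.ndarray,
    b: Structure | np.ndarray,
    pairing: np.ndarray | list[tuple[int, int]] | None = None,
) -> float:
    """Root-mean-square deviation over paired atoms, with no fitting.

    sqrt( (1/N) Σ_i [(x_i−x'_i)² + (y_i−y'_i)² + (z_i−z'_i)²] )
    """
    xa = a.coords if isinstance(a, Structure) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, Structure) else np.asarray(b, dtype=float)
    if pairing is not None:
        pairs = np.asarray(pairing, dtype=int)
        if pairs.size == 0:
            raise ValueError("empty pairing")
        xa, xb = xa[pairs[:, 0]], xb[pairs[:, 1]]
    if xa.shape != xb.shape or xa.shape[0] == 0:
        raise ValueError("pairing must select equal, nonzero atom counts")
    d = xa - xb
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _kabsch_arrays(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with fixed ≈ moving·Rᵀ + t."""
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cf - rot @ cm


def kabsch(
    moving: Structure | np.ndarray,
    fixed: Structure | np.ndarray,
    pairing: np.ndarray | list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    A proper rotation is enforced by determinant correction of the SVD
    solution.  Requires at least three non-collinear atom pairs.
    """
    xm = moving.coords if isinstance(moving, Structure) else np.asarray(moving, float)
    xf = fixed.coords if isinstance(fixed, Structure) else np.asarray(fixed, float)
    if pairing is not None:
        pairs = np.asarray(pairing, dtype=int)
        xm, xf = xm[pairs[:, 0]], xf[pairs[:, 1]]
    if xm.shape != xf.shape:
        raise ValueError("pairing must select equal atom counts")
    n = xm.shape[0]
    if n < 3:
        raise ValueError(f"need ≥3 paired atoms, got {n}")
    for x in (xm, xf):
        if np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-8) < 2:
            raise ValueError("paired atoms are collinear; rotation is underdetermined")
    rot, trans = _kabsch_arrays(xm, xf)
    rmsd = rmsd_fixed(xm @ rot.T + trans, xf)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def renumber_offset(structure: Structure, offset: int) -> Structure:
    """Shift every residue number by ``offset`` (atoms otherwise untouched)."""
    out = replace(structure)
    out.res_numbers = structure.res_numbers + int(offset)
    return out


def pair_by_residue_atom(
    a: Structure, b: Structure, residue_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Index pairs matching atoms on (residue number, atom name).

    Atoms whose (residue, name) key is absent from the other structure
    — unresolved loops, missing side chains — are dropped; the dropped
    counts are logged.
    """
    def keys(s: Structure) -> dict[tuple[int, str], int]:
        out: dict[tuple[int, str], int] = {}
        for i, (num, name) in enumerate(zip(s.res_numbers, s.atom_names)):
            if residue_range is not None and not (
                residue_range[0] <= num <= residue_range[1]
            ):
                continue
            out.setdefault((int(num), name), i)
        return out

    ka, kb = keys(a), keys(b)
    shared = sorted(set(ka) & set(kb))
    if len(shared) < len(ka) or len(shared) < len(kb):
        logger.info(
            "pairing dropped %d atoms from A, %d from B (unmatched residue/atom keys)",
            len(ka) - len(shared), len(kb) - len(shared),
        )
    return np.array([(ka[k], kb[k]) for k in shared], dtype=int).reshape(-1, 2)


def region_rmsd_report(
    a: Structure,
    b: Structure,
    ranges: dict[str, tuple[int, int]] | None = None,
    selection: str = "backbone",
    fit_region: str = "conserved",
    per_region_fit: bool = False,
) -> pd.DataFrame:
    """Per-region RMSD between two receptor structures.

    Both structures must share residue numbering (apply
    :func:`renumber_offset` first where conventions differ).  By
    default one rigid fit is made on the ``fit_region`` pairing and
    every region's RMSD is then measured in that common frame, so a
    region that moves relative to the conserved core shows a large
    RMSD; ``per_region_fit`` instead refits within each region.

    Returns a table with columns ``region``, ``rmsd_A``, ``n_atoms``;
    a region with no paired atoms is reported with ``n_atoms = 0`` and
    a missing RMSD rather than raising.
    """
    ranges = dict(DEFAULT_TM_RANGES) if ranges is None else ranges
    _validate_ranges(ranges)
    sa, sb = a.select(selection), b.select(selection)
    if fit_region not in ranges:
        raise ValueError(f"fit region {fit_region!r} not in range map")
    fit_pairs = pair_by_residue_atom(sa, sb, ranges[fit_region])
    if fit_pairs.shape[0] < 3:
        raise ValueError(f"fit region {fit_region!r} pairs too few atoms")
    fit = kabsch(sa, sb, fit_pairs)
    moved = sa.with_coords(fit.apply(sa.coords))
    rows = []
    for name, interval in ranges.items():
        pairs = pair_by_residue_atom(sa, sb, interval)
        if pairs.shape[0] == 0:
            rows.append({"region": name, "rmsd_A": np.nan, "n_atoms": 0})
            continue
        if per_region_fit and pairs.shape[0] >= 3:
            val = kabsch(sa, sb, pairs).rmsd
        else:
            val = rmsd_fixed(moved, sb, pairs)
        rows.append({"region": name, "rmsd_A": val, "n_atoms": int(pairs.shape[0])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation-optimal heavy-atom RMSD for small molecules

def _element_groups(structure: Structure) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, e in enumerate(structure.elements):
        groups.setdefault(e, []).append(i)
    return {e: np.array(ix, dtype=int) for e, ix in groups.items()}


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    axes = vecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def ligand_heavy_rmsd(
    a: Structure, b: Structure, max_rounds: int = 50
) -> tuple[float, np.ndarray]:
    """Minimum heavy-atom RMSD over like-element atom relabellings.

    Hydrogens are excluded; the two structures must then contain the
    same element multiset.  The assignment (Hungarian per element,
    squared-distance cost) and the rigid fit are alternated until the
    assignment is stable, starting from the input atom order and from
    principal-axes pre-alignments under the four proper axis-flip
    hypotheses; the best converged minimum is returned together with
    the atom permutation mapping a's heavy atoms onto b's.
    """
    ha, hb = a.heavy_atoms(), b.heavy_atoms()
    ca, cb = sorted(ha.elements), sorted(hb.elements)
    if ca != cb:
        only_a = sorted(set(ha.elements) - set(hb.elements))
        counts = {
            e: (ha.elements.count(e), hb.elements.count(e))
            for e in set(ca) | set(cb)
            if ha.elements.count(e) != hb.elements.count(e)
        }
        raise ValueError(
            f"heavy-atom element multisets differ: {counts or only_a}"
        )
    n = ha.n_atoms
    groups_a = _element_groups(ha)
    groups_b = _element_groups(hb)
    xb = hb.coords
    cb_centroid = xb.mean(axis=0)

    def refine(x0: np.ndarray) -> tuple[float, np.ndarray]:
        """Alternate assignment and fit from the start pose x0."""
        x = x0
        perm = np.empty(n, dtype=int)
        prev = None
        best = (np.inf, None)
        for _ in range(max_rounds):
            for e, ia in groups_a.items():
                ib = groups_b[e]
                cost = (
                    np.sum(x[ia][:, None, :] ** 2, axis=2)
                    - 2.0 * x[ia] @ xb[ib].T
                    + np.sum(xb[ib] ** 2, axis=1)[None, :]
                )
                ri, ci = linear_sum_assignment(cost)
                perm[ia[ri]] = ib[ci]
            if prev is not None and np.array_equal(perm, prev):
                break
            prev = perm.copy()
            rot, trans = _kabsch_arrays(ha.coords, xb[perm])
            x = ha.coords @ rot.T + trans
            val = rmsd_fixed(x, xb[perm])
            if val < best[0]:
                best = (val, perm.copy())
        return best

    # start poses: input order fit is implied by the principal-axes
    # identity flip; four proper flips of the principal frame
    axes_a = _principal_axes(ha.coords)
    axes_b = _principal_axes(xb)
    ca_centroid = ha.coords.mean(axis=0)
    flips = [np.diag(f) for f in
             ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]
    starts = [ha.coords - ca_centroid + cb_centroid]
    for f in flips:
        rot = axes_b @ f @ axes_a.T
        starts.append((ha.coords - ca_centroid) @ rot.T + cb_centroid)
    best_val, best_perm = np.inf, None
    for x0 in starts:
        val, perm = refine(x0)
        if val < best_val:
            best_val, best_perm = val, perm
    return float(best_val), best_perm
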