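"""Independent reference implementations used to check the package.

These deliberately avoid the package's own linear-algebra path: the
superposition oracle is Horn's closed-form quaternion method (largest
eigenvalue of the 4x4 key matrix), not an SVD Kabsch solve, and the
permutation oracle enumerates every like-element assignment.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Minimum RMSD over rigid motions, via Horn's quaternion method.

    rmsd^2 = (G_a + G_b - 2*lambda_max) / n, where lambda_max is the
    largest eigenvalue of the 4x4 key matrix built from the correlation
    matrix of the centered point sets.
    """
    a = moving - moving.mean(axis=0)
    b = fixed - fixed.mean(axis=0)
    n = a.shape[0]
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key).max()
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def exhaustive_heavy_rmsd(
    elements_a: list[str],
    coords_a: np.ndarray,
    elements_b: list[str],
    coords_b: np.ndarray,
) -> float:
    """Minimum RMSD over all like-element atom assignments.

    Enumerates every per-element permutation and scores each candidate
    pairing with the quaternion superposition oracle.  Exponential —
    only for toy molecules.
    """
    groups_a: dict[str, list[int]] = {}
    groups_b: dict[str, list[int]] = {}
    for i, e in enumerate(elements_a):
        if e != "H":
            groups_a.setdefault(e, []).append(i)
    for i, e in enumerate(elements_b):
        if e != "H":
            groups_b.setdefault(e, []).append(i)
    assert {e: len(v) for e, v in groups_a.items()} == {
        e: len(v) for e, v in groups_b.items()
    }
    elems = sorted(groups_a)
    ia = [i for e in elems for i in groups_a[e]]
    best = np.inf
    for combo in itertools.product(
        *[itertools.permutations(groups_b[e]) for e in elems]
    ):
        ib = [i for p in combo for i in p]
        best = min(best, quaternion_rmsd(coords_a[ia], coords_b[ib]))
    return best


def rotation_about_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
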