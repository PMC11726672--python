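"""Structure-ensemble analysis: alignment, invariant core, clustering, PCA.

Workflow for a set of homologous receptor chains (e.g. the μ-opioid
receptor in active and inactive states):

1. map the Cα positions of every chain onto a common set of alignment
   positions (progressive pairwise sequence alignment against the first
   chain; positions with a gap in any chain are removed),
2. find a structural *invariant core* — the positions whose ellipsoid
   of positional scatter stays small across the ensemble — and
   superimpose everything on it,
3. cluster the chains by pairwise Cα RMSD (agglomerative, complete
   linkage) and cut the tree into a requested number of groups,
4. run principal component analysis on the stacked Cartesian Cα
   coordinates: eigenvalues of the 3P×3P covariance are the variances
   (Å²) of collective displacement modes, and each structure's
   projection onto the leading modes places it on the
   active↔inactive landscape,
5. export interpolated trajectories along a chosen mode for
   visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data.IUPACData import protein_letters_3to1_extended
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .structio import Structure
from .superpose import _kabsch_arrays, rmsd_fixed


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -1.0
    al.extend_gap_score = -1.0
    return al


# ---------------------------------------------------------------------------
# Sequence identity

def sequence_identity(
    a: str,
    b: str,
    region: tuple[int, int] | None = None,
    a_start: int = 1,
) -> tuple[float, list[int]]:
    """Pairwise global sequence identity and mismatch positions.

    Aligns with match +1 / mismatch 0 / gap −1 and reports
    ``matches / aligned columns`` over the requested ``region``
    (inclusive interval in a's residue numbering, which begins at
    ``a_start``).  Mismatch positions are returned in a's numbering.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if region is not None and region[0] > region[1]:
        raise ValueError(f"empty region {region}")
    alignment = _aligner().align(a, b)[0]
    sa, sb = alignment[0], alignment[1]
    pos_a = a_start - 1
    matches = columns = 0
    mismatches: list[int] = []
    for ca, cb in zip(sa, sb):
        if ca != "-":
            pos_a += 1
        if ca == "-" or cb == "-":
            continue
        if region is not None and not (region[0] <= pos_a <= region[1]):
            continue
        columns += 1
        if ca == cb:
            matches += 1
        else:
            mismatches.append(pos_a)
    if columns == 0:
        raise ValueError("no aligned columns in the requested region")
    return matches / columns, mismatches


# ---------------------------------------------------------------------------
# Aligned ensembles

def _one_letter(res_names: list[str]) -> str:
    out = []
    for name in res_names:
        out.append(protein_letters_3to1_extended.get(name.capitalize(), "X"))
    return "".join(out)


@dataclass
class AlignedEnsemble:
    """Gap-free position×structure×3 Cα coordinate tensor.

    ``coords[p, s]`` is the Cα position (Å) of alignment position ``p``
    in structure ``s``; only positions present in every structure are
    kept.  ``residue_map[p, s]`` holds the source residue number.
    ``core`` is the currently selected subset of positions used as the
    superposition frame (all positions until a core is found).
    """

    labels: list[str]
    coords: np.ndarray  # (P, S, 3)
    residue_map: np.ndarray  # (P, S) source residue numbers
    res_names: list[str]  # reference residue names per position
    core: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    superposed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (positions, structures, 3)")
        if self.core.size == 0:
            self.core = np.arange(self.n_positions)

    @property
    def n_positions(self) -> int:
        return self.coords.shape[0]

    @property
    def n_structures(self) -> int:
        return self.coords.shape[1]


def build_aligned_ensemble(
    structures: list[Structure], labels: list[str] | None = None
) -> AlignedEnsemble:
    """Map Cα positions of homologous chains onto shared alignment columns.

    Each chain is aligned pairwise against the first (adequate at the
    high sequence identities of a single-receptor ensemble); columns
    gapped in any chain are removed.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    cas = [s.select("calpha") for s in structures]
    for s, ca in zip(structures, cas):
        if ca.n_atoms == 0:
            raise ValueError(f"structure {s.title!r} has no Cα atoms")
    if labels is None:
        labels = [s.title or f"structure_{i}" for i, s in enumerate(structures)]
    ref = cas[0]
    ref_seq = _one_letter(ref.res_names)
    n_ref = ref.n_atoms
    # index_map[s][i] = atom index in chain s aligned to ref position i, or -1
    index_map = np.full((n_ref, len(cas)), -1, dtype=int)
    index_map[:, 0] = np.arange(n_ref)
    aligner = _aligner()
    for s_idx, ca in enumerate(cas[1:], start=1):
        seq = _one_letter(ca.res_names)
        alignment = aligner.align(ref_seq, seq)[0]
        ia = ib = 0
        for col_a, col_b in zip(alignment[0], alignment[1]):
            if col_a != "-" and col_b != "-":
                index_map[ia, s_idx] = ib
            if col_a != "-":
                ia += 1
            if col_b != "-":
                ib += 1
    keep = np.all(index_map >= 0, axis=1)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 gap-free aligned positions")
    kept = np.nonzero(keep)[0]
    coords = np.empty((kept.size, len(cas), 3))
    resmap = np.empty((kept.size, len(cas)), dtype=int)
    for s_idx, ca in enumerate(cas):
        idx = index_map[kept, s_idx]
        coords[:, s_idx, :] = ca.coords[idx]
        resmap[:, s_idx] = ca.res_numbers[idx]
    return AlignedEnsemble(
        labels=list(labels),
        coords=coords,
        residue_map=resmap,
        res_names=[ref.res_names[i] for i in kept],
    )


def _superpose_onto_mean(
    coords: np.ndarray, core: np.ndarray, max_iter: int = 10, tol: float = 1e-8
) -> np.ndarray:
    """Iteratively fit every structure onto the core-region mean."""
    x = coords.copy()
    ref = x[core, 0, :]
    for _ in range(max_iter):
        for s in range(x.shape[1]):
            rot, trans = _kabsch_arrays(x[core, s, :], ref)
            x[:, s, :] = x[:, s, :] @ rot.T + trans
        new_ref = x[core].mean(axis=1)
        if np.max(np.abs(new_ref - ref)) < tol:
            ref = new_ref
            break
        ref = new_ref
    return x


def superpose_ensemble(ensemble: AlignedEnsemble, core: np.ndarray | None = None) -> AlignedEnsemble:
    """Superimpose all structures on the (core of the) ensemble mean."""
    core = ensemble.core if core is None else np.asarray(core, dtype=int)
    coords = _superpose_onto_mean(ensemble.coords, core)
    return AlignedEnsemble(
        labels=ensemble.labels,
        coords=coords,
        residue_map=ensemble.residue_map,
        res_names=ensemble.res_names,
        core=core,
        superposed=True,
    )


# ---------------------------------------------------------------------------
# Invariant core

@dataclass
class CoreSelection:
    """Positions selected as the low-variance superposition frame."""

    indices: np.ndarray  # into ensemble positions, sorted
    volumes: np.ndarray  # final scatter-ellipsoid volume (Å³) per position
    n_dropped: int


def _ellipsoid_volumes(coords: np.ndarray) -> np.ndarray:
    """Per-position scatter ellipsoid volume (Å³) across structures."""
    centered = coords - coords.mean(axis=1, keepdims=True)
    vols = np.empty(coords.shape[0])
    for p in range(coords.shape[0]):
        cov = centered[p].T @ centered[p] / max(coords.shape[1] - 1, 1)
        lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        vols[p] = 4.0 / 3.0 * np.pi * float(np.sqrt(np.prod(lam)))
    return vols


def find_invariant_core(
    ensemble: AlignedEnsemble,
    volume_cutoff: float = 0.5,
    min_core: int = 30,
) -> CoreSelection:
    """Iteratively strip high-variance positions to find a rigid core.

    Each round superimposes all structures on the current core (first
    structure as initial reference, the ensemble mean thereafter),
    measures every position's scatter-ellipsoid volume, and drops the
    position with the largest volume, until the largest core volume is
    ≤ ``volume_cutoff`` Å³ or only ``min_core`` positions remain.
    Fully deterministic; ties drop the lowest index.
    """
    if ensemble.n_structures < 3:
        raise ValueError("invariant-core detection needs ≥3 structures")
    if ensemble.n_positions < min_core:
        raise ValueError(
            f"only {ensemble.n_positions} common positions; min_core={min_core}"
        )
    core = np.arange(ensemble.n_positions)
    while True:
        coords = _superpose_onto_mean(ensemble.coords, core)
        vols = _ellipsoid_volumes(coords)
        core_vols = vols[core]
        if core_vols.max() <= volume_cutoff or core.size <= min_core:
            return CoreSelection(
                indices=core.copy(),
                volumes=vols,
                n_dropped=ensemble.n_positions - core.size,
            )
        core = np.delete(core, int(np.argmax(core_vols)))


# ---------------------------------------------------------------------------
# Pairwise RMSD and clustering

@dataclass
class ClusterTree:
    """Pairwise Cα RMSD matrix with an agglomerative clustering cut."""

    rmsd_matrix: np.ndarray  # (S, S), Å
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    groups: np.ndarray  # group index per structure, 1..k
    method: str = "complete"

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (ultrametric heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length / 2 + node.dist / 2:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length / 2:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});" \
            if not tree.is_leaf() else f"({self.labels[tree.id]});"


def pairwise_rmsd_and_cluster(
    ensemble: AlignedEnsemble,
    k: int,
    refit: bool = False,
    method: str = "complete",
) -> ClusterTree:
    """All-pairs Cα RMSD and an agglomerative cut into ``k`` groups.

    On a superposed ensemble, RMSD is measured in the common frame
    (no per-pair refit) unless ``refit`` is set.  Group labels are
    renumbered by order of first appearance, so they are stable under
    relabelling of the scipy cut.
    """
    s = ensemble.n_structures
    if k > s:
        raise ValueError(f"cannot cut {s} structures into {k} groups")
    d = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            if refit:
                xi, xj = ensemble.coords[:, i, :], ensemble.coords[:, j, :]
                rot, trans = _kabsch_arrays(xi, xj)
                d[i, j] = d[j, i] = rmsd_fixed(xi @ rot.T + trans, xj)
            else:
                d[i, j] = d[j, i] = rmsd_fixed(
                    ensemble.coords[:, i, :], ensemble.coords[:, j, :]
                )
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    groups = np.empty_like(raw)
    for i, g in enumerate(raw):
        remap.setdefault(g, len(remap) + 1)
        groups[i] = remap[g]
    return ClusterTree(
        rmsd_matrix=d, linkage=link, labels=list(ensemble.labels),
        groups=groups, method=method,
    )


# ---------------------------------------------------------------------------
# Cartesian PCA

@dataclass
class PCAResult:
    """Eigen-decomposition of the ensemble coordinate covariance.

    ``eigenvalues`` (Å², descending) has length 3·P; with S structures
    at most S−1 of them are nonzero.  ``mode_vectors[c]`` is the unit
    displacement direction of component ``c`` over the flattened
    (x₁,y₁,z₁,…) coordinate vector; ``projections[s, c]`` is structure
    s's score (Å) on component c.
    """

    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    cumulative_proportions: np.ndarray
    projections: np.ndarray  # (S, 3P)
    mean_coords: np.ndarray  # (P, 3)
    mode_vectors: np.ndarray  # (3P, ) rows: (n_components, 3P)
    labels: list[str]
    degenerate: bool = False

    @property
    def n_positions(self) -> int:
        return self.mean_coords.shape[0]


def pca_cartesian(ensemble: AlignedEnsemble) -> PCAResult:
    """PCA on the stacked Cartesian Cα coordinates of a superposed ensemble.

    Builds the mean-centered covariance of the 3P-dimensional
    coordinate vector across structures and eigen-decomposes it.  The
    variance proportion of a component is its eigenvalue over the
    eigenvalue sum; an ensemble of identical structures is flagged
    ``degenerate`` (zero total variance) with zero proportions rather
    than NaNs.  Mode signs are fixed by making each mode's
    largest-magnitude loading positive.
    """
    if ensemble.n_structures < 2:
        raise ValueError("PCA needs at least 2 structures")
    x = ensemble.coords.transpose(1, 0, 2).reshape(ensemble.n_structures, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # deterministic sign: largest-|loading| entry of each mode positive
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    vec = vec * flip
    total = float(lam.sum())
    degenerate = total <= 1e-12
    props = np.zeros_like(lam) if degenerate else lam / total
    return PCAResult(
        eigenvalues=lam,
        variance_proportions=props,
        cumulative_proportions=np.cumsum(props),
        projections=xc @ vec,
        mean_coords=mean.reshape(-1, 3),
        mode_vectors=vec.T,
        labels=list(ensemble.labels),
        degenerate=degenerate,
    )


def pca_report(pca: PCAResult, n_components: int = 10) -> pd.DataFrame:
    """Eigenvalue/variance table for the leading components."""
    n = min(n_components, pca.eigenvalues.size)
    return pd.DataFrame(
        {
            "component": np.arange(1, n + 1),
            "eigenvalue_A2": pca.eigenvalues[:n],
            "variance_pct": 100.0 * pca.variance_proportions[:n],
            "cumulative_pct": 100.0 * pca.cumulative_proportions[:n],
        }
    )


def export_mode_trajectory(
    pca: PCAResult,
    component: int,
    amplitude: float,
    n_frames: int = 11,
    template: Structure | None = None,
) -> list[Structure]:
    """Frames interpolating mean ± amplitude (Å) along one PCA mode.

    ``component`` is 0-based.  Frames are returned as Cα pseudo-
    structures (metadata borrowed from ``template`` when given) suitable
    for :func:`confensemble.structio.write_xyz` or PDB export.
    """
    if not 0 <= component < pca.mode_vectors.shape[0]:
        raise ValueError(
            f"component {component} out of range 0..{pca.mode_vectors.shape[0] - 1}"
        )
    if n_frames < 1:
        raise ValueError("need at least one frame")
    mode = pca.mode_vectors[component].reshape(-1, 3)
    scores = np.linspace(-amplitude, amplitude, n_frames) if n_frames > 1 else np.array([0.0])
    frames = []
    p = pca.n_positions
    for s in scores:
        coords = pca.mean_coords + s * mode
        if template is not None:
            ca = template.select("calpha")
            if ca.n_atoms != p:
                raise ValueError("template Cα count does not match the PCA positions")
            frame = ca.with_coords(coords)
        else:
            frame = Structure(
                elements=["C"] * p,
                coords=coords,
                atom_names=["CA"] * p,
                res_names=["GLY"] * p,
                res_numbers=np.arange(1, p + 1),
            )
        frame.title = f"mode {component + 1} displacement {s:+.3f} A"
        frames.append(frame)
    return frames
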