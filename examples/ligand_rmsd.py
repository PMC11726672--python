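"""Heavy-atom RMSD between conformers with optimal atom matching.

Chemically equivalent atoms (e.g. the two oxygens of a carboxylate)
can be labelled in either order by a conformer generator, so a naive
index-paired RMSD overstates the difference.  The permutation-optimal
RMSD alternates Hungarian assignment within each element with a rigid
refit until stable.
"""

import numpy as np

from confensemble import Structure, kabsch, ligand_heavy_rmsd

rng = np.random.default_rng(3)
mol = Structure(
    elements=["C", "C", "C", "N", "O", "O", "H", "H"],
    coords=rng.uniform(-3, 3, (8, 3)),
)

# the "other conformer": same molecule, rigidly moved, with the two
# oxygens' labels swapped and a little coordinate noise
perm = [0, 1, 2, 3, 5, 4, 6, 7]
other = mol.subset(perm)
rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
other = other.with_coords(other.coords @ rot.T + [5.0, 1.0, -2.0]
                          + rng.normal(0, 0.05, (8, 3)))

naive = kabsch(mol.heavy_atoms(), other.heavy_atoms()).rmsd
best, assignment = ligand_heavy_rmsd(mol, other)
print(f"index-paired RMSD:        {naive:.3f} A")
print(f"permutation-optimal RMSD: {best:.3f} A")
print(f"recovered assignment:     {assignment.tolist()}")
# The optimal value is near the 0.05 A noise floor; the naive pairing is
# inflated by the swapped oxygen labels.
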