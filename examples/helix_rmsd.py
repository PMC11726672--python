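"""Per-transmembrane-helix backbone RMSD between two receptor states.

Builds two synthetic μ-opioid-receptor-like backbones in which helix 6
is rigidly displaced by 2 Å — the hallmark outward swing of GPCR
activation — and reports backbone RMSD per helix after a single fit on
the conserved region (residues 66-349, human numbering; a mouse-
numbered structure would first get renumber_offset(+2)).
"""

import numpy as np

from confensemble import Structure, region_rmsd_report


def make_receptor(displace_tm6=False, noise_seed=1):
    """A helical Cα/backbone trace spanning the receptor numbering."""
    rng = np.random.default_rng(noise_seed)
    elements, names, resnums, coords = [], [], [], []
    for r in range(60, 361):
        t = np.deg2rad(100.0 * r)
        base = np.array([8.0 * np.cos(t), 8.0 * np.sin(t), 1.5 * r])
        shift = np.array([2.0, 0.0, 0.0]) if displace_tm6 and 270 <= r <= 308 \
            else np.zeros(3)
        for name, el, d in (("N", "N", (0.0, 0.0, 0.0)),
                            ("CA", "C", (0.8, 0.9, 0.2)),
                            ("C", "C", (1.8, 0.2, 0.5)),
                            ("O", "O", (2.2, -0.9, 0.5))):
            elements.append(el)
            names.append(name)
            resnums.append(r)
            coords.append(base + d + shift + rng.normal(0, 0.01, 3))
    return Structure(elements=elements, coords=np.array(coords),
                     atom_names=names, res_names=["ALA"] * len(names),
                     res_numbers=np.array(resnums))


inactive = make_receptor()
active = make_receptor(displace_tm6=True)

report = region_rmsd_report(inactive, active, selection="backbone",
                            fit_region="conserved")
print("region      RMSD (A)   atoms")
for _, row in report.iterrows():
    print(f"{row['region']:<10s} {row['rmsd_A']:8.3f}   {row['n_atoms']:5d}")
# After superposing on the whole conserved core, helices that move
# relative to that core retain a large residual RMSD: TM6 stands out,
# while the others stay near the coordinate-noise floor.
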