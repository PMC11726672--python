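import sys
from pathlib import Path

import numpy as np
import pytest

from confensemble.structio import Structure

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

WATER_XYZ = """3
water frame
O   0.000000   0.000000   0.117300
H   0.000000   0.757200  -0.469200
H   0.000000  -0.757200  -0.469200
"""


@pytest.fixture
def water_xyz(tmp_path):
    p = tmp_path / "water.xyz"
    p.write_text(WATER_XYZ)
    return p


def _pdb_atom(serial, name, resname, chain, resnum, x, y, z, element, altloc=" "):
    field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {field}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def make_peptide_pdb_text(
    chains=("A", "B"), n_res=3, two_models=False, altloc_res=None, hetatm=False
):
    """A tiny synthetic peptide PDB with backbone + CB + H atoms."""
    lines = []
    serial = 1

    def chain_block(offset):
        nonlocal serial
        out = []
        for ci, ch in enumerate(chains):
            for r in range(1, n_res + 1):
                base = np.array([3.8 * r + offset, 10.0 * ci, 0.0])
                atoms = [
                    ("N", "N", (0.0, 0.0, 0.0)),
                    ("CA", "C", (1.0, 0.5, 0.0)),
                    ("C", "C", (2.0, 0.0, 0.3)),
                    ("O", "O", (2.5, -1.0, 0.3)),
                    ("CB", "C", (1.0, 1.5, 1.0)),
                    ("H", "H", (-0.5, 0.5, 0.2)),
                ]
                for name, el, d in atoms:
                    if altloc_res == (ch, r) and name == "CB":
                        for alt, dx in (("A", 0.0), ("B", 0.4)):
                            out.append(
                                _pdb_atom(serial, name, "ALA", ch, r,
                                          *(base + d + np.array([dx, 0, 0])),
                                          el, altloc=alt)
                            )
                            serial += 1
                    else:
                        out.append(
                            _pdb_atom(serial, name, "ALA", ch, r, *(base + d), el)
                        )
                        serial += 1
        return out

    if two_models:
        lines += ["MODEL        1", *chain_block(0.0), "ENDMDL"]
        lines += ["MODEL        2", *chain_block(100.0), "ENDMDL"]
    else:
        lines += chain_block(0.0)
    if hetatm:
        lines.append(
            "HETATM" + _pdb_atom(serial, "O", "HOH", chains[0], 99,
                                 50.0, 50.0, 50.0, "O")[6:]
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def peptide_pdb(tmp_path):
    p = tmp_path / "pept.pdb"
    p.write_text(make_peptide_pdb_text())
    return p


def make_receptor(seed=0, res_range=(60, 360), displace=None):
    """Synthetic receptor backbone covering the TM residue numbering.

    ``displace`` maps an inclusive residue interval to a rigid (3,)
    shift applied to every atom of those residues.
    """
    rng = np.random.default_rng(seed)
    elements, names, resnames, resnums, coords = [], [], [], [], []
    lo, hi = res_range
    for r in range(lo, hi + 1):
        t = r * 100.0 * np.pi / 180.0
        base = np.array([8.0 * np.cos(t), 8.0 * np.sin(t), 1.5 * r])
        for name, el, d in (
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (0.8, 0.9, 0.2)),
            ("C", "C", (1.8, 0.2, 0.5)),
            ("O", "O", (2.2, -0.9, 0.5)),
        ):
            shift = np.zeros(3)
            if displace:
                for (a, b), v in displace.items():
                    if a <= r <= b:
                        shift = np.asarray(v, dtype=float)
            elements.append(el)
            names.append(name)
            resnames.append("ALA")
            resnums.append(r)
            coords.append(base + np.array(d) + shift + rng.normal(0, 0.01, 3))
    return Structure(
        elements=elements,
        coords=np.array(coords),
        atom_names=names,
        res_names=resnames,
        res_numbers=np.array(resnums),
        chain_ids=["A"] * len(elements),
        title=f"receptor_{seed}",
    )


@pytest.fixture
def receptor_pair():
    a = make_receptor(seed=1)
    b = make_receptor(seed=2)
    return a, b


def make_molecule(rng, n_atoms=6, elements=("C", "C", "C", "N", "O", "O")):
    coords = rng.uniform(-3, 3, size=(n_atoms, 3))
    return Structure(elements=list(elements), coords=coords)
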