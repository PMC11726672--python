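"""Readers and writers for the pipeline's external formats.

Covers multi-frame XYZ, a PDB subset (first model, blank/'A' altlocs,
ATOM vs HETATM selectable), FASTA sequences, and the delimited
energy/frequency table dialect consumed by the thermochemistry stages.

Units are fixed package-wide: coordinates in Å, electronic energies in
hartree, thermal corrections in kcal·mol⁻¹, frequencies in cm⁻¹,
rotational constants in GHz, masses in u.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO


class ParseError(ValueError):
    """Raised when an input file violates its documented dialect."""


#: atom-name sets for the named selections; ``all`` keeps everything
SELECTIONS: dict[str, frozenset[str] | None] = {
    "all": None,
    "backbone": frozenset({"N", "CA", "C", "O"}),
    "calpha": frozenset({"CA"}),
}

#: energy-table column -> level key used throughout the package
ENERGY_COLUMNS: dict[str, str] = {
    "e_dz_hartree": "dz",
    "e_tz_hartree": "tz",
    "e_qz_hartree": "qz",
    "e_dft_hartree": "dft",
}


def _normalize_element(symbol: str) -> str:
    sym = symbol.strip()
    sym = sym[:1].upper() + sym[1:].lower()
    if gemmi.Element(sym).atomic_number == 0:
        raise ParseError(f"unknown element symbol {symbol!r}")
    return sym


def element_mass(symbol: str) -> float:
    """Standard atomic weight (u) of an element symbol."""
    return gemmi.Element(_normalize_element(symbol)).weight


@dataclass
class Structure:
    """An ordered set of atoms with coordinates in Å.

    Atom order is preserved exactly as read from the source file; all
    per-atom fields are parallel arrays/lists of equal length.
    """

    elements: list[str]
    coords: np.ndarray
    atom_names: list[str] = field(default_factory=list)
    res_names: list[str] = field(default_factory=list)
    res_numbers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    chain_ids: list[str] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if not self.atom_names:
            self.atom_names = list(self.elements)
        if not self.res_names:
            self.res_names = ["MOL"] * n
        if len(self.res_numbers) == 0:
            self.res_numbers = np.ones(n, dtype=int)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        if not self.chain_ids:
            self.chain_ids = ["A"] * n
        lengths = {
            len(self.elements),
            self.coords.shape[0],
            len(self.atom_names),
            len(self.res_names),
            len(self.res_numbers),
            len(self.chain_ids),
        }
        if len(lengths) != 1:
            raise ValueError(f"inconsistent per-atom field lengths: {sorted(lengths)}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.elements = [_normalize_element(e) for e in self.elements]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            elements=[self.elements[i] for i in idx],
            coords=self.coords[idx].copy(),
            atom_names=[self.atom_names[i] for i in idx],
            res_names=[self.res_names[i] for i in idx],
            res_numbers=self.res_numbers[idx].copy(),
            chain_ids=[self.chain_ids[i] for i in idx],
            title=self.title,
        )

    def select(self, selection: str) -> "Structure":
        """Subset by a named atom selection (``all``/``backbone``/``calpha``)."""
        if selection not in SELECTIONS:
            raise ValueError(
                f"unknown selection {selection!r}; choose from {sorted(SELECTIONS)}"
            )
        names = SELECTIONS[selection]
        if names is None:
            return self.subset(np.arange(self.n_atoms))
        idx = [i for i, nm in enumerate(self.atom_names) if nm in names]
        return self.subset(idx)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = replace(self)
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if out.coords.shape[0] != self.n_atoms:
            raise ValueError("coordinate count changed")
        return out

    def heavy_atoms(self) -> "Structure":
        return self.subset([i for i, e in enumerate(self.elements) if e != "H"])

    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.elements])


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path: str | Path) -> list[Structure]:
    """Read a (multi-frame) XYZ file into one Structure per frame."""
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if i + 1 + count >= len(lines) + 1 and count > 0:
            pass
        title = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + count]
        if len(body) < count:
            raise ParseError(
                f"{path}: line {i + 1}: frame declares {count} atoms but only "
                f"{len(body)} coordinate lines follow"
            )
        elements: list[str] = []
        coords = np.empty((count, 3))
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i + 3 + j}: malformed atom line {ln!r}")
            elements.append(parts[0])
            try:
                coords[j] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate in {ln!r}"
                ) from None
        try:
            frames.append(Structure(elements=elements, coords=coords, title=title.strip()))
        except ParseError as exc:
            raise ParseError(f"{path}: frame at line {i + 1}: {exc}") from None
        i += 2 + count
    if not frames:
        raise ParseError(f"{path}: no XYZ frames found")
    return frames


def write_xyz(structures: Structure | Iterable[Structure], path: str | Path) -> None:
    if isinstance(structures, Structure):
        structures = [structures]
    chunks = []
    for s in structures:
        body = "\n".join(
            f"{e:<2s} {x: 15.8f} {y: 15.8f} {z: 15.8f}"
            for e, (x, y, z) in zip(s.elements, s.coords)
        )
        chunks.append(f"{s.n_atoms}\n{s.title}\n{body}")
    _atomic_write(path, "\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# PDB

def read_pdb_chain(
    path: str | Path,
    chain: str,
    selection: str = "all",
    records: str = "ATOM",
) -> Structure:
    """Read one chain of a PDB file into a Structure.

    Only the first model is used; alternate locations other than blank or
    'A' are discarded; residues carrying insertion codes are rejected.
    ``records`` chooses ``ATOM`` (polymer, default), ``HETATM`` (ligands,
    waters), or ``both``.
    """
    if selection not in SELECTIONS:
        raise ValueError(
            f"unknown selection {selection!r}; choose from {sorted(SELECTIONS)}"
        )
    if records not in ("ATOM", "HETATM", "both"):
        raise ValueError("records must be 'ATOM', 'HETATM' or 'both'")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = st[0]
    chains = [ch.name for ch in model]
    # gemmi may split one author chain into several objects (polymer,
    # ligands, waters); gather them all
    targets = [ch for ch in model if ch.name == chain]
    if not targets:
        raise ParseError(
            f"{path}: chain {chain!r} not present; available chains: "
            + ", ".join(sorted(set(chains)))
        )
    keep_names = SELECTIONS[selection]
    elements, names, resnames, resnums, chainids, xyz = [], [], [], [], [], []
    for res in (r for ch in targets for r in ch):
        if records == "ATOM" and res.het_flag != "A":
            continue
        if records == "HETATM" and res.het_flag != "H":
            continue
        if res.seqid.icode not in (" ", "\0", ""):
            raise ParseError(
                f"{path}: residue {res.name} {res.seqid.num}{res.seqid.icode.strip()} "
                "carries an insertion code; renumber the structure first"
            )
        for atom in res:
            if atom.altloc not in ("", "\0", "A"):
                continue
            if keep_names is not None and atom.name not in keep_names:
                continue
            elements.append(atom.element.name)
            names.append(atom.name)
            resnames.append(res.name)
            resnums.append(res.seqid.num)
            chainids.append(chain)
            xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not elements:
        raise ParseError(
            f"{path}: chain {chain!r} has no atoms after selection "
            f"{selection!r} with records={records!r}"
        )
    return Structure(
        elements=elements,
        coords=np.array(xyz),
        atom_names=names,
        res_names=resnames,
        res_numbers=np.array(resnums, dtype=int),
        chain_ids=chainids,
        title=f"{Path(path).stem}:{chain}",
    )


def write_pdb(structures: Structure | Iterable[Structure], path: str | Path) -> None:
    """Write structures as PDB ATOM records (multiple → MODEL blocks)."""
    if isinstance(structures, Structure):
        structures = [structures]
    structures = list(structures)
    out: list[str] = []
    multi = len(structures) > 1
    for m, s in enumerate(structures, start=1):
        if multi:
            out.append(f"MODEL     {m:4d}")
        for i in range(s.n_atoms):
            name = s.atom_names[i]
            # PDB column-13 convention: 1-3 char names start in column 14
            field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = s.coords[i]
            out.append(
                f"ATOM  {i + 1:5d} {field}{'':1s}{s.res_names[i]:>3s} "
                f"{s.chain_ids[i][:1]}{int(s.res_numbers[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {s.elements[i]:>2s}"
            )
        out.append("ENDMDL" if multi else "TER")
    out.append("END")
    _atomic_write(path, "\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicated sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


# ---------------------------------------------------------------------------
# Energy tables

@dataclass
class ConformerRecord:
    """One conformer's tabulated energetics.

    ``energies`` maps level keys (``dz``/``tz``/``qz``/``dft``) to
    electronic energies in hartree; ``frequencies`` are harmonic
    wavenumbers in cm⁻¹ (negative values tag imaginary modes);
    ``rot_constants`` are the three rotational constants in GHz.
    """

    conformer_id: str
    energies: dict[str, float]
    frequencies: np.ndarray
    rot_constants: np.ndarray | None
    mass: float

    def __post_init__(self) -> None:
        if not self.energies:
            raise ParseError(
                f"conformer {self.conformer_id!r}: needs at least one electronic energy"
            )
        if not self.mass > 0:
            raise ParseError(f"conformer {self.conformer_id!r}: mass must be positive")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.rot_constants is not None:
            self.rot_constants = np.asarray(self.rot_constants, dtype=float)
            if self.rot_constants.shape != (3,):
                raise ParseError(
                    f"conformer {self.conformer_id!r}: expected 3 rotational constants"
                )
            if np.any(self.rot_constants < 0):
                raise ParseError(
                    f"conformer {self.conformer_id!r}: negative rotational constant"
                )

    @property
    def cbs_eligible(self) -> bool:
        """True when the DZ/TZ/QZ series is complete."""
        return all(k in self.energies for k in ("dz", "tz", "qz"))


@dataclass
class EnergyTable:
    """Conformer records keyed by unique conformer id."""

    records: list[ConformerRecord]

    def __post_init__(self) -> None:
        ids = [r.conformer_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ParseError(f"duplicated conformer id(s): {sorted(dupes)}")
        self._by_id = {r.conformer_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ConformerRecord]:
        return iter(self.records)

    def __getitem__(self, conformer_id: str) -> ConformerRecord:
        return self._by_id[conformer_id]

    @property
    def ids(self) -> list[str]:
        return [r.conformer_id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {"conformer_id": r.conformer_id}
            for col, key in ENERGY_COLUMNS.items():
                row[col] = r.energies.get(key, np.nan)
            row["freqs_cm1"] = ";".join(f"{f:.4f}" for f in r.frequencies)
            row["rotconst_ghz"] = (
                ";".join(f"{b:.9f}" for b in r.rot_constants)
                if r.rot_constants is not None
                else ""
            )
            row["mass_u"] = r.mass
            rows.append(row)
        return pd.DataFrame(rows)


def _split_floats(cell: object, what: str, row_id: str) -> np.ndarray:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return np.empty(0)
    try:
        return np.array([float(x) for x in str(cell).split(";") if x.strip() != ""])
    except ValueError:
        raise ParseError(f"row {row_id!r}: non-numeric {what} cell {cell!r}") from None


def read_energy_table(path: str | Path) -> EnergyTable:
    """Read the CSV/TSV energy-table dialect (delimiter inferred)."""
    header = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"conformer_id": str})
    for required in ("conformer_id", "mass_u"):
        if required not in df.columns:
            raise ParseError(f"{path}: missing required column {required!r}")
    if not any(c in df.columns for c in ENERGY_COLUMNS):
        raise ParseError(
            f"{path}: needs at least one electronic-energy column "
            f"({', '.join(ENERGY_COLUMNS)})"
        )
    records = []
    for _, row in df.iterrows():
        rid = str(row["conformer_id"])
        energies = {}
        for col, key in ENERGY_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                try:
                    energies[key] = float(row[col])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: row {rid!r}: non-numeric cell in {col!r}: {row[col]!r}"
                    ) from None
        freqs = _split_floats(row.get("freqs_cm1"), "frequency", rid)
        rot = _split_floats(row.get("rotconst_ghz"), "rotational-constant", rid)
        try:
            mass = float(row["mass_u"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: row {rid!r}: non-numeric mass_u") from None
        records.append(
            ConformerRecord(
                conformer_id=rid,
                energies=energies,
                frequencies=freqs,
                rot_constants=rot if rot.size else None,
                mass=mass,
            )
        )
    try:
        return EnergyTable(records)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    _atomic_write(path, table.to_dataframe().to_csv(index=False))


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV atomically (column names carry units)."""
    _atomic_write(path, df.to_csv(index=False))


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
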