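"""TRIPOS MOL2 writing and reading with per-atom partial charges.

A charged MOL2 (@<TRIPOS>MOLECULE / ATOM / BOND blocks) is the interchange
format for the interaction-energy pipeline: the ninth ATOM column carries
the partial charge to four decimals, and the bond block mirrors the
perceived connectivity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .energy import ChargeSet, perceive_bonds
from .structmodel import AtomRecord, ComplexModel, MolecularStructure, Role

__all__ = ["write_mol2", "read_mol2"]

_SYBYL = {
    "H": "H", "C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3", "ZN": "Zn",
}


def _sybyl_type(atom: AtomRecord) -> str:
    el = atom.element.upper()
    if el == "C" and atom.name == "C":
        return "C.2"
    if el == "O" and atom.name in ("O", "OXT"):
        return "O.2"
    if el == "N" and atom.name == "N":
        return "N.am"
    return _SYBYL.get(el, el.capitalize())


def write_mol2(model: ComplexModel, charges: ChargeSet, path: str | Path) -> None:
    """Write target+ligand (then waters, ions) as charged TRIPOS MOL2.

    ``charges`` must supply exactly one charge per atom of the complex, in
    the complex atom order (target, ligand, waters, ions).
    """
    atoms = model.all_atoms()
    if len(charges) != len(atoms):
        raise ValueError(f"{len(charges)} charges for {len(atoms)} atoms")
    bond_rows = []
    offset = 0
    for struct in (model.target, model.ligand, model.waters, model.ions):
        for i, j in perceive_bonds(struct):
            bond_rows.append((offset + i + 1, offset + j + 1))
        offset += len(struct.atoms)
    lines = [
        "@<TRIPOS>MOLECULE",
        model.target.label or "complex",
        f"{len(atoms):d} {len(bond_rows):d} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for n, (atom, q) in enumerate(zip(atoms, charges.charges), start=1):
        x, y, z = atom.position
        lines.append(
            f"{n:>7d} {atom.name:<8s}{x:>10.4f}{y:>10.4f}{z:>10.4f} "
            f"{_sybyl_type(atom):<8s}{atom.residue_index:>4d} "
            f"{atom.residue_name:<8s}{q:>10.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for n, (i, j) in enumerate(bond_rows, start=1):
        lines.append(f"{n:>6d}{i:>6d}{j:>6d} 1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mol2(path: str | Path) -> tuple[list[dict], np.ndarray, list[tuple[int, int]]]:
    """Parse a TRIPOS MOL2 file into atom records, charges and bonds.

    Returns (atoms, charges, bonds) with atoms as dicts carrying name,
    position, sybyl type, residue index and name; bonds as 0-based pairs.
    """
    atoms: list[dict] = []
    charges: list[float] = []
    bonds: list[tuple[int, int]] = []
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:]
            continue
        if not line or section is None:
            continue
        if section == "ATOM":
            parts = line.split()
            atoms.append(
                {
                    "name": parts[1],
                    "position": np.array([float(parts[2]), float(parts[3]), float(parts[4])]),
                    "sybyl": parts[5],
                    "residue_index": int(parts[6]) if len(parts) > 6 else 1,
                    "residue_name": parts[7] if len(parts) > 7 else "UNK",
                }
            )
            charges.append(float(parts[8]) if len(parts) > 8 else 0.0)
        elif section == "BOND":
            parts = line.split()
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
    return atoms, np.array(charges), bonds
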