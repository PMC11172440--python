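"""Structure data model, PDB I/O, atom selection, correspondence and superposition.

All downstream metrics operate on :class:`ComplexModel`, a partition of a
target-ligand complex into four role groups (target protein, peptide ligand,
waters, structural ions).  Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Role",
    "AtomRecord",
    "MolecularStructure",
    "ComplexModel",
    "SelectionKind",
    "AtomSelection",
    "RigidTransform",
    "PDBFormatError",
    "RoleMappingError",
    "SelectionError",
    "CorrespondenceError",
    "SuperpositionError",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "resolve_selection",
    "correspond",
    "superpose_kabsch",
]

WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "WAT"})
ION_RESIDUE_NAMES = frozenset({"ZN", "NA", "CL", "MG", "MN", "K", "CA2", "FE"})

#: Standard amino-acid three-letter codes (calpha selections are limited to these).
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class PDBFormatError(ValueError):
    """Raised when an ATOM/HETATM record cannot be parsed."""


class RoleMappingError(KeyError):
    """Raised when a chain has no role assignment."""


class SelectionError(ValueError):
    """Raised when a selection resolves to no atoms."""


class CorrespondenceError(ValueError):
    """Raised when selected atoms of one structure lack partners in the other."""


class SuperpositionError(ValueError):
    """Raised on degenerate superposition input (<3 pairs or collinear points)."""


class Role(str, enum.Enum):
    TARGET = "target"
    LIGAND = "ligand"
    WATER = "water"
    ION = "ion"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a complex; houses the space vectors entering the RMSD sums."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray  # (3,) float, Angstrom
    role: Role

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite position")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.residue_name)


@dataclass
class MolecularStructure:
    """An ordered list of atoms forming one role group of a complex."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"{self.label or 'structure'}: duplicate atom serials")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in atoms])

    def heavy_coords(self) -> np.ndarray:
        return np.stack([a.position for a in self.atoms if a.is_heavy]) if self.atoms else np.empty((0, 3))

    def residues(self) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Group atoms by residue, preserving file order."""
        out: list[tuple[tuple[str, int, str], list[AtomRecord]]] = []
        for atom in self.atoms:
            if out and out[-1][0] == atom.residue_key:
                out[-1][1].append(atom)
            else:
                out.append((atom.residue_key, [atom]))
        return out

    def transformed(self, transform: "RigidTransform") -> "MolecularStructure":
        new_atoms = [
            replace(a, position=transform.apply(a.position[None, :])[0]) for a in self.atoms
        ]
        return MolecularStructure(new_atoms, self.label)


@dataclass
class ComplexModel:
    """A docked target-ligand complex partitioned by role.

    Structural Zn ions travel with the complex (they are treated as heavy
    atoms of the target for restraint purposes) but live in ``ions`` so the
    energy sums can exclude them.
    """

    target: MolecularStructure
    ligand: MolecularStructure
    waters: MolecularStructure = field(default_factory=lambda: MolecularStructure([], "waters"))
    ions: MolecularStructure = field(default_factory=lambda: MolecularStructure([], "ions"))

    def __post_init__(self):
        for struct, role in (
            (self.target, Role.TARGET),
            (self.ligand, Role.LIGAND),
            (self.waters, Role.WATER),
            (self.ions, Role.ION),
        ):
            for atom in struct.atoms:
                if atom.role is not role:
                    raise ValueError(
                        f"atom {atom.serial} {atom.name} has role {atom.role.value}, "
                        f"stored in {role.value} container"
                    )

    def group(self, role: Role) -> MolecularStructure:
        return {
            Role.TARGET: self.target,
            Role.LIGAND: self.ligand,
            Role.WATER: self.waters,
            Role.ION: self.ions,
        }[role]

    def all_atoms(self) -> list[AtomRecord]:
        return self.target.atoms + self.ligand.atoms + self.waters.atoms + self.ions.atoms

    def transformed(self, transform: "RigidTransform") -> "ComplexModel":
        return ComplexModel(
            self.target.transformed(transform),
            self.ligand.transformed(transform),
            self.waters.transformed(transform),
            self.ions.transformed(transform),
        )


class SelectionKind(str, enum.Enum):
    ALL_HEAVY = "all_heavy"
    BACKBONE = "backbone"
    CALPHA = "calpha"
    N_TERMINAL_K = "n_terminal_k"
    CUSTOM = "custom"


_BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")


@dataclass
class AtomSelection:
    """A predicate over the atoms of one role group plus its resolved indices.

    ``indices`` index into the role group's atom list and are strictly
    increasing once resolved.
    """

    kind: SelectionKind
    k: int | None = None  # for n_terminal_k
    names: tuple[str, ...] | None = None  # for custom
    indices: tuple[int, ...] | None = None

    @classmethod
    def all_heavy(cls) -> "AtomSelection":
        return cls(SelectionKind.ALL_HEAVY)

    @classmethod
    def backbone(cls) -> "AtomSelection":
        return cls(SelectionKind.BACKBONE)

    @classmethod
    def calpha(cls) -> "AtomSelection":
        return cls(SelectionKind.CALPHA)

    @classmethod
    def n_terminal(cls, k: int) -> "AtomSelection":
        return cls(SelectionKind.N_TERMINAL_K, k=k)

    @classmethod
    def custom(cls, names: Iterable[str]) -> "AtomSelection":
        return cls(SelectionKind.CUSTOM, names=tuple(names))


def _match(atom: AtomRecord, sel: AtomSelection, residue_rank: int) -> bool:
    if sel.kind is SelectionKind.ALL_HEAVY:
        return atom.is_heavy
    if sel.kind is SelectionKind.BACKBONE:
        return atom.name in _BACKBONE_NAMES and atom.residue_name in AMINO_ACIDS
    if sel.kind is SelectionKind.CALPHA:
        return atom.name == "CA" and atom.residue_name in AMINO_ACIDS
    if sel.kind is SelectionKind.N_TERMINAL_K:
        return atom.is_heavy and residue_rank < (sel.k or 0)
    if sel.kind is SelectionKind.CUSTOM:
        return atom.name in (sel.names or ())
    raise ValueError(sel.kind)


def resolve_selection(model: ComplexModel, sel: AtomSelection, on: Role) -> AtomSelection:
    """Resolve ``sel`` against one role group of ``model``.

    ``n_terminal_k`` counts residues in chain order starting from the first
    residue of the (single-chain) ligand, so it is only meaningful with
    ``on=Role.LIGAND``.
    """
    struct = model.group(on)
    residue_rank: dict[tuple[str, int, str], int] = {}
    for rank, (key, _) in enumerate(struct.residues()):
        residue_rank[key] = rank
    indices = tuple(
        i for i, atom in enumerate(struct.atoms) if _match(atom, sel, residue_rank[atom.residue_key])
    )
    if not indices:
        raise SelectionError(f"selection {sel.kind.value} resolves to no atoms on {on.value}")
    return replace(sel, indices=indices)


def correspond(
    a: MolecularStructure, b: MolecularStructure, sel: AtomSelection
) -> tuple[list[int], list[int]]:
    """Pair selected atoms of ``a`` with atoms of ``b`` by residue identity and name.

    Pairing key is (chain_id, residue_index, atom_name); output follows a's
    order.  Raises :class:`CorrespondenceError` naming every unpaired atom.
    """
    if sel.indices is None:
        raise ValueError("selection must be resolved before correspondence")
    b_lookup: dict[tuple[str, int, str], int] = {}
    for j, atom in enumerate(b.atoms):
        b_lookup.setdefault((atom.chain_id, atom.residue_index, atom.name), j)
    ia, ib, missing = [], [], []
    for i in sel.indices:
        atom = a.atoms[i]
        key = (atom.chain_id, atom.residue_index, atom.name)
        j = b_lookup.get(key)
        if j is None:
            missing.append(f"{atom.chain_id}/{atom.residue_name}{atom.residue_index}/{atom.name}")
        else:
            ia.append(i)
            ib.append(j)
    if missing:
        raise CorrespondenceError(f"no partner for {len(missing)} atoms: {', '.join(missing)}")
    return ia, ib


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def superpose_kabsch(
    mobile: ComplexModel,
    reference: ComplexModel,
    sel: AtomSelection,
    on: Role = Role.TARGET,
) -> RigidTransform:
    """Least-squares proper rigid fit of ``mobile`` onto ``reference``.

    The selection is resolved on ``on`` (target Calpha for trajectory fitting)
    and paired by residue identity.  Returns the transform that, applied to
    mobile, minimises the selection RMSD; reflections are never returned.
    """
    rsel = resolve_selection(mobile, sel, on)
    ia, ib = correspond(mobile.group(on), reference.group(on), rsel)
    if len(ia) < 3:
        raise SuperpositionError(f"need >=3 paired atoms, got {len(ia)}")
    mob = mobile.group(on).coords(ia)
    ref = reference.group(on).coords(ib)
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of centered mobile cloud
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise SuperpositionError("selected atoms are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------


def _validate_pdb_text(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBFormatError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise PDBFormatError(f"{path}:{lineno}: unparseable coordinates") from exc


def _classify(residue_name: str, chain_id: str, role_map: dict[str, Role | str]) -> Role:
    if residue_name in WATER_RESIDUE_NAMES:
        return Role.WATER
    if residue_name in ION_RESIDUE_NAMES:
        return Role.ION
    if chain_id not in role_map:
        raise RoleMappingError(
            f"chain {chain_id!r} (residue {residue_name}) has no role mapping"
        )
    return Role(role_map[chain_id])


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name, first on tie."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    return [best[name] for name in order]


def _model_to_complex(
    model: gemmi.Model, role_map: dict[str, Role | str], label: str
) -> ComplexModel:
    groups: dict[Role, list[AtomRecord]] = {r: [] for r in Role}
    for chain in model:
        for residue in chain:
            role = _classify(residue.name, chain.name, role_map)
            for atom in _pick_altlocs(residue):
                groups[role].append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_index=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        role=role,
                    )
                )
    return ComplexModel(
        MolecularStructure(groups[Role.TARGET], f"{label}:target"),
        MolecularStructure(groups[Role.LIGAND], f"{label}:ligand"),
        MolecularStructure(groups[Role.WATER], f"{label}:waters"),
        MolecularStructure(groups[Role.ION], f"{label}:ions"),
    )


def _read_structure(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBFormatError(f"{path}: {exc}") from exc
    return st

def read_pdb(path: str | Path, role_map: dict[str, Role | str]) -> ComplexModel:
    """Read one PDB file into a :class:`ComplexModel`.

    ``role_map`` maps chain ids to ``target`` or ``ligand``; waters
    (HOH/SOL/WAT) and ions (ZN, NA, ...) are classified by residue name
    regardless of chain.  Multi-model files yield the first model.
    """
    st = _read_structure(path)
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models")
    return _model_to_complex(st[0], role_map, Path(path).stem)


def read_pdb_models(path: str | Path, role_map: dict[str, Role | str]) -> list[ComplexModel]:
    """Read every MODEL of a (possibly multi-model) PDB file, e.g. an NMR ensemble."""
    st = _read_structure(path)
    return [_model_to_complex(m, role_map, f"{Path(path).stem}#{i + 1}") for i, m in enumerate(st)]


def _complex_to_model(model: ComplexModel, name: str = "1") -> gemmi.Model:
    gm = gemmi.Model(1)
    # chain order: roles in fixed order, original chain ids preserved
    for struct, het in (
        (model.target, False),
        (model.ligand, False),
        (model.waters, True),
        (model.ions, True),
    ):
        for atom in struct.atoms:
            chain = None
            for ch in gm:
                if ch.name == atom.chain_id:
                    chain = ch
                    break
            if chain is None:
                gm.add_chain(gemmi.Chain(atom.chain_id))
                chain = gm[len(gm) - 1]
            resname = "HOH" if atom.role is Role.WATER else atom.residue_name
            res = None
            if len(chain) > 0:
                last = chain[len(chain) - 1]
                if last.seqid.num == atom.residue_index and last.name == resname:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(atom.residue_index, " ")
                res.het_flag = "H" if het else "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.serial = atom.serial
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = 1.0
            res.add_atom(ga)
    return gm


def write_pdb(model: ComplexModel, path: str | Path) -> None:
    """Write a complex as standard PDB (coordinates to 3 decimals, waters as HOH)."""
    st = gemmi.Structure()
    st.add_model(_complex_to_model(model))
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def write_pdb_models(models: Sequence[ComplexModel], path: str | Path) -> None:
    """Write an ordered series of complexes as a multi-model PDB (MODEL/ENDMDL)."""
    st = gemmi.Structure()
    for i, m in enumerate(models):
        gm = _complex_to_model(m)
        gm.num = i + 1
        st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
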