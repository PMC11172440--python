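"""Per-residue target-ligand interaction energy with a distance-dependent dielectric.

The interaction energy between a target (N_T atoms) and a peptide ligand
(N_L atoms) is a pairwise sum of a Lennard-Jones and a screened Coulomb term,

    E_inter = E_LJ + E_Coulomb
            = sum_ij [ A_ij / r_ij^12 - B_ij / r_ij^6 ]
            + sum_ij [ K q_i q_j / (eps_r(r_ij) r_ij) ],

with Amber-style combination rules

    R_ij = R_i + R_j,   eps_ij = sqrt(eps_i eps_j),
    A_ij = eps_ij R_ij^12,   B_ij = 2 eps_ij R_ij^6,

and the sigmoidal Mehler-Solmajer dielectric

    eps_r(r) = A + B / (1 + k exp(-lambda B r)),   B = eps_water - A.

Units are kcal/mol, charges in elementary charge units, distances in
Angstrom; K = 332.06 kcal mol^-1 A e^-2 folds in 1/(4 pi eps_vacuum).  The
sum is decomposed per ligand residue (the partition of the full double sum),
which identifies anchoring residues: peptide positions whose strongly
negative E_inter dominates binding.  Waters and ions never enter the sums.

Partial charges follow the iterative partial equalization of orbital
electronegativities (PEOE, Gasteiger-Marsili): electronegativity is a
quadratic in the atomic charge, chi(q) = a + b q + c q^2, and each bond
transfers charge from the less to the more electronegative atom, damped by
(1/2)^n at iteration n, which conserves total formal charge exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structmodel import ComplexModel, MolecularStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ChargeSet",
    "LJParameterTable",
    "DielectricModel",
    "EnergyProfile",
    "ParameterizationError",
    "GeometryError",
    "COULOMB_CONSTANT",
    "AMBER_LJ",
    "perceive_bonds",
    "assign_gasteiger",
    "assign_complex_charges",
    "epsilon_r",
    "lj_pair_params",
    "lj_atom_params",
    "per_residue_einter",
    "total_einter",
    "anchoring_report",
]

#: Electrostatic constant for q in e, r in A, E in kcal/mol.
COULOMB_CONSTANT = 332.06


class ParameterizationError(KeyError):
    """An atom has no charge or LJ parameters."""


class GeometryError(ValueError):
    """Degenerate geometry (coincident atoms) in an energy evaluation."""


# ---------------------------------------------------------------------------
# Gasteiger-Marsili PEOE
# ---------------------------------------------------------------------------

# chi(q) = a + b q + c q^2 coefficients per (element, hybridization).
# Cation electronegativity chi+ = chi(+1) = a + b + c, except H (20.02).
_PEOE_PARAMS: dict[tuple[str, str | None], tuple[float, float, float]] = {
    ("H", None): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", None): (14.66, 13.85, 2.31),
    ("CL", None): (11.00, 9.69, 1.35),
    ("BR", None): (10.08, 8.47, 1.16),
    ("I", None): (9.90, 7.96, 0.96),
    ("S", None): (10.14, 9.13, 1.38),
}

_H_CATION_CHI = 20.02

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "ZN": 1.22,
}
_BOND_SLACK = 0.45  # A added to the sum of covalent radii

# Atom names that are sp2 in standard amino acids (used when no explicit
# hybridization is supplied; everything else defaults to sp3).
_SP2_NAMES: dict[str, frozenset[str]] = {
    "*": frozenset({"C", "O", "OXT", "N"}),  # backbone amide
    "ARG": frozenset({"CZ", "NE", "NH1", "NH2"}),
    "ASN": frozenset({"CG", "OD1", "ND2"}),
    "ASP": frozenset({"CG", "OD1", "OD2"}),
    "GLN": frozenset({"CD", "OE1", "NE2"}),
    "GLU": frozenset({"CD", "OE1", "OE2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
}

# Formal charge seeds at physiological pH, per (residue, atom name).
_FORMAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 1.0,
    ("ASP", "OD2"): -1.0,
    ("GLU", "OE2"): -1.0,
}


@dataclass
class ChargeSet:
    """Per-atom partial charges in elementary charge units."""

    charges: np.ndarray
    total_formal_charge: float
    method: str = "gasteiger"

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if abs(float(self.charges.sum()) - self.total_formal_charge) > 1e-6:
            raise ValueError(
                f"charges sum to {self.charges.sum():.8f}, expected "
                f"{self.total_formal_charge:.8f}"
            )

    def __len__(self) -> int:
        return len(self.charges)


def perceive_bonds(structure: MolecularStructure) -> list[tuple[int, int]]:
    """Distance-based covalent bond perception within one structure.

    Two atoms are bonded when their distance is below the sum of covalent
    radii plus 0.45 A; H-H pairs are never bonded.  Bonds are only perceived
    within a residue or between the backbone C/N of consecutive residues
    (plus disulfides), which keeps through-space contacts out of the graph.
    """
    atoms = structure.atoms
    if not atoms:
        return []
    coords = structure.coords()
    tree = cKDTree(coords)
    max_r = 2 * max(_COVALENT_RADII.values()) + _BOND_SLACK
    bonds = []
    for i, j in sorted(tree.query_pairs(max_r)):
        a, b = atoms[i], atoms[j]
        ea, eb = a.element.upper(), b.element.upper()
        if ea == "H" and eb == "H":
            continue
        ra = _COVALENT_RADII.get(ea)
        rb = _COVALENT_RADII.get(eb)
        if ra is None or rb is None:
            continue
        if np.linalg.norm(a.position - b.position) >= ra + rb + _BOND_SLACK:
            continue
        same_res = a.residue_key == b.residue_key
        peptide = (
            a.chain_id == b.chain_id
            and abs(a.residue_index - b.residue_index) == 1
            and {a.name, b.name} == {"C", "N"}
        )
        disulfide = ea == "S" and eb == "S"
        if same_res or peptide or disulfide:
            bonds.append((i, j))
    return bonds


def _default_hybridization(atom) -> str:
    if atom.residue_name in ("HOH", "SOL", "WAT"):
        return "sp3"
    names = _SP2_NAMES.get(atom.residue_name, frozenset()) | _SP2_NAMES["*"]
    return "sp2" if atom.name in names else "sp3"


def _peoe_coeffs(element: str, hybridization: str) -> tuple[float, float, float]:
    el = element.upper()
    for key in ((el, None), (el, hybridization)):
        if key in _PEOE_PARAMS:
            return _PEOE_PARAMS[key]
    raise ParameterizationError(f"no PEOE parameters for element {element} ({hybridization})")


def peoe_charges(
    elements: list[str],
    bonds: list[tuple[int, int]],
    hybridizations: list[str],
    formal_charges: np.ndarray | None = None,
    iterations: int = 6,
) -> np.ndarray:
    """Raw PEOE iteration on an explicit molecular graph.

    At iteration n every bond transfers ((chi_hi - chi_lo) / chi+_lo) (1/2)^n
    of an elementary charge from the less to the more electronegative atom,
    with chi+ the cation electronegativity of the less electronegative one;
    all transfers of one iteration are computed from the same charge state.
    """
    n_atoms = len(elements)
    abc = np.array([_peoe_coeffs(el, hyb) for el, hyb in zip(elements, hybridizations)])
    chi_plus = abc.sum(axis=1)
    for i, el in enumerate(elements):
        if el.upper() == "H":
            chi_plus[i] = _H_CATION_CHI
    q = np.zeros(n_atoms) if formal_charges is None else np.asarray(formal_charges, float).copy()
    for n in range(1, iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros(n_atoms)
        damp = 0.5 ** n
        for i, j in bonds:
            if chi[i] == chi[j]:
                continue
            lo, hi = (i, j) if chi[i] < chi[j] else (j, i)
            t = (chi[hi] - chi[lo]) / chi_plus[lo] * damp
            dq[lo] += t
            dq[hi] -= t
        q += dq
    return q


def assign_gasteiger(
    structure: MolecularStructure,
    iterations: int = 6,
    hydrogen_mode: str = "polar",
    bonds: list[tuple[int, int]] | None = None,
    hybridizations: list[str] | None = None,
    formal_charges: np.ndarray | None = None,
) -> ChargeSet:
    """PEOE partial charges for one structure.

    Connectivity is perceived from distances unless ``bonds`` is given;
    hybridizations come from an amino-acid name table unless supplied.
    Formal-charge seeds default to physiological protonation of Lys/Arg/
    Asp/Glu side chains.  ``hydrogen_mode="polar"`` folds the charge of every
    carbon-bound hydrogen into its carbon (AutoDock-style polar-H model);
    ``"all"`` keeps all-atom charges.
    """
    atoms = structure.atoms
    if bonds is None:
        bonds = perceive_bonds(structure)
    if hybridizations is None:
        hybridizations = [_default_hybridization(a) for a in atoms]
    if formal_charges is None:
        formal_charges = np.array(
            [_FORMAL_CHARGES.get((a.residue_name, a.name), 0.0) for a in atoms]
        )
    q = peoe_charges(
        [a.element for a in atoms], bonds, hybridizations, formal_charges, iterations
    )
    if hydrogen_mode == "polar":
        heavy_partner = {}
        for i, j in bonds:
            for h, x in ((i, j), (j, i)):
                if atoms[h].element.upper() == "H":
                    heavy_partner[h] = x
        for h, x in heavy_partner.items():
            if atoms[x].element.upper() == "C":
                q[x] += q[h]
                q[h] = 0.0
    elif hydrogen_mode != "all":
        raise ValueError(f"unknown hydrogen_mode {hydrogen_mode!r}")
    return ChargeSet(q, float(np.asarray(formal_charges).sum()), "gasteiger")


def assign_complex_charges(model: ComplexModel, **kwargs) -> ChargeSet:
    """Charges for target then ligand atoms, assigned per molecule."""
    ct = assign_gasteiger(model.target, **kwargs)
    cl = assign_gasteiger(model.ligand, **kwargs)
    return ChargeSet(
        np.concatenate([ct.charges, cl.charges]),
        ct.total_formal_charge + cl.total_formal_charge,
        "gasteiger",
    )


# ---------------------------------------------------------------------------
# Lennard-Jones parameters (Amber-style)
# ---------------------------------------------------------------------------


@dataclass
class LJParameterTable:
    """Per-type (R_i, eps_i) with R_i the half-minimum (Rmin/2) radius in A.

    The pair minimum then sits at R_ij = R_i + R_j with depth
    eps_ij = sqrt(eps_i eps_j) (kcal/mol).
    """

    entries: dict[str, tuple[float, float]]
    source: str = ""

    def __post_init__(self):
        for t, (r, e) in self.entries.items():
            if r <= 0 or e < 0:
                raise ValueError(f"type {t}: need R > 0 and eps >= 0, got ({r}, {e})")

    def __contains__(self, t: str) -> bool:
        return t in self.entries

    def __getitem__(self, t: str) -> tuple[float, float]:
        try:
            return self.entries[t]
        except KeyError:
            raise ParameterizationError(f"no LJ parameters for type {t!r}") from None


#: Amber protein force-field nonbonded set (Rmin/2 in A, eps in kcal/mol).
AMBER_LJ = LJParameterTable(
    {
        "H": (0.6000, 0.0157),   # H on N
        "HO": (0.3000, 0.0000),  # H on O (Amber gives it no dispersion)
        "HS": (0.6000, 0.0157),
        "HC": (1.4870, 0.0157),  # H on aliphatic C
        "HA": (1.4590, 0.0150),  # H on aromatic C
        "C": (1.9080, 0.0860),   # carbonyl / carboxylate C
        "CA": (1.9080, 0.0860),  # aromatic C
        "CT": (1.9080, 0.1094),  # aliphatic C
        "N": (1.8240, 0.1700),   # all N classes share these values
        "O": (1.6612, 0.2100),   # carbonyl O
        "O2": (1.6612, 0.2100),  # carboxylate O
        "OH": (1.7210, 0.2104),  # hydroxyl O
        "OW": (1.7683, 0.1520),  # TIP3P water O
        "S": (2.0000, 0.2500),
        "P": (2.1000, 0.2000),
        "ZN": (1.1000, 0.0125),
    },
    source="Amber protein force-field nonbonded parameters",
)

_AROMATIC_C = {
    ("PHE", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TYR", n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TRP", n) for n in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
} | {
    ("HIS", n) for n in ("CG", "CD2", "CE1")
}
_CARBONYL_C = {("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ")}
_HYDROXYL_O = {"OG", "OG1", "OH"}
_CARBOXYLATE_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

_ELEMENT_FALLBACK = {"C": "CT", "N": "N", "O": "O", "H": "HC", "S": "S", "P": "P", "ZN": "ZN"}


def lj_atom_type(atom, h_partner_element: str | None = None) -> str:
    """Amber LJ class of one atom from residue/atom-name lookup.

    ``h_partner_element`` is the element the hydrogen is bonded to, when
    connectivity is available; unknown atoms fall back to element defaults
    with a logged warning.
    """
    el = atom.element.upper()
    name = atom.name
    res = atom.residue_name
    if el == "H":
        partner = (h_partner_element or "").upper()
        if partner == "N":
            return "H"
        if partner == "O":
            return "HO"
        if partner == "S":
            return "HS"
        return "HC"
    if el == "C":
        if name == "C" or (res, name) in _CARBONYL_C:
            return "C"
        if (res, name) in _AROMATIC_C:
            return "CA"
        return "CT"
    if el == "N":
        return "N"
    if el == "O":
        if name in ("O", "OXT") or (res, name) in _CARBOXYLATE_O:
            return "O2" if (res, name) in _CARBOXYLATE_O or name == "OXT" else "O"
        if name in _HYDROXYL_O:
            return "OH"
        if res in ("HOH", "SOL", "WAT"):
            return "OW"
        return "O"
    if el in _ELEMENT_FALLBACK:
        return _ELEMENT_FALLBACK[el]
    logger.warning("atom %s/%s%s/%s: no LJ class, falling back to CT",
                   atom.chain_id, res, atom.residue_index, name)
    return "CT"


def lj_pair_params(
    type_i: str, type_j: str, table: LJParameterTable = AMBER_LJ
) -> tuple[float, float]:
    """A_ij and B_ij of the 12-6 pair potential A/r^12 - B/r^6.

    R_ij = R_i + R_j and eps_ij = sqrt(eps_i eps_j), so the potential minimum
    sits exactly at r = R_ij with depth -eps_ij.
    """
    r_i, e_i = table[type_i]
    r_j, e_j = table[type_j]
    r_ij = r_i + r_j
    e_ij = np.sqrt(e_i * e_j)
    return e_ij * r_ij**12, 2.0 * e_ij * r_ij**6


def lj_atom_params(structure: MolecularStructure, table: LJParameterTable = AMBER_LJ):
    """Per-atom (Rmin/2, eps) arrays for a structure (H typed via connectivity)."""
    bonds = perceive_bonds(structure)
    partner: dict[int, str] = {}
    for i, j in bonds:
        for h, x in ((i, j), (j, i)):
            if structure.atoms[h].element.upper() == "H":
                partner[h] = structure.atoms[x].element
    r = np.empty(len(structure.atoms))
    e = np.empty(len(structure.atoms))
    for idx, atom in enumerate(structure.atoms):
        t = lj_atom_type(atom, partner.get(idx))
        r[idx], e[idx] = table[t]
    return r, e


# ---------------------------------------------------------------------------
# Distance-dependent dielectric
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DielectricModel:
    """Sigmoidal distance-dependent dielectric eps_r(r) = A + B/(1 + k e^{-lam B r}).

    B = eps_water - A, with eps_water the dielectric constant of bulk water at
    25 C; eps_r rises monotonically from a low short-range value to eps_water.
    Defaults are the Mehler-Solmajer constants.
    """

    A: float = -8.5525
    lam: float = 0.003627
    k: float = 7.7839
    eps_water: float = 78.4

    @property
    def B(self) -> float:
        return self.eps_water - self.A


def epsilon_r(r, model: DielectricModel = DielectricModel()):
    """Relative permittivity at separation r (A); accepts scalars or arrays."""
    r = np.asarray(r, dtype=float)
    B = model.B
    out = model.A + B / (1.0 + model.k * np.exp(-model.lam * B * r))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Per-residue interaction energy
# ---------------------------------------------------------------------------


@dataclass
class EnergyProfile:
    """Per-ligand-residue decomposition of E_inter = E_LJ + E_Coulomb (kcal/mol)."""

    residues: list[tuple[str, int, str]]  # (chain, index, name) in ligand order
    e_lj: np.ndarray
    e_coulomb: np.ndarray

    @property
    def e_inter(self) -> np.ndarray:
        return self.e_lj + self.e_coulomb

    @property
    def total_lj(self) -> float:
        return float(self.e_lj.sum())

    @property
    def total_coulomb(self) -> float:
        return float(self.e_coulomb.sum())

    @property
    def total(self) -> float:
        return float(self.e_inter.sum())

    def to_records(self) -> list[dict]:
        return [
            {
                "chain": c, "residue_index": i, "residue_name": n,
                "E_LJ": float(lj), "E_Coulomb": float(cb), "E_inter": float(lj + cb),
            }
            for (c, i, n), lj, cb in zip(self.residues, self.e_lj, self.e_coulomb)
        ]


def per_residue_einter(
    model: ComplexModel,
    charges: ChargeSet | None = None,
    table: LJParameterTable = AMBER_LJ,
    dielectric: DielectricModel = DielectricModel(),
    coulomb_constant: float = COULOMB_CONSTANT,
) -> EnergyProfile:
    """Full double-sum target-ligand interaction energy, split per ligand residue.

    ``charges`` covers target atoms followed by ligand atoms (as produced by
    :func:`assign_complex_charges`, the default when omitted).  No distance
    cutoff is applied; waters and ions are excluded from both sums.
    """
    if charges is None:
        charges = assign_complex_charges(model)
    n_t, n_l = len(model.target.atoms), len(model.ligand.atoms)
    if len(charges) != n_t + n_l:
        raise ValueError(
            f"charge set has {len(charges)} entries for {n_t}+{n_l} target+ligand atoms"
        )
    q_t = charges.charges[:n_t]
    q_l = charges.charges[n_t:]
    r_t, e_t = lj_atom_params(model.target, table)
    r_l, e_l = lj_atom_params(model.ligand, table)
    residues = []
    e_lj_out, e_cb_out = [], []
    tgt_xyz = model.target.coords()
    for key, atoms in model.ligand.residues():
        idx = [i for i, a in enumerate(model.ligand.atoms) if a.residue_key == key]
        lig_xyz = model.ligand.coords(idx)
        r = cdist(tgt_xyz, lig_xyz)
        if n_t and np.any(r < 1e-9):
            raise GeometryError(f"coincident target/ligand atoms at residue {key}")
        r_ij = r_t[:, None] + r_l[idx][None, :]
        e_ij = np.sqrt(e_t[:, None] * e_l[idx][None, :])
        a_ij = e_ij * r_ij**12
        b_ij = 2.0 * e_ij * r_ij**6
        e_lj = np.sum(a_ij / r**12 - b_ij / r**6) if n_t else 0.0
        qq = q_t[:, None] * q_l[idx][None, :]
        e_cb = np.sum(coulomb_constant * qq / (epsilon_r(r, dielectric) * r)) if n_t else 0.0
        residues.append(key)
        e_lj_out.append(float(e_lj))
        e_cb_out.append(float(e_cb))
    return EnergyProfile(residues, np.array(e_lj_out), np.array(e_cb_out))


def total_einter(profile: EnergyProfile) -> float:
    """Whole-ligand interaction energy: the sum of the per-residue partition."""
    return profile.total


def anchoring_report(profile: EnergyProfile, dominance: float = 0.5) -> dict:
    """Rank ligand residues by E_inter and flag dominant anchors.

    A residue is flagged as dominant when its (negative) E_inter contributes
    at least ``dominance`` of the (negative) total, the signature of an
    anchoring residue such as R2 of the histone H3 tail.
    """
    order = np.argsort(profile.e_inter)  # most favorable (most negative) first
    ranked = [
        {
            "residue": profile.residues[i],
            "E_inter": float(profile.e_inter[i]),
        }
        for i in order
    ]
    dominant = []
    if profile.total < 0:
        for i in order:
            if profile.e_inter[i] < 0 and profile.e_inter[i] / profile.total >= dominance:
                dominant.append(profile.residues[i])
    return {"ranked": ranked, "dominant": dominant, "total": profile.total}
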