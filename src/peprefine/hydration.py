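"""Interface hydration editing and water-position scoring.

Pre-MD hydration fills the docked target-ligand interface with explicitly
placed waters so that no void cavity survives into the simulation.  This
module implements the editing and validation arithmetic around that step:
stripping waters that clash with the docked ligand (default minimum distance
1.75 A), identifying interface waters (within 3.5 A of both partners),
one-to-one matching of predicted against reference water oxygens within a
1.5 A tolerance expressed as a success rate

    SR(%) = 100 * (count of matches) / (count of reference water positions),

and enumeration of bridging waters (simultaneously H-bond distance from a
ligand polar atom and a target polar atom).  All distances are measured
between water oxygen atoms; pre-equilibration hydrogen positions are not
trusted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import ComplexModel, MolecularStructure, Role

__all__ = [
    "WaterSource",
    "WaterSet",
    "WaterMatchResult",
    "WaterBridge",
    "DEFAULT_DMIN",
    "DEFAULT_DMAX",
    "DEFAULT_MATCH_TOLERANCE",
    "DEFAULT_HBOND_CUTOFF",
    "waters_as_set",
    "strip_clashing_waters",
    "interface_waters",
    "match_waters",
    "find_water_bridges",
    "bridges_by_residue",
]

DEFAULT_DMIN = 1.75  # A, ligand-clash strip threshold
DEFAULT_DMAX = 3.5  # A, interface membership threshold
DEFAULT_MATCH_TOLERANCE = 1.5  # A, O-O match tolerance
DEFAULT_HBOND_CUTOFF = 3.5  # A, heavy-atom H-bond distance

_POLAR_ELEMENTS = ("N", "O")


class WaterSource(str, enum.Enum):
    PREDICTED = "predicted"
    CRYSTALLOGRAPHIC = "crystallographic"
    TRAJECTORY = "trajectory"


@dataclass
class WaterSet:
    """Water oxygen positions, one per water residue."""

    residue_ids: list[int]
    oxygens: np.ndarray  # (n, 3)
    source: WaterSource = WaterSource.PREDICTED

    def __post_init__(self):
        self.oxygens = np.asarray(self.oxygens, dtype=float).reshape(-1, 3)
        if len(self.residue_ids) != len(self.oxygens):
            raise ValueError("one oxygen position per water residue id required")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("duplicate water residue ids")

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class WaterMatchResult:
    """One-to-one predicted/reference water matching and its success rate."""

    matches: list[tuple[int, int, float]]  # (predicted id, reference id, distance A)
    n_reference: int
    tolerance: float
    #: True when the reference set was empty and SR is undefined (NaN), not 0.
    undefined: bool = False

    @property
    def success_rate(self) -> float:
        if self.undefined:
            return math.nan
        return 100.0 * len(self.matches) / self.n_reference


@dataclass(frozen=True)
class WaterBridge:
    """A water bridging a ligand polar atom and a target polar atom."""

    water_residue_id: int
    ligand_atom: str  # "chain/RESname index/atom"
    ligand_residue_index: int
    target_atom: str
    d_ligand: float
    d_target: float


def waters_as_set(
    model: ComplexModel, source: WaterSource = WaterSource.PREDICTED
) -> WaterSet:
    """Extract the water oxygens of a complex as a :class:`WaterSet`."""
    ids, pos = [], []
    for (chain, resid, name), atoms in model.waters.residues():
        oxy = [a for a in atoms if a.element.upper() == "O"]
        if len(oxy) != 1:
            raise ValueError(f"water {chain}/{name}{resid} has {len(oxy)} oxygen atoms")
        ids.append(resid)
        pos.append(oxy[0].position)
    return WaterSet(ids, np.array(pos).reshape(-1, 3), source)


def strip_clashing_waters(
    hydrated_target: ComplexModel,
    ligand: MolecularStructure,
    dmin: float = DEFAULT_DMIN,
) -> ComplexModel:
    """Remove waters clashing with the docked ligand and merge the complex.

    A water is removed (whole residue) when its oxygen lies strictly closer
    than ``dmin`` to any ligand heavy atom; a water at exactly ``dmin`` is
    retained.  Returns a merged complex of target, ligand, surviving waters
    and ions, all in the input coordinate frame.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    lig_heavy = ligand.heavy_coords()
    surviving = []
    if len(lig_heavy) == 0:
        surviving = list(hydrated_target.waters.atoms)
    else:
        tree = cKDTree(lig_heavy)
        for key, atoms in hydrated_target.waters.residues():
            oxy = [a for a in atoms if a.element.upper() == "O"]
            if not oxy:
                continue
            d, _ = tree.query(oxy[0].position)
            if d >= dmin:
                surviving.extend(atoms)
    return ComplexModel(
        hydrated_target.target,
        ligand,
        MolecularStructure(surviving, "waters"),
        hydrated_target.ions,
    )


def interface_waters(model: ComplexModel, dmax: float = DEFAULT_DMAX) -> WaterSet:
    """Waters whose oxygen is within ``dmax`` of both the target and the ligand.

    Membership is non-strict (<= dmax), measured to the nearest heavy atom of
    each partner.
    """
    waters = waters_as_set(model, WaterSource.CRYSTALLOGRAPHIC)
    if len(waters) == 0:
        return waters
    tgt = cKDTree(model.target.heavy_coords())
    lig = cKDTree(model.ligand.heavy_coords())
    d_t, _ = tgt.query(waters.oxygens)
    d_l, _ = lig.query(waters.oxygens)
    keep = (d_t <= dmax) & (d_l <= dmax)
    return WaterSet(
        [rid for rid, k in zip(waters.residue_ids, keep) if k],
        waters.oxygens[keep],
        waters.source,
    )


def match_waters(
    predicted: WaterSet,
    reference: WaterSet,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> WaterMatchResult:
    """One-to-one greedy matching of predicted to reference water oxygens.

    Candidate pairs with O-O distance strictly below ``tolerance`` are matched
    greedily by ascending distance (ties broken by lower predicted, then
    reference, residue id).  With well-separated sites this equals the maximum
    bipartite matching.  An empty reference set yields an ``undefined`` result
    (SR is NaN), never 0/0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(reference) == 0:
        return WaterMatchResult([], 0, tolerance, undefined=True)
    matches: list[tuple[int, int, float]] = []
    if len(predicted) > 0:
        diff = predicted.oxygens[:, None, :] - reference.oxygens[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        cand = [
            (dist[i, j], predicted.residue_ids[i], reference.residue_ids[j], i, j)
            for i in range(len(predicted))
            for j in range(len(reference))
            if dist[i, j] < tolerance
        ]
        cand.sort(key=lambda c: (c[0], c[1], c[2]))
        used_p: set[int] = set()
        used_r: set[int] = set()
        for d, pid, rid, i, j in cand:
            if i in used_p or j in used_r:
                continue
            used_p.add(i)
            used_r.add(j)
            matches.append((pid, rid, float(d)))
    return WaterMatchResult(matches, len(reference), tolerance)


def _polar_atoms(struct: MolecularStructure) -> list:
    return [a for a in struct.atoms if a.element.upper() in _POLAR_ELEMENTS]


def find_water_bridges(
    model: ComplexModel, hbond_cutoff: float = DEFAULT_HBOND_CUTOFF
) -> list[WaterBridge]:
    """Waters bridging the target and the ligand through polar contacts.

    For every water whose oxygen lies within ``hbond_cutoff`` of at least one
    ligand N/O atom and at least one target N/O atom, one bridge is emitted
    with the closest such atom on each side.  No angle criterion is applied
    (pre-MD hydrogen positions are unreliable).
    """
    if hbond_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_polar = _polar_atoms(model.ligand)
    tgt_polar = _polar_atoms(model.target)
    if not lig_polar or not tgt_polar:
        return []
    lig_tree = cKDTree(np.stack([a.position for a in lig_polar]))
    tgt_tree = cKDTree(np.stack([a.position for a in tgt_polar]))
    bridges = []
    waters = waters_as_set(model)
    for rid, pos in zip(waters.residue_ids, waters.oxygens):
        dl, il = lig_tree.query(pos)
        dt, it = tgt_tree.query(pos)
        if dl <= hbond_cutoff and dt <= hbond_cutoff:
            la, ta = lig_polar[il], tgt_polar[it]
            bridges.append(
                WaterBridge(
                    water_residue_id=rid,
                    ligand_atom=f"{la.chain_id}/{la.residue_name}{la.residue_index}/{la.name}",
                    ligand_residue_index=la.residue_index,
                    target_atom=f"{ta.chain_id}/{ta.residue_name}{ta.residue_index}/{ta.name}",
                    d_ligand=float(dl),
                    d_target=float(dt),
                )
            )
    return bridges


def bridges_by_residue(bridges: list[WaterBridge]) -> dict[int, list[WaterBridge]]:
    """Group bridges by the ligand residue they anchor to (per-residue report)."""
    out: dict[int, list[WaterBridge]] = {}
    for b in bridges:
        out.setdefault(b.ligand_residue_index, []).append(b)
    return out
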