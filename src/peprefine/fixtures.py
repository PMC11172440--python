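"""Deterministic synthetic complexes, trajectories and hydration layouts.

Everything a refinement metric consumes can be generated here without
running MD: a rigid helical-turn target with a shallow pocket, a linear
peptide in a reference pose and a displaced docked pose of exactly known
starting RMSD, interpolated noisy trajectories with an exactly planted
number of improving frames, and interface/bulk water layouts with a planted
match fraction.  All randomness flows through ``numpy.random.default_rng``
(PCG64), so identical seed and config give bit-identical output on every
platform.  The fixtures emulate the bookkeeping of real refinement data,
not force-field physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hydration import WaterSet, WaterSource
from .metrics import TrajectorySeries
from .structmodel import AtomRecord, ComplexModel, MolecularStructure, Role

__all__ = ["FixtureConfig", "make_toy_complex", "make_trajectory", "make_hydration_layout"]

#: Histone H3 N-terminal tail; toy peptides take their sequence from it.
H3_SEQUENCE = "ARTKQTARKSTGGKA"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Side-chain atoms per residue type (name, element, offset from CA).  Kept
# minimal but with real PDB naming so selections, truncation, LJ typing and
# bridge detection all exercise realistic atoms.
_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": [("CB", "C", (0.7, 1.2, 0.6))],
    "ARG": [
        ("CB", "C", (0.7, 1.2, 0.6)),
        ("CG", "C", (1.2, 2.4, 0.8)),
        ("CD", "C", (1.6, 3.6, 1.0)),
        ("NE", "N", (2.0, 4.7, 1.2)),
        ("CZ", "C", (2.3, 5.8, 1.3)),
        ("NH1", "N", (2.1, 6.9, 0.8)),
        ("NH2", "N", (3.0, 5.9, 2.3)),
    ],
    "LYS": [
        ("CB", "C", (0.7, 1.2, 0.6)),
        ("CG", "C", (1.2, 2.4, 0.8)),
        ("CD", "C", (1.6, 3.6, 1.0)),
        ("CE", "C", (2.0, 4.7, 1.2)),
        ("NZ", "N", (2.4, 5.8, 1.4)),
    ],
    "THR": [("CB", "C", (0.7, 1.2, 0.6)), ("OG1", "O", (0.4, 2.4, 0.9)),
            ("CG2", "C", (2.1, 1.4, 0.8))],
    "GLN": [
        ("CB", "C", (0.7, 1.2, 0.6)),
        ("CG", "C", (1.2, 2.4, 0.8)),
        ("CD", "C", (1.6, 3.6, 1.0)),
        ("OE1", "O", (1.2, 4.7, 1.0)),
        ("NE2", "N", (2.9, 3.6, 1.2)),
    ],
    "SER": [("CB", "C", (0.7, 1.2, 0.6)), ("OG", "O", (0.4, 2.4, 0.9))],
    "GLY": [],
}


def _residue_atoms(resname: str) -> list[tuple[str, str, tuple[float, float, float]]]:
    backbone = [
        ("N", "N", (-1.2, -0.8, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, -0.7, 0.2)),
        ("O", "O", (1.5, -1.9, 0.1)),
    ]
    return backbone + _SIDECHAINS.get(resname, [("CB", "C", (0.7, 1.2, 0.6))])


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generator; identical config + seed is bit-stable."""

    seed: int = 7
    n_target_residues: int = 12
    peptide_length: int = 10
    n_interface_waters: int = 6
    n_bulk_waters: int = 10
    noise_sigma: float = 0.1  # A, per-atom isotropic Gaussian
    n_frames: int = 40
    frame_spacing: float = 0.1  # ns
    improving_fraction: float = 0.5
    rmsd_start: float = 6.0  # A, planted docked-pose displacement
    match_fraction: float = 0.86  # fraction of predicted waters within tolerance

    def __post_init__(self):
        if min(self.n_target_residues, self.peptide_length) < 1:
            raise ValueError("need at least one residue on each side")
        if not 0.0 <= self.improving_fraction <= 1.0:
            raise ValueError("improving_fraction must lie in [0, 1]")
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ValueError("match_fraction must lie in [0, 1]")
        if self.n_frames < 1 or self.frame_spacing <= 0:
            raise ValueError("trajectory must have frames at positive spacing")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _build_target(cfg: FixtureConfig) -> MolecularStructure:
    """Gently undulating wall of ALA residues forming a shallow groove.

    The wall runs parallel to the peptide axis at y about -6.5 A with its
    backbone carbonyls facing the pocket (offsets mirrored in y), leaving a
    solvent-width gap that the interface water sites occupy.
    """
    atoms: list[AtomRecord] = []
    serial = 1
    n = cfg.n_target_residues
    for i in range(n):
        ca = np.array(
            [3.8 * i - 1.9 * (n - 1), -6.5 + 0.4 * np.cos(2.0 * i), 0.5 * np.sin(1.3 * i)]
        )
        for name, element, off in _residue_atoms("ALA"):
            off = np.asarray(off) * np.array([1.0, -1.0, 1.0])  # face the pocket
            atoms.append(
                AtomRecord(serial, name, element, "ALA", i + 1, "A", ca + off, Role.TARGET)
            )
            serial += 1
    return MolecularStructure(atoms, "toy-target")


def _build_peptide(cfg: FixtureConfig, chain: str = "B") -> MolecularStructure:
    seq = (H3_SEQUENCE * (1 + cfg.peptide_length // len(H3_SEQUENCE)))[: cfg.peptide_length]
    atoms: list[AtomRecord] = []
    serial = 1001
    for i, letter in enumerate(seq):
        resname = _ONE_TO_THREE[letter]
        ca = np.array([3.8 * i - 1.9 * (cfg.peptide_length - 1), 0.0, 0.0])
        for name, element, off in _residue_atoms(resname):
            atoms.append(
                AtomRecord(serial, name, element, resname, i + 1, chain, ca + np.asarray(off), Role.LIGAND)
            )
            serial += 1
    return MolecularStructure(atoms, "toy-peptide")


def _interface_water_positions(cfg: FixtureConfig) -> np.ndarray:
    """Deterministic grid of sites between the pocket wall and the peptide axis.

    Sites sit within 3.5 A of both partners and at least 4 A apart, so greedy
    matching on them equals the optimal assignment.
    """
    n = cfg.n_interface_waters
    if n == 0:
        return np.empty((0, 3))
    # never let the grid outgrow the pocket: clamp to the shorter partner span
    span = min(
        2.0 * (n - 1),
        1.9 * (cfg.peptide_length - 1),
        1.9 * (cfg.n_target_residues - 1),
    )
    xs = np.linspace(-span, span, n) if n > 1 else np.array([0.0])
    return np.stack([xs, np.full(n, -3.0), np.full(n, 1.6)], axis=1)


def _bulk_water_positions(cfg: FixtureConfig) -> np.ndarray:
    n = cfg.n_bulk_waters
    if n == 0:
        return np.empty((0, 3))
    rng = cfg.rng(3)
    # shell far above the complex: > 8 A from every target/ligand atom
    pts = rng.uniform(-15.0, 15.0, size=(n, 2))
    return np.column_stack([pts[:, 0], pts[:, 1], np.full(n, 25.0)])


def _water_structure(positions: np.ndarray, first_resid: int = 500) -> MolecularStructure:
    atoms = [
        AtomRecord(9000 + i, "O", "O", "HOH", first_resid + i, "W", pos, Role.WATER)
        for i, pos in enumerate(positions)
    ]
    return MolecularStructure(atoms, "toy-waters")


def make_toy_complex(cfg: FixtureConfig) -> tuple[ComplexModel, ComplexModel]:
    """Reference and docked poses of a peptide in a shallow toy pocket.

    Returns ``(docked, reference)``.  The docked pose is the reference ligand
    translated rigidly by ``cfg.rmsd_start`` A (every heavy atom displaced
    equally), so the planted starting RMSD is exact by construction.  Both
    complexes share the same rigid target and the same interface/bulk waters.
    """
    target = _build_target(cfg)
    ref_lig = _build_peptide(cfg)
    waters = _water_structure(
        np.concatenate([_interface_water_positions(cfg), _bulk_water_positions(cfg)])
    )
    direction = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
    shift = cfg.rmsd_start * direction
    docked_lig = MolecularStructure(
        [replace(a, position=a.position + shift) for a in ref_lig.atoms], ref_lig.label
    )
    reference = ComplexModel(target, ref_lig, waters)
    docked = ComplexModel(target, docked_lig, waters)
    return docked, reference


def _scaled_frame(
    reference: ComplexModel, raw_ligand: np.ndarray, target_rmsd: float
) -> ComplexModel:
    """Rescale a ligand displacement field so the frame's RMSD is exact."""
    ref_xyz = reference.ligand.coords()
    heavy = np.array([a.is_heavy for a in reference.ligand.atoms])
    delta = raw_ligand - ref_xyz
    current = np.sqrt(np.mean(np.sum(delta[heavy] ** 2, axis=1)))
    scale = 0.0 if current == 0 else target_rmsd / current
    new_xyz = ref_xyz + delta * scale
    new_atoms = [
        replace(a, position=p) for a, p in zip(reference.ligand.atoms, new_xyz)
    ]
    return ComplexModel(
        reference.target,
        MolecularStructure(new_atoms, reference.ligand.label),
        reference.waters,
        reference.ions,
    )


def make_trajectory(
    docked: ComplexModel, reference: ComplexModel, cfg: FixtureConfig
) -> TrajectorySeries:
    """Noisy interpolation of the ligand from the docked toward the reference pose.

    Exactly ``round(improving_fraction * n_frames)`` frames (the last ones,
    refinement-style) have RMSD_start - RMSD_frame >= 1 A; every frame's RMSD
    is pinned exactly by post-hoc scaling of its displacement field, because
    raw Gaussian noise would make the counts stochastic.  The target stays
    rigid, as under the strong position restraints of the refinement stages.
    """
    rng = cfg.rng(1)
    ref_xyz = reference.ligand.coords()
    docked_xyz = docked.ligand.coords()
    heavy = np.array([a.is_heavy for a in reference.ligand.atoms])
    d = docked_xyz - ref_xyz
    rmsd_start = float(np.sqrt(np.mean(np.sum(d[heavy] ** 2, axis=1))))
    n_improving = round(cfg.improving_fraction * cfg.n_frames)
    if n_improving > 0 and rmsd_start < 1.0:
        raise ValueError("cannot plant improving frames: RMSD_start below the 1 A cutoff")
    improved_rmsd = max(0.0, min(0.5, rmsd_start - 1.0))
    unimproved_rmsd = max(rmsd_start - 0.5, 0.0)
    frames = []
    for f in range(cfg.n_frames):
        improving = f >= cfg.n_frames - n_improving
        lam = 1.0 if improving else f / max(cfg.n_frames - 1, 1) * 0.1
        raw = ref_xyz + (1.0 - lam) * d + rng.normal(0.0, cfg.noise_sigma, ref_xyz.shape)
        target_rmsd = improved_rmsd if improving else unimproved_rmsd
        frames.append(_scaled_frame(reference, raw, target_rmsd))
    return TrajectorySeries(frames, cfg.frame_spacing)


def make_hydration_layout(cfg: FixtureConfig) -> tuple[WaterSet, WaterSet]:
    """Reference interface waters and predicted copies with a planted match rate.

    Reference sites sit on a 4 A grid, so candidate sets are disjoint and
    greedy matching equals the optimal assignment.  A ``match_fraction`` share
    of the predictions is displaced by 0.2-1.2 A (inside the 1.5 A tolerance);
    the rest by 1.8-2.0 A, which misses every site.  Returns
    ``(predicted, reference)``.
    """
    n = cfg.n_interface_waters
    xs = 4.0 * np.arange(n) - 2.0 * (n - 1)
    sites = np.stack([xs, np.full(n, -3.0), np.full(n, 1.6)], axis=1)
    reference = WaterSet(list(range(1, n + 1)), sites, WaterSource.CRYSTALLOGRAPHIC)
    rng = cfg.rng(2)
    n_match = round(cfg.match_fraction * n)
    offsets = np.empty((n, 3))
    for i in range(n):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        mag = rng.uniform(0.2, 1.2) if i < n_match else rng.uniform(1.8, 2.0)
        offsets[i] = mag * u
    predicted = WaterSet(list(range(101, 101 + n)), sites + offsets, WaterSource.PREDICTED)
    return predicted, reference
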