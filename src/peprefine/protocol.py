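"""Refinement protocol definitions P1-P6 and GROMACS-style parameter documents.

Each protocol is three consecutive stages: an initial equilibrium MD with a
restrained target, a simulated-annealing (SA) MD whose temperature climbs
through plateaus to a maximum and back down the same ladder, and (P1/P2
only) a final fully flexible MD.  The six protocols differ in stage
lengths, maximal SA temperature, target restraint scheme and whether the
peptide's C-terminal tail is truncated:

    P1:  5 ns + 20 ns SA (max 323 K) + 20 ns flexible, all-heavy restraints
    P2:  as P1 but SA climbs to 353 K in 14 K steps
    P3: 15 ns + 40 ns SA (323 K), all-heavy restraints
    P4: 10 ns + 30 ns SA (323 K), binding-site residues released
    P5: 15 ns + 40 ns SA (323 K), truncated peptide
    P6: 10 ns + 30 ns SA (323 K), released binding site + truncated peptide

The 323 K ladder holds 300/310/323/310/300 K for 2.5 ns per plateau with the
remaining stage time spent at the maximum; the 353 K ladder of P2 uses
1.2 ns plateaus (300, 311, then 14 K steps to 353 and back), 10 ns at the
maximum, with the final 300 K plateau extended to fill the nominal stage
length.  This module emits the machine-readable stage documents (.mdp
dialect) and restraint selections; it never runs MD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import (
    AtomRecord,
    AtomSelection,
    ComplexModel,
    MolecularStructure,
    Role,
)

__all__ = [
    "SAStep",
    "RestraintScheme",
    "Stage",
    "ProtocolSpec",
    "ProtocolError",
    "MDPDocument",
    "builtin_protocols",
    "get_protocol",
    "sa_schedule",
    "emit_mdp",
    "parse_mdp",
    "binding_site_selection",
    "BindingSiteRestraints",
    "truncate_peptide",
    "MOBYWAT_PROVENANCE",
]

#: Upstream water-prediction parameters, recorded for provenance only; the
#: hydrated-target PDB is an input to this package, never computed by it.
MOBYWAT_PROVENANCE = {
    "algorithm": "IDa",
    "dmax_A": 5.0,
    "ctol_A": 1.5,
    "ptol_A": 2.5,
}

BASE_TEMPERATURE = 300.0  # K
DT_PS = 0.002  # 2 fs
OUTPUT_INTERVAL_PS = 10.0
POSRE_FORCE_CONSTANT = 1000.0  # kJ/mol/nm^2


class ProtocolError(ValueError):
    """Requested stage or parameter is invalid for the protocol."""


@dataclass(frozen=True)
class SAStep:
    """One temperature plateau of a simulated-annealing schedule."""

    temperature: float  # K
    duration: float  # ns

    def __post_init__(self):
        if self.temperature <= 0 or self.duration <= 0:
            raise ValueError("temperature and duration must be positive")


class RestraintScheme(str, enum.Enum):
    ALL_HEAVY_TARGET = "all_heavy_target"
    CALPHA_TARGET = "calpha_target"
    RELEASE_BINDING_SITE = "release_binding_site"


class Stage(str, enum.Enum):
    EM_SD = "em_sd"
    EM_CG = "em_cg"
    INIT_MD = "init_md"
    SA_MD = "sa_md"
    FLEX_MD = "flex_md"


@dataclass(frozen=True)
class ProtocolSpec:
    """Machine-readable definition of one refinement protocol."""

    id: str
    initial_md_ns: float
    sa_max_temp: float
    sa_steps: tuple[SAStep, ...]
    final_flex_md_ns: float = 0.0
    restraint_scheme: RestraintScheme = RestraintScheme.ALL_HEAVY_TARGET
    truncate_peptide: bool = False
    truncate_keep_n: int = 5
    binding_site_radius: float = 5.0

    def __post_init__(self):
        temps = [s.temperature for s in self.sa_steps]
        if temps != temps[::-1]:
            raise ValueError(f"{self.id}: SA plateau temperatures must be palindromic")
        if temps and max(temps) != self.sa_max_temp:
            raise ValueError(f"{self.id}: ladder maximum differs from sa_max_temp")

    @property
    def sa_total_ns(self) -> float:
        return sum(s.duration for s in self.sa_steps)

    @property
    def total_ns(self) -> float:
        return self.initial_md_ns + self.sa_total_ns + self.final_flex_md_ns

    @property
    def has_flex_stage(self) -> bool:
        return self.final_flex_md_ns > 0


def _ladder_323(hold_ns: float) -> tuple[SAStep, ...]:
    temps = (300.0, 310.0, 323.0, 310.0, 300.0)
    return tuple(
        SAStep(t, hold_ns if t == 323.0 else 2.5) for t in temps
    )


def _ladder_353(hold_ns: float, nominal_ns: float) -> tuple[SAStep, ...]:
    up = (300.0, 311.0, 325.0, 339.0)
    temps = up + (353.0,) + up[::-1]
    steps = [SAStep(t, hold_ns if t == 353.0 else 1.2) for t in temps]
    # the 1.2 ns ladder arithmetic leaves the nominal stage length short;
    # the deficit is absorbed by the final 300 K plateau
    deficit = nominal_ns - sum(s.duration for s in steps)
    if deficit > 1e-9:
        steps[-1] = SAStep(300.0, steps[-1].duration + deficit)
    return tuple(steps)


def builtin_protocols() -> list[ProtocolSpec]:
    """The six refinement protocols.

    Maximum-temperature holds are 10/10/30/20/30/20 ns for P1..P6, giving SA
    stage totals of 20/20/40/30/40/30 ns.
    """
    return [
        ProtocolSpec("P1", 5.0, 323.0, _ladder_323(10.0), final_flex_md_ns=20.0),
        ProtocolSpec("P2", 5.0, 353.0, _ladder_353(10.0, 20.0), final_flex_md_ns=20.0),
        ProtocolSpec("P3", 15.0, 323.0, _ladder_323(30.0)),
        ProtocolSpec(
            "P4", 10.0, 323.0, _ladder_323(20.0),
            restraint_scheme=RestraintScheme.RELEASE_BINDING_SITE,
        ),
        ProtocolSpec("P5", 15.0, 323.0, _ladder_323(30.0), truncate_peptide=True),
        ProtocolSpec(
            "P6", 10.0, 323.0, _ladder_323(20.0),
            restraint_scheme=RestraintScheme.RELEASE_BINDING_SITE,
            truncate_peptide=True,
        ),
    ]


def get_protocol(pid: str) -> ProtocolSpec:
    for spec in builtin_protocols():
        if spec.id == pid.upper():
            return spec
    raise ProtocolError(f"unknown protocol {pid!r} (expected P1..P6)")


def sa_schedule(spec: ProtocolSpec) -> list[tuple[float, float]]:
    """Piecewise-constant annealing points (time ns, temperature K).

    Each plateau contributes its start and end point, so the schedule renders
    as a step function with instantaneous set-point changes at plateau
    boundaries.
    """
    points: list[tuple[float, float]] = []
    t = 0.0
    for step in spec.sa_steps:
        points.append((t, step.temperature))
        t += step.duration
        points.append((t, step.temperature))
    return points


@dataclass
class MDPDocument:
    """Ordered key-value parameter document for one simulation stage."""

    stage: Stage
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def set(self, key: str, value) -> None:
        self.pairs.append((key, str(value)))

    def get(self, key: str) -> str | None:
        for k, v in self.pairs:
            if k == key:
                return v
        return None

    def render(self) -> str:
        width = max((len(k) for k, _ in self.pairs), default=0)
        return "\n".join(f"{k:<{width}} = {v}" for k, v in self.pairs) + "\n"


def parse_mdp(text: str) -> list[tuple[str, str]]:
    """Parse an .mdp-style document back into ordered key-value pairs."""
    pairs = []
    for line in text.splitlines():
        line = line.split(";", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        pairs.append((key.strip(), value.strip()))
    return pairs


def _md_common(doc: MDPDocument, length_ns: float, restrained: bool) -> None:
    doc.set("integrator", "md")
    doc.set("dt", f"{DT_PS:g}")
    doc.set("nsteps", int(round(length_ns * 1000.0 / DT_PS)))
    doc.set("nstxout", int(round(OUTPUT_INTERVAL_PS / DT_PS)))  # every 10 ps
    doc.set("constraints", "h-bonds")
    doc.set("constraint-algorithm", "lincs")
    doc.set("tcoupl", "v-rescale")
    doc.set("tc-grps", "Protein Non-Protein")
    doc.set("tau-t", "0.1 0.1")
    doc.set("ref-t", f"{BASE_TEMPERATURE:g} {BASE_TEMPERATURE:g}")
    doc.set("pcoupl", "Parrinello-Rahman")
    doc.set("tau-p", "0.5")
    doc.set("ref-p", "1.0")
    doc.set("compressibility", "4.5e-5")
    doc.set("coulombtype", "PME")
    doc.set("fourierspacing", "0.12")
    doc.set("pme-grid-spacing", "0.1")
    doc.set("rcoulomb", "1.1")
    doc.set("rvdw", "1.1")
    if restrained:
        doc.set("define", "-DPOSRES")
        doc.set("posre-fc", f"{POSRE_FORCE_CONSTANT:g}")


def emit_mdp(spec: ProtocolSpec, stage: Stage) -> MDPDocument:
    """Parameter document for one stage of a protocol.

    Energy-minimization stages carry the steepest-descent (1000 kJ/mol/nm)
    and conjugate-gradient (10 kJ/mol/nm) convergence thresholds; MD stages
    carry the fixed simulation parameters (2 fs step, v-rescale at 300 K,
    Parrinello-Rahman at 1 bar, PME, 11 A vdW cutoff, LINCS, 10 ps output)
    plus the stage length and, for the SA stage, the annealing point lists.
    A flexible final stage exists only for P1/P2.
    """
    stage = Stage(stage)
    doc = MDPDocument(stage)
    doc.set("title", f"{spec.id} {stage.value}")
    if stage is Stage.EM_SD:
        doc.set("integrator", "steep")
        doc.set("emtol", "1000")  # kJ/mol/nm
        doc.set("define", "-DPOSRES")
        doc.set("posre-fc", f"{POSRE_FORCE_CONSTANT:g}")
        return doc
    if stage is Stage.EM_CG:
        doc.set("integrator", "cg")
        doc.set("emtol", "10")  # kJ/mol/nm
        doc.set("define", "-DPOSRES")
        doc.set("posre-fc", f"{POSRE_FORCE_CONSTANT:g}")
        return doc
    if stage is Stage.INIT_MD:
        _md_common(doc, spec.initial_md_ns, restrained=True)
        return doc
    if stage is Stage.SA_MD:
        _md_common(doc, spec.sa_total_ns, restrained=True)
        points = sa_schedule(spec)
        doc.set("annealing", "single single")
        doc.set("annealing-npoints", f"{len(points)} {len(points)}")
        times = " ".join(f"{1000.0 * t:g}" for t, _ in points)  # ps
        temps = " ".join(f"{T:g}" for _, T in points)
        doc.set("annealing-time", f"{times} {times}")
        doc.set("annealing-temp", f"{temps} {temps}")
        return doc
    if stage is Stage.FLEX_MD:
        if not spec.has_flex_stage:
            raise ProtocolError(
                f"{spec.id} has no final full-flexibility stage (P3-P6 skip it)"
            )
        _md_common(doc, spec.final_flex_md_ns, restrained=False)
        return doc
    raise ProtocolError(stage)


@dataclass
class BindingSiteRestraints:
    """Restraint partition of the target around a docked ligand."""

    released_residues: list[tuple[str, int, str]]
    restrained_selection: AtomSelection  # heavy-atom indices into the target


def binding_site_selection(
    model: ComplexModel, radius: float = 5.0
) -> BindingSiteRestraints:
    """Release target residues contacting the docked ligand; restrain the rest.

    A target residue is released when any of its heavy atoms lies within
    ``radius`` (A) of any ligand heavy atom.  All heavy atoms of the
    remaining residues stay position-restrained, and Zn ions are always
    restrained (they count as heavy atoms of the target).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig = model.ligand.heavy_coords()
    released: list[tuple[str, int, str]] = []
    released_keys = set()
    if len(lig) > 0:
        tree = cKDTree(lig)
        for key, atoms in model.target.residues():
            heavy = [a.position for a in atoms if a.is_heavy]
            if heavy and np.any(tree.query(np.stack(heavy))[0] <= radius):
                released.append(key)
                released_keys.add(key)
    indices = tuple(
        i
        for i, a in enumerate(model.target.atoms)
        if a.is_heavy and a.residue_key not in released_keys
    )
    sel = AtomSelection.all_heavy()
    sel.indices = indices
    return BindingSiteRestraints(released, sel)


def truncate_peptide(ligand: MolecularStructure, keep_n: int) -> MolecularStructure:
    """Remove the C-terminal tail of the peptide, keeping residues 1..keep_n.

    The new last residue is converted to a standard C-terminus: an OXT atom
    is added opposite the carbonyl O in the carboxylate plane (reflection of
    O through the CA-C axis) unless one is already present.
    """
    residues = ligand.residues()
    if not 1 <= keep_n <= len(residues):
        raise ValueError(f"keep_n={keep_n} out of range for {len(residues)} residues")
    if keep_n == len(residues):
        return ligand
    kept: list[AtomRecord] = []
    for _, atoms in residues[:keep_n]:
        kept.extend(atoms)
    last_atoms = {a.name: a for a in residues[keep_n - 1][1]}
    if "OXT" not in last_atoms and {"CA", "C", "O"} <= set(last_atoms):
        ca, c, o = (last_atoms[n].position for n in ("CA", "C", "O"))
        axis = c - ca
        axis = axis / np.linalg.norm(axis)
        v = o - c
        oxt_pos = c + 2.0 * np.dot(v, axis) * axis - v  # reflect O through the CA-C axis
        template = last_atoms["O"]
        kept.append(
            replace(
                template,
                serial=max(a.serial for a in ligand.atoms) + 1,
                name="OXT",
                position=oxt_pos,
            )
        )
    return MolecularStructure(kept, ligand.label)
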