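"""Refinement quality metrics.

The central quantity is the all-heavy-atom RMSD between a calculated
(docked or MD-refined) peptide binding mode C and the experimental
reference R,

    RMSD = sqrt( sum_i |C_i - R_i|^2 / N_H ),

evaluated after fitting the calculated frame onto the reference on target
Calpha atoms (the ligand atoms themselves are never re-fit, so rigid-body
placement errors of the peptide count in full).  Improvement of a docked
start upon refinement is

    dRMSD   = RMSD_start - RMSD_best
    dRMSD%  = 100 * dRMSD / RMSD_start,

and kinetic stability of the refined binding mode is the residence
frequency

    RF = (# frames with RMSD_start - RMSD_frame >= cutoff) / simulation time,

in 1/ns, with a 1 A cutoff by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structmodel import (
    AtomSelection,
    ComplexModel,
    Role,
    correspond,
    resolve_selection,
    superpose_kabsch,
)

__all__ = [
    "TrajectorySeries",
    "RefinementReport",
    "rmsd",
    "ligand_rmsd",
    "delta_rmsd",
    "trajectory_report",
    "n_terminal_report",
    "ensemble_rmsd",
    "DEFAULT_RF_CUTOFF",
    "HIGH_STABILITY_RF",
]

#: RF cutoff in Angstrom: a frame counts when it improves on the start by >= 1 A.
DEFAULT_RF_CUTOFF = 1.0
#: RF above which a complex is considered kinetically highly stable (1/ns).
HIGH_STABILITY_RF = 0.5


@dataclass
class TrajectorySeries:
    """Time-ordered snapshots of a complex at uniform frame spacing (ns)."""

    frames: list[ComplexModel]
    frame_spacing: float = 0.1
    stage_boundaries: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_spacing <= 0:
            raise ValueError("frame spacing must be positive")
        times = [t for t, _ in self.stage_boundaries]
        if times != sorted(times):
            raise ValueError("stage boundary times must be monotone")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def total_time(self) -> float:
        """Total simulation time in ns (frames are spaced by frame_spacing)."""
        return len(self.frames) * self.frame_spacing

    def times(self) -> np.ndarray:
        """Time stamp of each frame: frame i is the snapshot at (i+1)*spacing ns."""
        return (np.arange(len(self.frames)) + 1) * self.frame_spacing


@dataclass
class RefinementReport:
    """RMSD bookkeeping for one refinement run."""

    rmsd_start: float
    rmsd_best: float
    best_frame_time: float
    delta_rmsd: float
    delta_rmsd_percent: float
    rf: float
    per_frame_rmsd: list[float]

    def to_dict(self) -> dict:
        return {
            "rmsd_start": self.rmsd_start,
            "rmsd_best": self.rmsd_best,
            "best_frame_time": self.best_frame_time,
            "delta_rmsd": self.delta_rmsd,
            "delta_rmsd_percent": self.delta_rmsd_percent,
            "rf": self.rf,
            "per_frame_rmsd": list(self.per_frame_rmsd),
        }


def _paired_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    d = coords_a - coords_b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd(
    calc: ComplexModel,
    ref: ComplexModel,
    sel: AtomSelection | None = None,
    fit_sel: AtomSelection | None = None,
) -> float:
    """Ligand RMSD of ``calc`` vs ``ref`` after target-Calpha fitting.

    ``sel`` selects the ligand atoms entering the sum (all heavy atoms by
    default); ``fit_sel`` selects the target atoms used for the rigid fit
    (Calpha by default).  Pass ``fit_sel=None`` explicitly via
    :func:`ligand_rmsd` when the structures are already in a common frame.
    """
    sel = sel or AtomSelection.all_heavy()
    fit_sel = fit_sel or AtomSelection.calpha()
    transform = superpose_kabsch(calc, ref, fit_sel, on=Role.TARGET)
    fitted_ligand = calc.ligand.transformed(transform)
    rsel = resolve_selection(calc, sel, Role.LIGAND)
    ia, ib = correspond(fitted_ligand, ref.ligand, rsel)
    return _paired_rmsd(fitted_ligand.coords(ia), ref.ligand.coords(ib))


def ligand_rmsd(calc: ComplexModel, ref: ComplexModel, sel: AtomSelection | None = None) -> float:
    """Ligand RMSD without any fitting (structures already in a common frame)."""
    sel = sel or AtomSelection.all_heavy()
    rsel = resolve_selection(calc, sel, Role.LIGAND)
    ia, ib = correspond(calc.ligand, ref.ligand, rsel)
    return _paired_rmsd(calc.ligand.coords(ia), ref.ligand.coords(ib))


def delta_rmsd(rmsd_start: float, rmsd_best: float) -> tuple[float, float]:
    """Improvement of a docked start upon refinement, absolute (A) and percent.

    Negative values mean the refinement worsened the pose.
    """
    if rmsd_start <= 0:
        raise ValueError(f"rmsd_start must be positive, got {rmsd_start}")
    d = rmsd_start - rmsd_best
    return d, 100.0 * d / rmsd_start


def trajectory_report(
    traj: TrajectorySeries,
    ref: ComplexModel,
    start: ComplexModel,
    sel: AtomSelection | None = None,
    rf_cutoff: float = DEFAULT_RF_CUTOFF,
    fit_sel: AtomSelection | None = None,
    time_window: tuple[float, float] | None = None,
) -> RefinementReport:
    """Score a refinement trajectory against the experimental reference.

    Every frame and the docked ``start`` (treated as the t=0 structure, not
    counted in RF) are fit to ``ref`` on target Calpha before the ligand RMSD.
    The RF denominator is the trajectory's full simulation time in ns.
    ``time_window`` restricts the frames considered (e.g. a single protocol
    stage); RF then uses the window duration as denominator.
    """
    sel = sel or AtomSelection.all_heavy()
    rmsd_start = rmsd(start, ref, sel, fit_sel)
    times = traj.times()
    if time_window is not None:
        lo, hi = time_window
        mask = (times >= lo) & (times <= hi)
        if not mask.any():
            raise ValueError(f"no frames in window {time_window}")
        frames = [f for f, m in zip(traj.frames, mask) if m]
        times = times[mask]
        total_time = hi - lo
    else:
        frames = traj.frames
        total_time = traj.total_time
    per_frame = [rmsd(frame, ref, sel, fit_sel) for frame in frames]
    best_idx = int(np.argmin(per_frame))
    rmsd_best = per_frame[best_idx]
    n_improving = int(np.sum(rmsd_start - np.asarray(per_frame) >= rf_cutoff))
    d, dpct = delta_rmsd(rmsd_start, rmsd_best)
    return RefinementReport(
        rmsd_start=rmsd_start,
        rmsd_best=rmsd_best,
        best_frame_time=float(times[best_idx]),
        delta_rmsd=d,
        delta_rmsd_percent=dpct,
        rf=n_improving / total_time,
        per_frame_rmsd=per_frame,
    )


def n_terminal_report(
    traj: TrajectorySeries,
    ref: ComplexModel,
    start: ComplexModel,
    k: int = 5,
    rf_cutoff: float = DEFAULT_RF_CUTOFF,
) -> RefinementReport:
    """Trajectory report restricted to the N-terminal ``k`` ligand residues.

    For histone tails the N-terminal head (about five residues) is the tightly
    bound part; excluding the mobile C-terminus scores what the pocket holds.
    """
    n_res = len(start.ligand.residues())
    if k < 1 or k > n_res:
        raise ValueError(f"k={k} out of range for a {n_res}-residue ligand")
    return trajectory_report(traj, ref, start, AtomSelection.n_terminal(k), rf_cutoff)


def ensemble_rmsd(
    models: list[ComplexModel],
    reference_index: int = 0,
    sel: AtomSelection | None = None,
    fit_sel: AtomSelection | None = None,
) -> list[float]:
    """Ligand RMSD of each ensemble member vs one representative member.

    For an NMR ensemble this quantifies the conformational uncertainty of the
    bound peptide: each model's target is first fit to the representative's
    target on Calpha, then the ligand RMSD is taken.  The representative
    itself is excluded from the returned list.
    """
    ref = models[reference_index]
    return [
        rmsd(m, ref, sel, fit_sel) for i, m in enumerate(models) if i != reference_index
    ]
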