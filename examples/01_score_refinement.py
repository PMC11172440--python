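"""Score a synthetic refinement trajectory against its experimental reference.

Builds a toy peptide-in-pocket complex with a docked pose planted exactly
6 A from the reference, generates a 40-frame (4 ns) trajectory in which half
the frames have converged near the reference, and reports the refinement
metrics: RMSD_start, RMSD_best, dRMSD (absolute and percent), and the
residence frequency RF (improving frames per ns; RF > 0.5 per ns marks a
kinetically stable binding mode).
"""

from peprefine import FixtureConfig, make_toy_complex, make_trajectory, trajectory_report

cfg = FixtureConfig(seed=7, n_frames=40, improving_fraction=0.5, rmsd_start=6.0)
docked, reference = make_toy_complex(cfg)
trajectory = make_trajectory(docked, reference, cfg)

report = trajectory_report(trajectory, reference, docked)
print(f"RMSD_start      : {report.rmsd_start:6.2f} A   (docked pose vs reference)")
print(f"RMSD_best       : {report.rmsd_best:6.2f} A   at t = {report.best_frame_time:.1f} ns")
print(f"dRMSD           : {report.delta_rmsd:6.2f} A   ({report.delta_rmsd_percent:.1f} %)")
print(f"RF              : {report.rf:6.2f} /ns (planted: 20 improving frames / 4 ns = 5.00)")
print(f"kinetically stable (RF > 0.5/ns): {report.rf > 0.5}")
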