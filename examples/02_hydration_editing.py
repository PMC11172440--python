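"""Pre-MD hydration editing and interface-water validation.

Strips waters clashing with the docked ligand (oxygen closer than
dmin = 1.75 A to any ligand heavy atom), identifies interface waters
(within 3.5 A of both partners), scores a predicted water layout against
the reference sites as a success rate (one-to-one oxygen matches below the
1.5 A tolerance), and enumerates bridging waters that link ligand and
target polar atoms at hydrogen-bond distance.
"""

from peprefine import (
    FixtureConfig,
    find_water_bridges,
    interface_waters,
    make_hydration_layout,
    make_toy_complex,
    match_waters,
    strip_clashing_waters,
)
from peprefine.hydration import bridges_by_residue

cfg = FixtureConfig(seed=7, n_interface_waters=10, n_bulk_waters=20, match_fraction=0.8)
docked, reference = make_toy_complex(cfg)

wet = strip_clashing_waters(reference, docked.ligand, dmin=1.75)
n_before = len(reference.waters.residues())
n_after = len(wet.waters.residues())
print(f"waters before/after clash stripping : {n_before} / {n_after}")

iface = interface_waters(reference, dmax=3.5)
print(f"interface waters (<= 3.5 A of both) : {len(iface)} (planted: {cfg.n_interface_waters})")

predicted, ref_sites = make_hydration_layout(cfg)
result = match_waters(predicted, ref_sites, tolerance=1.5)
print(f"water placement success rate        : {result.success_rate:.0f} % "
      f"({len(result.matches)}/{result.n_reference} matched)")

per_residue = bridges_by_residue(find_water_bridges(reference, hbond_cutoff=3.5))
total = sum(len(v) for v in per_residue.values())
print(f"bridging waters                     : {total}, grouped over "
      f"{len(per_residue)} ligand residues")
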