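"""Per-residue target-ligand interaction energy of a docked peptide.

Assigns Gasteiger PEOE partial charges, then evaluates the pairwise
interaction energy E_inter = E_LJ + E_Coulomb over all target-ligand atom
pairs (Amber-style 12-6 Lennard-Jones; Coulomb screened by the sigmoidal
Mehler-Solmajer distance-dependent dielectric), decomposed per ligand
residue.  Strongly negative residues are binding anchors: for histone H3
tails these are typically A1, R2 and K4 at the N-terminus.
"""

from peprefine import FixtureConfig, make_toy_complex, per_residue_einter
from peprefine.energy import anchoring_report, assign_complex_charges

cfg = FixtureConfig(seed=7, peptide_length=10)
_, reference = make_toy_complex(cfg)  # the seated (reference) pose

charges = assign_complex_charges(reference)
print(f"total formal charge: {charges.total_formal_charge:+.0f} e "
      f"(conserved to {abs(charges.charges.sum() - charges.total_formal_charge):.1e} e)")

profile = per_residue_einter(reference, charges)
print(f"{'residue':>10s} {'E_LJ':>10s} {'E_Coulomb':>10s} {'E_inter':>10s}  (kcal/mol)")
for rec in profile.to_records():
    tag = f"{rec['residue_name']}{rec['residue_index']}"
    print(f"{tag:>10s} {rec['E_LJ']:10.3f} {rec['E_Coulomb']:10.3f} {rec['E_inter']:10.3f}")
print(f"{'total':>10s} {profile.total_lj:10.3f} {profile.total_coulomb:10.3f} "
      f"{profile.total:10.3f}")

report = anchoring_report(profile)
best = report["ranked"][0]
print(f"most favorable residue: {best['residue'][2]}{best['residue'][1]} "
      f"({best['E_inter']:.3f} kcal/mol)")
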