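# Methods

This note records the models implemented by `peprefine`, their assumptions,
the defaults that matter, and the design choices made where the published
description of the workflow leaves the design open.

## Structure model and superposition

A complex is partitioned by role into target, ligand, waters and ions.
Structural Zn²⁺ ions travel with the complex and are treated as heavy atoms
of the target wherever restraints are concerned, but are excluded (with the
waters) from the interaction-energy sums. PDB I/O is delegated to gemmi;
waters are recognised by residue name (HOH/SOL/WAT) and ions by residue name
regardless of chain, while protein chains need an explicit chain→role map.
Alternate locations keep the highest-occupancy conformer, first on tie.
Hydrogens are parsed and stored but excluded from every metric by the
all-heavy selection.

Rigid superposition is the least-squares Kabsch fit (via
`scipy.spatial.transform.Rotation.align_vectors`), restricted to proper
rotations — a reflection is never a physical rigid-body motion of a protein.
Atom correspondence is by (chain, residue index, atom name): snapshots and
references derive from the same topology, so name-based pairing is exact and
any mismatch is reported atom by atom rather than silently dropped.
Degenerate input (fewer than three pairs, or a collinear selection) is an
error, not a warning.

## RMSD, ΔRMSD and residence frequency

The ligand RMSD between a calculated and a reference binding mode is
computed over paired heavy atoms *after* fitting the calculated frame onto
the reference on target Cα atoms; the ligand atoms themselves are never
re-fit, so rigid placement error counts in full. ΔRMSD = RMSD_start −
RMSD_best may be negative when refinement worsens a pose; the percent form
is relative to RMSD_start and is reported to one decimal.

For trajectory reports, RMSD_best is the single best frame over the whole
analysed trajectory; stage-restricted minima are available through a time
window, because whether a published best frame comes from all stages or
only post-SA stages is ambiguous and both views are useful. The residence
frequency uses the full planned simulation time in ns as denominator (not
the frame count), so with the 0.1 ns default frame spacing RF saturates at
10 ns⁻¹. The docked start is the t = 0 structure but is not counted in RF:
RF measures refinement frames. The improvement cutoff defaults to 1 Å, and
RF · (total time) is always an integer count, which the tests exploit.

The N-terminal-k report (default k = 5) restricts the RMSD to the first k
ligand residues. For histone H3 tails the N-terminal head is the tightly
bound, well-defined part, and scoring it separately distinguishes a correct
anchor with a mobile tail from a globally wrong pose.

## Hydration editing and water scoring

All water geometry is measured from the oxygen alone: hydrogen positions of
predicted or pre-equilibration waters are not reliable, so no angle
criterion is applied anywhere. The editing and scoring thresholds are:
strip waters whose oxygen lies strictly within d_min = 1.75 Å of a ligand
heavy atom (a water at exactly d_min survives); interface membership is
non-strict at d_max = 3.5 Å to both partners; a predicted/reference oxygen
pair matches when strictly below the 1.5 Å tolerance.

Matching is one-to-one and greedy by ascending distance, ties broken by
lower residue id. Greedy was chosen over optimal assignment because it
mirrors common water-validation practice, is deterministic, and is provably
identical to the maximum matching whenever candidate sets are disjoint —
which holds for well-separated hydration sites; the test suite asserts
equality against an exhaustive assignment oracle on planted layouts. An
empty reference set yields an explicitly flagged undefined success rate
(NaN), never 0/0. Waters with partial occupancy are all included.

A bridging water is one whose oxygen is within 3.5 Å of at least one ligand
N/O atom and one target N/O atom; one bridge is emitted per water, carrying
the closest polar atom on each side, and bridges group per ligand residue
for anchor-centred reports. The parameters of the upstream water-placement
step (surface prediction at d_max = 5 Å, clustering tolerance 1.5 Å,
prediction tolerance 2.5 Å, identity-based algorithm) are recorded as
provenance constants only: hydrated-target structures are an *input* to
this package.

## Interaction energy

E_inter = E_LJ + E_Coulomb is a full double sum over target × ligand atoms
with no distance cutoff (none is part of the model; the sums are small
enough that O(N_T · N_L) evaluation is unproblematic). Waters and ions are
excluded. Units are kcal/mol with charges in e and distances in Å; the
electrostatic constant 332.06 kcal·mol⁻¹·Å·e⁻² folds 1/(4πε₀) into the
Coulomb term. The per-residue decomposition is an exact partition of the
total (asserted to 1e-9), and the total is symmetric under exchanging the
roles of target and ligand.

The distance-dependent dielectric is the sigmoidal
ε_r(r) = A + B/(1 + k·e^(−λBr)) with B = ε_water − A. The functional form's
two constants named ε₀ in the literature (vacuum permittivity vs. water
dielectric) are kept as two distinct named quantities here. The defaults
are the Mehler–Solmajer constants A = −8.5525, λ = 0.003627, k = 7.7839,
ε_water = 78.4 (the standard parameter set for this form), exposed on
`DielectricModel` for substitution. ε_r is strictly increasing and
approaches ε_water at large r; both properties are tested, along with
agreement with a symbolic evaluation to 1e-12.

Lennard-Jones parameters are Amber-style (R_i is Rmin/2, so R_ij = R_i + R_j
is the pair minimum and the potential there equals −ε_ij exactly — a tested
calculus identity). Atom typing is a residue/atom-name lookup covering the
standard amino-acid classes (carbonyl vs. aromatic vs. aliphatic carbon,
hydroxyl vs. carbonyl vs. carboxylate oxygen, hydrogen classes by bonded
heavy atom); unknown atoms fall back to element defaults with a logged
warning. The Amber nitrogen classes share identical LJ values, so a single
N class is used.

Partial charges are Gasteiger–Marsili PEOE, authored here: electronegativity
χ(q) = a + bq + cq² with the published element/hybridisation coefficients;
at iteration n each bond transfers ((χ_hi − χ_lo)/χ⁺_lo)·(1/2)ⁿ from the
less to the more electronegative atom, with χ⁺ the cation electronegativity
of the less electronegative partner (20.02 for H). All transfers of an
iteration are computed from one charge state, so total formal charge is
conserved exactly; six iterations are the default (the damping makes later
iterations negligible). Connectivity is perceived from distances (covalent
radii + 0.45 Å, restricted to intra-residue, peptide C–N and disulfide
pairs), hybridisation from an amino-acid name table, and formal-charge
seeds default to physiological protonation (Lys/Arg +1, Asp/Glu −1). The
test suite cross-checks the PEOE iteration against rdkit's independent
implementation on an alanine-dipeptide graph (same graph and
hybridisations, so the check isolates the iteration itself) to 0.01 e.
Following AutoDock-style preparation, the default "polar" hydrogen mode
folds carbon-bound hydrogen charges into their carbons; an all-atom mode is
available, since which of the two a published per-residue profile used is
generally not stated.

## Refinement protocols

The six protocols are fixed three-stage designs (initial restrained MD →
simulated-annealing MD → optional fully flexible MD): P1/P2 use 5 + 20 (+20)
ns, P3/P5 use 15 + 40 ns, P4/P6 use 10 + 30 ns. The 323 K ladder holds
300/310/323/310/300 K for 2.5 ns per plateau, with the remainder of the
stage (10/30/20/30/20 ns for P1/P3/P4/P5/P6) at the maximum. P2 climbs
300 → 311 → 325 → 339 → 353 K (14 K steps) at 1.2 ns per plateau with 10 ns
at the maximum; that arithmetic totals 19.6 ns against the nominal 20 ns
stage, and the deficit is absorbed by extending the final 300 K plateau to
1.6 ns. Plateau temperature sequences are palindromic with the maximum held
exactly once, and schedules render as step functions with instantaneous
set-point changes at plateau boundaries (only plateau durations are part of
the protocol definition).

Emitted stage documents carry the fixed simulation parameters (2 fs step,
v-rescale thermostat at 300 K with τ = 0.1 ps, Parrinello–Rahman at 1 bar
with τ = 0.5 ps and compressibility 4.5×10⁻⁵ bar⁻¹, PME with 0.12 nm
Fourier spacing, 11 Å vdW cutoff, LINCS constraints, position-restraint
force constant 1000 kJ·mol⁻¹·nm⁻², output every 10 ps), the steepest-descent
(1000 kJ·mol⁻¹·nm⁻¹) and conjugate-gradient (10 kJ·mol⁻¹·nm⁻¹) minimisation
thresholds, and for the SA stage the annealing point lists. Documents are
deterministic byte streams and round-trip through the bundled parser. A
flexible final stage is an error for P3–P6, which deliberately skip it. The
package emits parameter documents only — it never runs minimisation or MD.

Three protocol parameters are not published and are explicit, overridable
defaults here: the binding-site release radius for P4/P6 (5 Å, a standard
contact-shell definition; released residues are those with any heavy atom
within the radius of a docked-ligand heavy atom, Zn always restrained), the
P5 restraint scheme (all-heavy target restraints, as in P1–P3), and the
truncation length for P5/P6 (keep the N-terminal 5 residues, consistent
with the five-residue head analyses). Truncation converts the new last
residue into a standard C-terminus by placing OXT as the reflection of the
carbonyl O through the CA–C axis.

## Synthetic data generator

The generator emulates the *bookkeeping* of refinement data, not
force-field physics. The toy target is a 12-residue wall with its backbone
carbonyls facing a solvent-width groove; the peptide is linear with real
PDB atom naming (sequence taken from the histone H3 tail ARTKQTARKSTGGKA),
so selections, truncation, charge seeding and LJ typing are exercised
realistically. The docked pose is the reference ligand translated rigidly,
making the planted RMSD_start exact in closed form. Default condition
values mirror the refinement setting: 0.1 ns frame spacing, a 6 Å starting
deviation (within the study's 8–27 Å range scaled to the toy size), 0.1 Å
positional noise.

Trajectories interpolate the ligand toward the reference with seeded
Gaussian noise, then rescale each frame's displacement field so its RMSD is
pinned exactly — raw noise would make improving-frame counts stochastic,
and the point of the fixture is that the planted RF is recovered *exactly*.
Hydration layouts plant reference sites on a 4 Å grid and displace
predicted copies inside (0.2–1.2 Å) or outside (1.8–2.0 Å) the match
tolerance so the success rate is exact by construction and greedy matching
provably equals the optimal assignment. All randomness flows through
NumPy's PCG64 generator seeded per-stream, so identical seed and config are
bit-identical across platforms.

What passing tests on these fixtures shows: the metric arithmetic, set
operations, matching, schedules and energy decomposition are correct
against independent oracles. What they do not show: anything about the
physical realism of MD refinement on real complexes — sampling quality,
force-field accuracy, and water-model behaviour are properties of the
simulation engine, which is outside this package.

## Problem sizes and numerical choices

The test suite runs on toy complexes of ~60 target atoms and 5–15-residue
peptides, trajectories of 40–400 frames, and water layouts of up to 100
sites — sizes chosen so the full suite completes in seconds while every
planted quantity is still recovered exactly. Tolerances used throughout:
1e-9 Å for exact rigid-motion identities, 1e-8 Å for the Kabsch/quaternion
cross-check, 1e-9 kcal/mol for the energy partition, 1e-6 e for charge
conservation, and the published rounding (integer percent, 0.1 Å) for the
worked-example ΔRMSD figures. Ties in water matching break on the lower
residue id; coincident target/ligand atoms are a hard geometry error rather
than an infinite energy.

## Known limitations

- No mmCIF output, no topology generation, no hydrogen placement.
- The energy model is a scoring-style pair sum: no solvation free energy,
  entropy, or minimisation.
- Water prediction itself (the upstream placement step) is out of scope;
  only its editing and validation arithmetic are implemented.
- LJ typing by name lookup cannot distinguish protonation variants that
  real force-field topologies encode; unknown atoms degrade to element
  defaults.
- The published per-protocol restraint matrix is not fully recoverable from
  text; the three defaults listed above are assumptions by design,
  overridable per `ProtocolSpec`.
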