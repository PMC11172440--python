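"""The six simulated-annealing refinement protocols and their stage documents.

Prints the stage-length table (initial MD + SA + optional final flexible
MD), the SA temperature ladder of one protocol, and the GROMACS-style
parameter document of its SA stage, including the annealing point lists.
"""

from peprefine import Stage, builtin_protocols, emit_mdp, get_protocol, sa_schedule

print(f"{'id':>3s} {'init (ns)':>9s} {'SA (ns)':>8s} {'flex (ns)':>9s} "
      f"{'max T (K)':>9s} {'restraints':>22s} {'trunc':>6s}")
for spec in builtin_protocols():
    print(f"{spec.id:>3s} {spec.initial_md_ns:9.0f} {spec.sa_total_ns:8.0f} "
          f"{spec.final_flex_md_ns:9.0f} {spec.sa_max_temp:9.0f} "
          f"{spec.restraint_scheme.value:>22s} {str(spec.truncate_peptide):>6s}")

p4 = get_protocol("P4")
print("\nP4 annealing schedule (time ns, temperature K):")
print("  " + "  ".join(f"({t:g}, {T:g})" for t, T in sa_schedule(p4)))

print("\nP4 SA-stage parameter document:")
print(emit_mdp(p4, Stage.SA_MD).render())
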