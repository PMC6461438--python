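# EXAMPLE ONLY: placeholder repeat-array energies for demonstrating the
# folding-energy calculator. These are NOT measured values; supply your own
# intrinsic/interfacial free energies (kcal/mol).
n_repeats: 20
dg_intrinsic: 2.0      # per-repeat folding free energy, kcal/mol
dg_interface: -5.0     # per-interface coupling free energy, kcal/mol
rt: 0.593              # kcal/mol (298 K)
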