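"""Assemble computed binding free energies and combine conformers.

Loads the packaged per-conformer energy-component table for the CB[7]
complex series (interaction, dispersion, solvation, entropic term, host and
guest deformation, all kJ/mol), sums the six terms per conformer, and
Boltzmann-combines conformers into one binding free energy per complex.
"""

from hostguest.refdata import conformer_ensembles

print(f"{'complex':<10} {'per-conformer dG_calcd':<28} {'combined dG':>12} {'dG_exp':>8}")
for ens in conformer_ensembles():
    assembled = ", ".join(f"{dg:7.1f}" for dg in ens.assembled())
    print(f"{ens.complex_id:<10} [{assembled:<26}] {ens.combined_dg():12.2f} {ens.dg_exp:8.1f}")
# Combined values are never above the best conformer; for complexes whose
# two conformers lie within a few RT of each other the combination drops
# the free energy by up to ~RT ln 2 = 1.7 kJ/mol below the minimum.
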