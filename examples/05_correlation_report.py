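"""Correlate computed and experimental binding free energies and report.

Boltzmann-combines the per-conformer computed free energies of the five
CB[7] complexes, regresses the experimental values on them by ordinary
least squares, and emits the pipeline report with every consistency flag
(Gibbs-relation checks and experimental-source discrepancies).
"""

from hostguest import ThermoRecord, assemble_comparison, ols_fit, report
from hostguest.refdata import conformer_ensembles, experimental_thermo

ensembles = conformer_ensembles()
calorimetric = [
    ThermoRecord("CB7-" + t.complex_id, kd=t.kd, dg=t.dg, dh=t.dh,
                 minus_t_ds=t.minus_t_ds)
    for t in experimental_thermo()
    if t.complex_id in ("1a", "1b", "1h", "1i", "2a")
]

comparison = assemble_comparison(ensembles, calorimetric, source_policy="attached")
fitted = comparison[comparison["combined_dg"].notna()]
regression = ols_fit(fitted["combined_dg"], fitted["dg_exp"])
print(regression.summary())
print()
print(report(comparison=comparison, regression=regression, thermo=calorimetric))
# The regression line has slope ~0.15: the additive computed free energies
# overspread the experimental range by almost an order of magnitude, but
# rank the complexes consistently (R^2 = 0.85).
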