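"""Validation statistics: DFR ELISpot positivity and FP competition IC50.

Simulates an ELISpot plate with known responder peptides and a
fluorescence-polarization competition series with a known IC50, then runs
the DFR1x/DFR2x permutation tests and the one-parameter IC50 fit.
"""

from isletpep import SyntheticConfig, dfr_both, fit_ic50, fraction_bound, generate_validation_assays

assays = generate_validation_assays(SyntheticConfig(seed=5), n_plates=1)
plate = assays.plates[0]

print("ELISpot DFR positivity (adjusted p, DFR1x / DFR2x):")
for pep, by_m in dfr_both(plate, seed=5).items():
    truth = "responder" if pep in assays.truth.responders else "null     "
    mark = "**" if by_m[2].positive else ("*" if by_m[1].positive else "")
    print(f"  {pep}  {truth}  p1x={by_m[1].p_adjusted:.3f}  p2x={by_m[2].p_adjusted:.3f} {mark}")
print("  ** positive under the stricter DFR2x null (mean exp <= 2x mean control)")

series_id, series = assays.fp_series[0]
fit = fit_ic50(fraction_bound(series))
true = assays.truth.true_ic50[series_id]
print(f"\nFP competition fit: IC50 = {fit.ic50 * 1e9:.0f} nM "
      f"(true {true * 1e9:.0f} nM)")
print("IC50 is the test-peptide concentration displacing half the probe peptide.")
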