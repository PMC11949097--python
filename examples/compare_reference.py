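"""Deviation report of the analytic model against the published grid.

Evaluates the Compton-mixture model for water at every published energy in
the Compton-dominated 0.15-2 MeV band and summarizes the per-point percent
deviations, the same kind of agreement statement the reference data were
validated with.
"""

from photonmu import analytic_coefficients, compare, load_reference, load_tissue

ref = load_reference()
water = load_tissue("Water")
band = (0.15, 2.0)

energies = [float(e) for e in ref.energies if band[0] <= e <= band[1]]
triples = [analytic_coefficients(water, e) for e in energies]
report = compare(triples, ref, "Water", band=band)
print(report.to_text())
print(
    "\nR^2 ~ 1 and percent-level worst-case deviations (largest at the band "
    "edges) mean the\nfree-electron Compton model explains the published "
    "coefficients in this band; outside it,\nphotoelectric absorption (low E) "
    "and pair production (high E) require tabulated\ncross-section providers."
)
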