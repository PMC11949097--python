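"""Narrow-beam Monte Carlo estimation of the water coefficient triple.

Fires 10^6 monoenergetic 1 MeV photons down the axis of a water absorber
one mean free path thick, then inverts the tallies: the un-collided
transmission gives mu/rho (Beer-Lambert), and the first-collision kerma per
un-collided energy fluence gives mu_tr/rho and mu_en/rho.
"""

from photonmu import (
    EstimateRequest,
    coefficients_from_tallies,
    load_tissue,
    relative_error,
    simulate_narrow_beam,
)

water = load_tissue("Water")
tally = simulate_narrow_beam(water, E=1.0, n_histories=1_000_000, seed=42)

print(f"absorber thickness (1 mfp): {tally.thickness:.2f} cm")
print(
    f"un-collided transmission:   {tally.detector_uncollided / tally.n_histories:.4f}"
    "  (expected e^-1 = 0.3679)"
)
print(f"rel. error of transmission: {relative_error(tally, 'transmission'):.2e}")

est = coefficients_from_tallies(EstimateRequest.from_tally(tally))
print(f"\nmu/rho    = {est.mu_rho:.5f} +/- {est.se_mu_rho:.5f} cm^2/g  (published 0.07042)")
print(f"mutr/rho  = {est.mu_tr_rho:.5f} +/- {est.se_mu_tr_rho:.5f} cm^2/g  (published 0.03114)")
print(f"muen/rho  = {est.mu_en_rho:.5f} +/- {est.se_mu_en_rho:.5f} cm^2/g  (published 0.03111)")
print(
    "\nEach estimate should sit within a percent of the published value; the "
    "quoted standard\nerrors shrink as 1/sqrt(histories)."
)
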