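# Methods

## The quantities

For monoenergetic photons of energy *E* traversing a material of density ρ,
three mass coefficients (cm²/g) summarize the interaction physics:

- μ/ρ — removal probability per unit areal density; defined operationally
  through narrow-beam (scatter-free) attenuation, I(x) = I₀ e^{−(μ/ρ)ρx}.
- μtr/ρ — energy transferred to charged-particle kinetic energy per unit
  areal density; kerma K = Φ_E · μtr/ρ for energy fluence Φ_E.
- μen/ρ = (μtr/ρ)(1 − g) — the collision-kerma analogue, with g the
  radiative fraction (energy re-emitted as bremsstrahlung by the
  liberated electrons).

By construction μ/ρ ≥ μtr/ρ ≥ μen/ρ; the package asserts this ordering for
everything it computes. (The bundled reference grid itself violates the
last inequality by a few 10⁻⁴ at ≥10 MeV — e.g. adipose at 15 MeV — which
we treat as noise in the published table, so the invariant is never
asserted on reference values.)

## Materials

A material is (name, ρ, weight fractions over the 12 elements H, C, N, O,
Na, Mg, P, S, Cl, K, Ca, Fe). The bundled library holds eleven ICRU-44 /
ICRP-89-style body tissues plus water. Atomic masses are IUPAC standard
atomic weights hard-coded in the registry; at the package's 1% validation
tolerance, differences between atomic-weight revisions are immaterial.
Weight-fraction sums are accepted within 10⁻³ and renormalized (with a
logged warning); larger deviations are rejected as transcription errors
rather than silently rescaled. Blank entries in published composition
tables are weight fraction zero. Atom-fraction (formula) input, isotopics
and temperature dependence are out of scope.

## Cross sections

**Default channel: Klein–Nishina Compton scattering off free electrons.**
The total cross section per electron σ_KN(α), α = E/m_ec², and the
energy-transfer cross section σ_KN,tr = ∫ (T/E) dσ are implemented in
closed form. Below α = 0.01 both closed forms lose precision to
cancellation, so a Taylor series (through α⁷, derived symbolically) takes
over; the switch point keeps both branches accurate to better than 10⁻⁸
relative. Both are unit-tested against independent numerical quadrature of
the angle-differential cross section to 5 significant figures across
0.01–20 MeV.

Electron binding (incoherent scattering function) is neglected: electrons
are treated as free and at rest. This is the dominant model bias at the
low-energy end of the Compton band — about 1% on μ/ρ for water at 0.15 MeV,
shrinking rapidly with energy — and is the reason quantitative validation
is restricted to ≈0.15–2 MeV. Doppler broadening, polarization and
photonuclear reactions are likewise out of scope.

**Optional channels.** Photoelectric, Rayleigh and pair production enter as
per-element CSV tables (columns `energy_MeV, sigma_cm2_per_atom,
sigma_tr_cm2_per_atom`, strictly increasing energies), interpolated
log–log; evaluation outside the tabulated range raises rather than
extrapolates (fail-fast, standard practice for photon data). The pair
channel returns zero below the 1.022 MeV threshold regardless of the
table. 1 barn = 10⁻²⁴ cm² exactly.

**Mixtures.** The additivity rule is applied exactly: mixture mass
coefficients are weight-fraction-weighted sums of elemental ones, with
σ per atom converted by N_A/A. Consequently, with Compton-only physics,
μ/ρ of two materials at the same energy scales exactly as their
electrons-per-gram ratio.

**Radiative fraction.** Default g ≡ 0. For the low-Z tissues in the
validation band the published μen–μtr gap is ≤0.5%, inside the package's
tolerance, and a physical g(E, Z) model would add a dependency without
changing any validated number. A table-driven g(E) override is provided
for users who have one.

## Transport

Geometry: point source 100 cm before a cylindrical absorber (r = 0.5 cm)
whose thickness defaults to one mean free path 1/((μ/ρ)ρ); a detector disc
200 cm from the source accepts only un-collided photons; vacuum everywhere
else. The source is an ideal pencil beam on the axis, which makes the radii
non-binding (they are kept for fidelity to the physical bench) and makes
narrow-beam geometry exact: no scattered photon can be miscounted.

Each history samples one free path from the total macroscopic cross
section Σ. If it exceeds the thickness the photon scores at the detector
(transmission I) and contributes its full crossing to the un-collided
track-length fluence; otherwise the first collision scores kerma. Because
every history is a single exponential draw against a fixed thickness, the
whole run is evaluated vectorically in numpy — this is an exact
reformulation of the event loop, not an approximation.

**Scoring.** Two modes, both unbiased:

- *expected* (default): each collision scores E·Σtr/Σ — the expected
  transferred energy — cutting variance;
- *sampled*: the interaction channel is drawn ∝ its macroscopic cross
  section and, for Compton, the actual scattered energy E′ is sampled from
  the exact Klein–Nishina density (composition-rejection: a 1/ε–ε envelope
  mixture with acceptance factor 1 − ε sin²θ/(1+ε²)), scoring E − E′.

The two modes must and do agree within statistics; the sampled mode exists
chiefly to validate the expected-value mode. Secondary electrons are not
transported: the target quantities are defined through kerma, so scoring
transferred energy at the interaction point is the correct estimator, with
radiative escape handled entirely by the g model.

**Estimators.** With unprimed tallies restricted to un-collided particles,

- μ/ρ = −ln(I/I₀)/(xρ), with I₀ = n taken analytically (the open-beam
  vacuum run is deterministic; an explicit two-run mode exists for
  fidelity);
- μtr/ρ = D′/Φ′_E and μen/ρ = D/Φ_E.

Both fluence denominators use the un-collided track-length estimator and
the kerma numerators score first collisions only; the primed/unprimed
distinction is whether the radiative fraction is removed. This choice makes
each ratio exact in expectation for *any* absorber thickness: per history,
E[kerma] = (1−e^{−Σx}) E Σtr/Σ / m and E[Φ_E] = (1−e^{−Σx}) E/(ΣV), whose
ratio is identically μtr/ρ. Tracking the scattered shower would only add
variance to a quantity whose definition excludes it.

**Errors.** Every score keeps per-history sum and sum-of-squares (and the
kerma×track cross product), giving SEM/mean relative errors that scale as
n^{−1/2}. μ/ρ errors use the delta method on ln(I/I₀) with binomial I;
the kerma/fluence ratios use the ratio-of-means variance including the
numerator–denominator covariance, which matters because a collided history
scores kerma but a shorter track (anticorrelation). At 10⁶ histories the
relative errors at 1 MeV are ≈0.1–0.2%, comfortably below the 1%
regression tolerance.

**Reproducibility.** One numpy `default_rng(seed)` stream per run;
identical (seed, arguments) give bit-identical tallies. Free paths are
drawn in history order, so expected-mode runs are prefix-stable (the first
n′ histories of a longer run reproduce the n′-history run); sampled mode
uses vectorized rejection, which is reproducible but not prefix-stable —
per-history substreams would restore that at an order-of-magnitude runtime
cost and were not worth it for a validation-only mode. Every run can be
serialized to a JSON manifest (config + seed + version + tallies)
sufficient to reproduce it.

## Reference grid and comparisons

The packaged CSV (28 energies × 12 materials × 3 coefficients, checksummed)
is transcribed verbatim from its published source, uneven significant
digits included; all comparisons are relative so digit count is
immaterial. `compare` reports per-point percent deviations, max|%|, RMS%
and R² per coefficient kind over a chosen band; `mu_en_mu_tr_gap` measures
the published μen–μtr proximity (≤0.5% for water over 0.15–2 MeV,
≈0.10% at exactly 1 MeV). Re-deriving external coefficient databases
(e.g. the NIST XCOM tabulations) is out of scope.

## What the validation does and does not show

The regression suite establishes: (i) the Klein–Nishina implementation is
correct to 5 significant figures against quadrature; (ii) the transport
plus estimators recover arbitrary synthetic cross sections (closed-loop,
3σ); (iii) transmission follows Beer–Lambert and errors scale as n^{−1/2};
(iv) in the Compton band the full pipeline reproduces published tissue
coefficients to ≲1%. It does **not** show agreement outside that band with
the default physics (no photoelectric/pair data are bundled — validation
there is property-based: ordering, error scaling, provider recovery,
sampled-vs-expected agreement), nor does it capture detector response,
beam divergence or build-up in broad-beam conditions, which real
attenuation measurements must contend with.

## Problem sizes

Default Monte Carlo runs use 10⁶ histories (relative errors ≈0.1%); the
statistical property tests use 10³–10⁶ histories and the distributional
tests of the Compton sampler use 10⁶ samples. The vectorized transport
makes all of these near-instant on one CPU.
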