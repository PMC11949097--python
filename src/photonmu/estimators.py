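"""Convert narrow-beam tallies into mass interaction coefficients.

Three estimators, one per coefficient:

* mu/rho      = -ln(I/I0) / (x * rho)   — Beer-Lambert inversion of the
  un-collided transmission through an absorber of thickness x.
* mu_en/rho   = D / Phi_E               — collision kerma per unit
  un-collided energy fluence.
* mu_tr/rho   = D' / Phi'_E             — total kerma per unit energy
  fluence.

Standard errors come from the delta method on ln(I/I0) (the transmission is
binomial when I0 is the deterministic open-beam count) and from the
ratio-of-means variance formula for the kerma/fluence ratios, including the
numerator-denominator covariance accumulated history by history (a collided
history scores kerma but a shorter track, so the two are anticorrelated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cross_sections import CoefficientTriple
from .transport import TallyResult

__all__ = [
    "EstimateRequest",
    "mass_attenuation",
    "mass_energy_absorption",
    "mass_energy_transfer",
    "coefficients_from_tallies",
]


@dataclass(frozen=True)
class EstimateRequest:
    """Tallies plus the absorber parameters the estimators need."""

    tally: TallyResult
    absorber_thickness: float  # cm
    density: float             # g/cm^3

    def __post_init__(self) -> None:
        if self.absorber_thickness <= 0:
            raise ValueError("absorber thickness must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @classmethod
    def from_tally(cls, tally: TallyResult) -> "EstimateRequest":
        return cls(tally=tally, absorber_thickness=tally.thickness,
                   density=tally.density)


def mass_attenuation(I: float, I0: float, x: float, rho: float) -> float:
    """mu/rho from transmitted vs open-beam counts: -(1/(x rho)) ln(I/I0)."""
    if x <= 0 or rho <= 0:
        raise ValueError("thickness and density must be positive")
    if I0 <= 0:
        raise ValueError("open-beam count must be positive")
    if I <= 0:
        raise ValueError(
            "no un-collided photon reached the detector; increase histories"
        )
    if I > I0:
        raise ValueError(f"transmitted count {I} exceeds open-beam count {I0}")
    return -math.log(I / I0) / (x * rho)


def mass_energy_absorption(D: float, PhiE: float) -> float:
    """mu_en/rho as the ratio of collision kerma to energy fluence, cm^2/g."""
    if PhiE <= 0:
        raise ValueError("energy fluence must be positive")
    if D < 0:
        raise ValueError("dose cannot be negative")
    return D / PhiE


def mass_energy_transfer(Dp: float, PhiEp: float) -> float:
    """mu_tr/rho as the ratio of total kerma to energy fluence, cm^2/g."""
    if PhiEp <= 0:
        raise ValueError("energy fluence must be positive")
    if Dp < 0:
        raise ValueError("dose cannot be negative")
    return Dp / PhiEp


def _ratio_se(tally: TallyResult, num_score: str, den_score: str, value: float) -> float:
    """SE of a ratio of per-history means, with numerator-denominator covariance."""
    if value == 0:
        return 0.0
    n = tally.n_histories
    sn, ssn = tally.score_moments(num_score)
    sd, ssd = tally.score_moments(den_score)
    mn, md = sn / n, sd / n
    var_n = max(ssn / n - mn**2, 0.0)
    var_d = max(ssd / n - md**2, 0.0)
    cov = tally.cross_moment(num_score) / n - mn * md
    rel_var = var_n / mn**2 + var_d / md**2 - 2.0 * cov / (mn * md)
    return abs(value) * math.sqrt(max(rel_var, 0.0) / (n - 1))


def coefficients_from_tallies(req: EstimateRequest, E: float | None = None) -> CoefficientTriple:
    """Apply all three estimators to one tally and propagate standard errors.

    ``E`` defaults to the energy recorded in the tally.  Degenerate
    (zero-variance) tallies yield zero standard errors.
    """
    t = req.tally
    E = t.energy if E is None else float(E)
    x, rho = req.absorber_thickness, req.density

    I, I0 = t.detector_uncollided, t.detector_open_beam
    mu = mass_attenuation(I, I0, x, rho)
    # delta method on ln(I/I0) with binomial I, deterministic I0:
    # var(ln I) ~ (1-p)/(p n) = (I0 - I)/(I I0) * I0/I0
    p = I / I0
    se_mu = math.sqrt((1.0 - p) / I) / (x * rho)

    mu_en = mass_energy_absorption(t.dose, t.energy_fluence)
    mu_tr = mass_energy_transfer(t.dose_primed, t.energy_fluence_primed)
    se_mu_en = _ratio_se(t, "dose", "energy_fluence", mu_en) if mu_en > 0 else 0.0
    se_mu_tr = _ratio_se(t, "dose_primed", "energy_fluence", mu_tr) if mu_tr > 0 else 0.0

    return CoefficientTriple(
        energy=E,
        mu_rho=mu,
        mu_tr_rho=mu_tr,
        mu_en_rho=mu_en,
        se_mu_rho=se_mu,
        se_mu_tr_rho=se_mu_tr,
        se_mu_en_rho=se_mu_en,
    )
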