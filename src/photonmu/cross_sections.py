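"""Photon interaction cross sections and the elemental additivity rule.

The default physics is incoherent (Compton) scattering off free electrons
in the Klein-Nishina approximation, which carries both a total cross
section and an energy-transfer cross section (the recoil-energy-weighted
integral of the differential cross section).  Photoelectric absorption,
Rayleigh scattering and pair production can be supplied as tabulated
per-element providers read from CSV; they plug into the same provider
contract and simply add their macroscopic contributions.

Per-electron quantities are converted to mass coefficients (cm^2/g) of a
mixture through the additivity rule: the mixture coefficient is the
weight-fraction-weighted sum of the elemental ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    AVOGADRO,
    BARN_CM2,
    ELECTRON_REST_MEV,
    PAIR_THRESHOLD_MEV,
    R_ELECTRON_CM,
)
from .materials import ELEMENTS, MaterialComposition

__all__ = [
    "kn_total",
    "kn_transfer",
    "kn_differential",
    "sample_compton",
    "CrossSectionProvider",
    "AnalyticComptonProvider",
    "TabulatedProvider",
    "RadiativeFractionModel",
    "ZERO_RADIATIVE_FRACTION",
    "TabulatedRadiativeFraction",
    "CoefficientTriple",
    "mixture_coefficient",
    "element_mass_coefficients",
    "analytic_coefficients",
]

_TWO_PI_RE2 = 2.0 * math.pi * R_ELECTRON_CM**2

# Small-alpha Taylor coefficients of the bracketed Klein-Nishina factors
# (cross section = 2*pi*r_e^2 * bracket).  Used below alpha = 0.01 where the
# closed forms lose digits to cancellation.
_TOTAL_SERIES = (4 / 3, -8 / 3, 104 / 15, -266 / 15, 4576 / 105, -2176 / 21,
                 15136 / 63, -24592 / 45)
_TRANSFER_SERIES = (0.0, 4 / 3, -28 / 5, 98 / 5, -6464 / 105, 3760 / 21,
                    -10336 / 21, 58352 / 45)
_SERIES_SWITCH = 0.01


def _check_energy(E: float) -> float:
    E = float(E)
    if not E > 0:
        raise ValueError(f"photon energy must be positive, got {E} MeV")
    return E


def _poly(coeffs: Sequence[float], a: float) -> float:
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * a + c
    return acc


def kn_total(E: float) -> float:
    """Total Klein-Nishina cross section per electron, in barn.

    Closed form in alpha = E / m_e c^2; tends to the Thomson cross section
    (0.66525 barn) as E -> 0 and decreases strictly with energy.
    """
    E = _check_energy(E)
    a = E / ELECTRON_REST_MEV
    if a < _SERIES_SWITCH:
        bracket = _poly(_TOTAL_SERIES, a)
    else:
        t = math.log1p(2 * a)
        bracket = (
            (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - t / a)
            + t / (2 * a)
            - (1 + 3 * a) / (1 + 2 * a) ** 2
        )
    return _TWO_PI_RE2 * bracket / BARN_CM2


def kn_transfer(E: float) -> float:
    """Klein-Nishina energy-transfer cross section per electron, in barn.

    Equals the integral of (T/E) dsigma over scattering angle, with T the
    electron recoil energy; the ratio to :func:`kn_total` is the mean
    fraction of the photon energy handed to the electron and grows
    monotonically with energy (0 at E -> 0, 0.44 at 1 MeV).
    """
    E = _check_energy(E)
    a = E / ELECTRON_REST_MEV
    if a < _SERIES_SWITCH:
        bracket = _poly(_TRANSFER_SERIES, a)
    else:
        t = math.log1p(2 * a)
        bracket = (
            2 * (1 + a) ** 2 / (a**2 * (1 + 2 * a))
            - (1 + 3 * a) / (1 + 2 * a) ** 2
            - (1 + a) * (2 * a**2 - 2 * a - 1) / (a**2 * (1 + 2 * a) ** 2)
            - 4 * a**2 / (3 * (1 + 2 * a) ** 3)
            - ((1 + a) / a**3 - 1 / (2 * a) + 1 / (2 * a**3)) * t
        )
    return _TWO_PI_RE2 * bracket / BARN_CM2


def kn_differential(E: float, eps: np.ndarray | float) -> np.ndarray | float:
    """Differential cross section d(sigma)/d(eps) per electron, cm^2.

    ``eps`` is the scattered-to-incident energy ratio E'/E, valid on
    [1/(1+2 alpha), 1].  Exposed so samplers and goodness-of-fit tests can
    share one analytic density.
    """
    E = _check_energy(E)
    a = E / ELECTRON_REST_MEV
    eps = np.asarray(eps, dtype=float)
    t = (1.0 - eps) / (a * eps)
    sin2 = t * (2.0 - t)
    return math.pi * R_ELECTRON_CM**2 / a * (eps + 1.0 / eps - sin2)


def sample_compton(
    E: float, rng: np.random.Generator, size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample scattered photon energies and polar angles at energy ``E``.

    Uses composition-rejection on the exact Klein-Nishina density in
    eps = E'/E: eps is drawn from a mixture of 1/eps and eps envelopes and
    accepted with probability 1 - eps sin^2(theta) / (1 + eps^2).  Returns
    ``(E_prime, theta)`` arrays of length ``size`` (scalars if size is
    None).  The rejection loop terminates with probability one; acceptance
    efficiency stays above ~60% at all energies.
    """
    E = _check_energy(E)
    a = E / ELECTRON_REST_MEV
    n = 1 if size is None else int(size)
    eps_min = 1.0 / (1.0 + 2.0 * a)
    w1 = math.log(1.0 / eps_min)           # weight of the 1/eps branch
    w2 = 0.5 * (1.0 - eps_min**2)          # weight of the eps branch
    p1 = w1 / (w1 + w2)

    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        u = rng.random((3, todo.size))
        eps = np.where(
            u[0] < p1,
            eps_min * np.exp(w1 * u[1]),
            np.sqrt(eps_min**2 + (1.0 - eps_min**2) * u[1]),
        )
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        accept = u[2] <= 1.0 - eps * sin2 / (1.0 + eps**2)
        out[todo[accept]] = eps[accept]
        todo = todo[~accept]

    cos_theta = np.clip(1.0 - (1.0 - out) / (a * out), -1.0, 1.0)
    theta = np.arccos(cos_theta)
    e_prime = out * E
    if size is None:
        return float(e_prime[0]), float(theta[0])
    return e_prime, theta


@dataclass(frozen=True)
class CrossSectionProvider:
    """One interaction channel: per-atom total and energy-transfer cross sections.

    ``evaluate(element_symbol, E)`` and ``transfer_evaluate(element_symbol, E)``
    return cm^2/atom; 0 <= transfer <= total everywhere, and the pair channel
    is zero below the 1.022 MeV threshold.
    """

    channel: str  # compton | photoelectric | rayleigh | pair
    evaluate: Callable[[str, float], float]
    transfer_evaluate: Callable[[str, float], float]
    provenance: str = "analytic"  # analytic | tabulated

    _CHANNELS = ("compton", "photoelectric", "rayleigh", "pair")

    def __post_init__(self) -> None:
        if self.channel not in self._CHANNELS:
            raise ValueError(
                f"channel must be one of {self._CHANNELS}, got {self.channel!r}"
            )


def AnalyticComptonProvider() -> CrossSectionProvider:
    """The default provider: Z free electrons per atom, Klein-Nishina physics."""

    def evaluate(symbol: str, E: float) -> float:
        return ELEMENTS[symbol].Z * kn_total(E) * BARN_CM2

    def transfer_evaluate(symbol: str, E: float) -> float:
        return ELEMENTS[symbol].Z * kn_transfer(E) * BARN_CM2

    return CrossSectionProvider(
        channel="compton",
        evaluate=evaluate,
        transfer_evaluate=transfer_evaluate,
        provenance="analytic",
    )


class TabulatedProvider:
    """A channel backed by per-element CSV tables, log-log interpolated.

    Each CSV has columns ``energy_MeV, sigma_cm2_per_atom,
    sigma_tr_cm2_per_atom`` with strictly increasing energies.  Evaluation
    outside the tabulated range raises rather than extrapolates.
    """

    def __init__(self, channel: str, tables: Mapping[str, str | Path]):
        self.channel = channel
        self._grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for symbol, path in tables.items():
            import pandas as pd

            df = pd.read_csv(path)
            required = {"energy_MeV", "sigma_cm2_per_atom", "sigma_tr_cm2_per_atom"}
            if not required.issubset(df.columns):
                raise ValueError(
                    f"{path}: expected columns {sorted(required)}, "
                    f"got {list(df.columns)}"
                )
            e = df["energy_MeV"].to_numpy(float)
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValueError(f"{path}: energies must be strictly increasing")
            s = df["sigma_cm2_per_atom"].to_numpy(float)
            st = df["sigma_tr_cm2_per_atom"].to_numpy(float)
            if np.any(s < 0) or np.any(st < 0) or np.any(st > s * (1 + 1e-12)):
                raise ValueError(
                    f"{path}: need 0 <= sigma_tr <= sigma at every energy"
                )
            self._grids[symbol] = (e, s, st)
        # delegate through the shared dataclass contract
        self._provider = CrossSectionProvider(
            channel=channel,
            evaluate=self._evaluate,
            transfer_evaluate=self._transfer_evaluate,
            provenance="tabulated",
        )

    def _interp(self, symbol: str, E: float, col: int) -> float:
        if symbol not in self._grids:
            raise KeyError(
                f"no {self.channel} table for element {symbol!r}"
            )
        e, s, st = self._grids[symbol]
        if self.channel == "pair" and E < PAIR_THRESHOLD_MEV:
            return 0.0
        if E < e[0] or E > e[-1]:
            raise ValueError(
                f"{self.channel}/{symbol}: energy {E} MeV outside tabulated "
                f"range [{e[0]}, {e[-1]}]; extrapolation is not performed"
            )
        y = (s, st)[col]
        if np.all(y > 0):
            return float(np.exp(np.interp(math.log(E), np.log(e), np.log(y))))
        return float(np.interp(E, e, y))  # linear fallback when zeros present

    def _evaluate(self, symbol: str, E: float) -> float:
        return self._interp(symbol, E, 0)

    def _transfer_evaluate(self, symbol: str, E: float) -> float:
        return self._interp(symbol, E, 1)

    @property
    def provider(self) -> CrossSectionProvider:
        return self._provider


@dataclass(frozen=True)
class RadiativeFractionModel:
    """Fraction g of transferred electron energy re-emitted radiatively.

    mu_en/rho = mu_tr/rho * (1 - g).  The default model is g identically
    zero, appropriate for low-Z tissues below a few MeV where bremsstrahlung
    losses are sub-percent.
    """

    g: Callable[[MaterialComposition, float], float]
    label: str = "zero"

    def __call__(self, mat: MaterialComposition, E: float) -> float:
        val = float(self.g(mat, E))
        if not 0.0 <= val < 1.0:
            raise ValueError(f"radiative fraction must lie in [0, 1), got {val}")
        return val


ZERO_RADIATIVE_FRACTION = RadiativeFractionModel(g=lambda mat, E: 0.0, label="zero")


def TabulatedRadiativeFraction(
    energies: Sequence[float], g_values: Sequence[float]
) -> RadiativeFractionModel:
    """Material-independent g(E) interpolated linearly in log E."""
    e = np.asarray(energies, float)
    gv = np.asarray(g_values, float)
    if e.size != gv.size or e.size < 2 or np.any(np.diff(e) <= 0):
        raise ValueError("need matching, strictly increasing energy grid")
    if np.any((gv < 0) | (gv >= 1)):
        raise ValueError("g values must lie in [0, 1)")
    loge = np.log(e)

    def g(mat: MaterialComposition, E: float) -> float:
        return float(np.interp(math.log(E), loge, gv))

    return RadiativeFractionModel(g=g, label="tabulated")


@dataclass(frozen=True)
class CoefficientTriple:
    """(mu/rho, mu_tr/rho, mu_en/rho) at one energy, with standard errors.

    Standard errors are zero for analytic evaluation.  Computed triples
    satisfy mu/rho >= mu_tr/rho >= mu_en/rho.
    """

    energy: float  # MeV
    mu_rho: float  # cm^2/g
    mu_tr_rho: float
    mu_en_rho: float
    se_mu_rho: float = 0.0
    se_mu_tr_rho: float = 0.0
    se_mu_en_rho: float = 0.0


def mixture_coefficient(
    mat: MaterialComposition, element_values: Mapping[str, float]
) -> float:
    """Additivity rule: weight-fraction-weighted sum of elemental values.

    ``element_values`` maps element symbol -> mass coefficient (cm^2/g).
    Every element carrying weight in the material must be present.
    """
    total = 0.0
    for sym, w in mat.fractions.items():
        if w == 0:
            continue
        if sym not in element_values:
            raise KeyError(
                f"no elemental value for {sym!r} required by {mat.name!r}"
            )
        total += w * element_values[sym]
    return total


def element_mass_coefficients(
    providers: Iterable[CrossSectionProvider],
    symbols: Iterable[str],
    E: float,
    transfer: bool = False,
) -> dict[str, float]:
    """Per-element mass coefficients (cm^2/g) summed over channels.

    sigma (cm^2/atom) converts to a mass coefficient via N_A / A.
    """
    out: dict[str, float] = {}
    for sym in symbols:
        A = ELEMENTS[sym].A
        acc = 0.0
        for p in providers:
            sig = p.transfer_evaluate(sym, E) if transfer else p.evaluate(sym, E)
            acc += sig * AVOGADRO / A
        out[sym] = acc
    return out


def analytic_coefficients(
    mat: MaterialComposition,
    E: float,
    providers: Sequence[CrossSectionProvider] | None = None,
    g_model: RadiativeFractionModel = ZERO_RADIATIVE_FRACTION,
) -> CoefficientTriple:
    """Deterministic coefficient triple from the provider physics.

    mu/rho sums the per-gram macroscopic cross sections of all channels;
    mu_tr/rho sums their energy-transfer parts; mu_en/rho removes the
    radiative fraction.  With the default (Klein-Nishina Compton only)
    physics this is exact for the free-electron model.
    """
    E = _check_energy(E)
    if providers is None:
        providers = [AnalyticComptonProvider()]
    providers = list(providers)
    if not providers:
        raise ValueError("at least one cross-section provider is required")
    symbols = mat.elements
    mu = mixture_coefficient(
        mat, element_mass_coefficients(providers, symbols, E, transfer=False)
    )
    mu_tr = mixture_coefficient(
        mat, element_mass_coefficients(providers, symbols, E, transfer=True)
    )
    mu_en = mu_tr * (1.0 - g_model(mat, E))
    return CoefficientTriple(energy=E, mu_rho=mu, mu_tr_rho=mu_tr, mu_en_rho=mu_en)
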