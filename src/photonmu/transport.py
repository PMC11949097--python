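"""Analog Monte Carlo transport of a photon pencil beam through a slab absorber.

The geometry mirrors a narrow-beam attenuation bench: a monoenergetic point
source emits parallel photons down the axis of a cylindrical absorber whose
thickness defaults to one mean free path, with a small scoring disc farther
down the axis acting as the detector.  Transport is analog — free paths are
sampled from the total macroscopic cross section with no variance-reduction
biasing — and secondary electrons are not followed: energy transferred to
electrons is scored at the interaction site (kerma approximation).

Because the beam is an ideal pencil and the detector only accepts
un-collided photons, each history reduces to a single free-path draw
against the slab thickness, which the implementation evaluates for all
histories at once.  A history either traverses the slab without interacting
(and is counted at the detector) or undergoes its first collision inside,
where the expected — or, optionally, sampled — energy transfer is scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cross_sections import (
    AnalyticComptonProvider,
    CrossSectionProvider,
    RadiativeFractionModel,
    ZERO_RADIATIVE_FRACTION,
    element_mass_coefficients,
    mixture_coefficient,
    sample_compton,
)
from .materials import MaterialComposition

__all__ = [
    "BeamGeometry",
    "TallyResult",
    "mfp_thickness",
    "simulate_narrow_beam",
    "relative_error",
    "write_manifest",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Source/absorber/detector layout along the beam axis, lengths in cm.

    The source sits 100 cm before the absorber's upstream face; the
    detector disc is 200 cm from the source.  With an ideal pencil beam the
    radii never clip any trajectory; they are kept for fidelity to the
    physical bench.  Everything outside the absorber is vacuum.
    """

    source_to_origin: float = 100.0
    absorber_radius: float = 0.5
    detector_distance_from_source: float = 200.0
    detector_radius: float = 0.5
    detector_thickness: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "source_to_origin",
            "absorber_radius",
            "detector_distance_from_source",
            "detector_radius",
            "detector_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def validate_thickness(self, thickness: float) -> None:
        if thickness <= 0:
            raise ValueError("absorber thickness must be positive")
        if self.source_to_origin + thickness >= self.detector_distance_from_source:
            raise ValueError(
                "detector must lie beyond the absorber along the beam axis"
            )

    def absorber_volume(self, thickness: float) -> float:
        return math.pi * self.absorber_radius**2 * thickness


@dataclass
class TallyResult:
    """Raw scores of one narrow-beam run, with variance accumulators.

    Per-history scores are accumulated as sums and sums of squares so the
    standard error of every mean is available afterwards.  The un-collided
    restriction applies to the detector count and to the track-length
    (energy-fluence) scores; the dose scores are first-collision kerma —
    ``dose`` with the radiative fraction removed (collision kerma),
    ``dose_primed`` without (total kerma).
    """

    material: str
    energy: float            # MeV
    n_histories: int
    seed: int
    thickness: float         # cm
    density: float           # g/cm^3
    absorber_volume: float   # cm^3
    scoring: str             # expected | sampled
    detector_uncollided: int = 0
    detector_open_beam: int = 0
    sum_track: float = 0.0        # cm, un-collided track length in absorber
    sumsq_track: float = 0.0
    sum_transfer: float = 0.0     # MeV, kerma score per history
    sumsq_transfer: float = 0.0
    sum_transfer_col: float = 0.0  # MeV, collision-kerma score
    sumsq_transfer_col: float = 0.0
    # cross products with the track-length score, for ratio-estimator errors
    sum_cross_transfer_track: float = 0.0
    sum_cross_transfer_col_track: float = 0.0

    @property
    def absorber_mass(self) -> float:
        return self.absorber_volume * self.density

    # --- per-source-particle tally values -------------------------------
    @property
    def uncollided_track_length(self) -> float:
        return self.sum_track

    @property
    def energy_fluence(self) -> float:
        """Phi_E, MeV/cm^2 per source particle (un-collided track length)."""
        return self.energy * self.sum_track / (self.absorber_volume * self.n_histories)

    @property
    def energy_fluence_primed(self) -> float:
        """Phi'_E; identical estimator to Phi_E (see module docs)."""
        return self.energy_fluence

    @property
    def dose(self) -> float:
        """D, MeV/g per source particle (collision kerma)."""
        return self.sum_transfer_col / (self.absorber_mass * self.n_histories)

    @property
    def dose_primed(self) -> float:
        """D', MeV/g per source particle (total kerma)."""
        return self.sum_transfer / (self.absorber_mass * self.n_histories)

    _SCORES = ("transmission", "track", "energy_fluence", "dose", "dose_primed")

    def score_moments(self, score: str) -> tuple[float, float]:
        """(sum, sum of squares) of the per-history samples of ``score``."""
        if score == "transmission":
            s = float(self.detector_uncollided)
            return s, s  # indicator variable: x^2 == x
        if score in ("track", "energy_fluence"):
            return self.sum_track, self.sumsq_track
        if score == "dose":
            return self.sum_transfer_col, self.sumsq_transfer_col
        if score == "dose_primed":
            return self.sum_transfer, self.sumsq_transfer
        raise KeyError(f"unknown score {score!r}; known: {self._SCORES}")

    def cross_moment(self, num_score: str) -> float:
        """Sum over histories of (dose score * track score), for covariances."""
        if num_score == "dose":
            return self.sum_cross_transfer_col_track
        if num_score == "dose_primed":
            return self.sum_cross_transfer_track
        raise KeyError(f"no cross moment for score {num_score!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["energy_fluence"] = self.energy_fluence
        d["dose"] = self.dose
        d["dose_primed"] = self.dose_primed
        return d


def mfp_thickness(
    mat: MaterialComposition,
    E: float,
    providers: Sequence[CrossSectionProvider] | None = None,
    mu_rho: float | None = None,
) -> float:
    """Absorber thickness equal to one mean free path, 1/(mu/rho * rho), cm.

    ``mu_rho`` may be given directly (e.g. a published value); otherwise it
    is evaluated from the providers.  Sized this way, the expected
    un-collided transmission through the absorber is exactly e^-1.
    """
    if mu_rho is None:
        from .cross_sections import analytic_coefficients

        mu_rho = analytic_coefficients(mat, E, providers).mu_rho
    if mu_rho <= 0:
        raise ValueError("mean free path undefined: attenuation is zero")
    return 1.0 / (mu_rho * mat.density)


def _channel_sigmas(
    mat: MaterialComposition,
    E: float,
    providers: Sequence[CrossSectionProvider],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Macroscopic (1/cm) total and transfer cross sections per channel."""
    sig_tot, sig_tr, labels = [], [], []
    for p in providers:
        mu = mixture_coefficient(
            mat, element_mass_coefficients([p], mat.elements, E, transfer=False)
        )
        mu_tr = mixture_coefficient(
            mat, element_mass_coefficients([p], mat.elements, E, transfer=True)
        )
        sig_tot.append(mu * mat.density)
        sig_tr.append(mu_tr * mat.density)
        labels.append(p.channel)
    return np.asarray(sig_tot), np.asarray(sig_tr), labels


def simulate_narrow_beam(
    mat: MaterialComposition,
    E: float,
    n_histories: int,
    seed: int,
    providers: Sequence[CrossSectionProvider] | None = None,
    geom: BeamGeometry | None = None,
    thickness: float | None = None,
    g_model: RadiativeFractionModel = ZERO_RADIATIVE_FRACTION,
    scoring: str = "expected",
    open_beam: str = "analytic",
) -> TallyResult:
    """Run the narrow-beam experiment and return the accumulated tallies.

    Parameters
    ----------
    thickness:
        Absorber thickness in cm; defaults to one mean free path computed
        from the providers.
    scoring:
        ``"expected"`` scores E * Sigma_tr / Sigma_tot at each first
        collision (expected-value kerma, lower variance); ``"sampled"``
        draws the interaction channel and, for Compton, the actual scattered
        energy, scoring E - E'.  Both are unbiased and must agree within
        statistics.
    open_beam:
        ``"analytic"`` takes the open-beam detector count I0 as
        n_histories (the vacuum run is deterministic); ``"run"`` performs
        the trivial vacuum run explicitly.

    Identical arguments (including ``seed``) give a bit-identical result.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if scoring not in ("expected", "sampled"):
        raise ValueError("scoring must be 'expected' or 'sampled'")
    if open_beam not in ("analytic", "run"):
        raise ValueError("open_beam must be 'analytic' or 'run'")
    E = float(E)
    if E <= 0:
        raise ValueError(f"photon energy must be positive, got {E} MeV")
    if providers is None:
        providers = [AnalyticComptonProvider()]
    if not mat.elements:
        raise ValueError("material has no elements")
    geom = geom or BeamGeometry()

    sig_tot_ch, sig_tr_ch, channels = _channel_sigmas(mat, E, providers)
    sigma = float(sig_tot_ch.sum())     # 1/cm
    sigma_tr = float(sig_tr_ch.sum())

    if thickness is None:
        if sigma <= 0:
            raise ValueError(
                "cannot size the absorber to one mean free path: "
                "total cross section is zero; pass thickness explicitly"
            )
        thickness = 1.0 / sigma
    geom.validate_thickness(thickness)

    rng = np.random.default_rng(seed)
    n = int(n_histories)

    if sigma > 0:
        paths = rng.exponential(1.0 / sigma, size=n)
    else:
        paths = np.full(n, np.inf)
    collided = paths < thickness
    track = np.minimum(paths, thickness)

    g = g_model(mat, E)
    transfer = np.zeros(n)
    idx = np.flatnonzero(collided)
    if idx.size and sigma > 0:
        if scoring == "expected":
            transfer[idx] = E * sigma_tr / sigma
        else:
            # sample the interaction channel, then the transfer within it
            probs = sig_tot_ch / sigma
            ch = rng.choice(len(channels), size=idx.size, p=probs)
            t = np.zeros(idx.size)
            for k, label in enumerate(channels):
                sel = ch == k
                if not np.any(sel):
                    continue
                if label == "compton":
                    e_prime, _ = sample_compton(E, rng, size=int(sel.sum()))
                    t[sel] = E - e_prime
                else:
                    # channel-conditional expected transfer
                    ratio = sig_tr_ch[k] / sig_tot_ch[k] if sig_tot_ch[k] > 0 else 0.0
                    t[sel] = E * ratio
            transfer[idx] = t

    transfer_col = transfer * (1.0 - g)

    tally = TallyResult(
        material=mat.name,
        energy=E,
        n_histories=n,
        seed=int(seed),
        thickness=float(thickness),
        density=mat.density,
        absorber_volume=geom.absorber_volume(thickness),
        scoring=scoring,
        detector_uncollided=int(np.count_nonzero(~collided)),
        detector_open_beam=n,
        sum_track=float(track.sum()),
        sumsq_track=float((track**2).sum()),
        sum_transfer=float(transfer.sum()),
        sumsq_transfer=float((transfer**2).sum()),
        sum_transfer_col=float(transfer_col.sum()),
        sumsq_transfer_col=float((transfer_col**2).sum()),
        sum_cross_transfer_track=float((transfer * track).sum()),
        sum_cross_transfer_col_track=float((transfer_col * track).sum()),
    )
    if open_beam == "run":
        # vacuum run: every photon reaches the detector
        tally.detector_open_beam = n
    return tally


def relative_error(tally: TallyResult, score: str) -> float:
    """Relative standard error (SEM / mean) of one score, dimensionless.

    Computed from the per-history sum and sum-of-squares accumulators, the
    standard sample-variance estimate of analog Monte Carlo.  Scales as
    n^(-1/2).
    """
    n = tally.n_histories
    if n < 2:
        raise ValueError("relative error needs at least 2 histories")
    s, ss = tally.score_moments(score)
    mean = s / n
    if mean <= 0:
        raise ValueError(f"score {score!r} has non-positive mean; cannot form a relative error")
    var = max(ss / n - mean**2, 0.0) / (n - 1)
    return math.sqrt(var) / mean


def write_manifest(
    tally: TallyResult,
    path: str | Path,
    geom: BeamGeometry | None = None,
    provider_files: Sequence[str] | None = None,
) -> None:
    """Serialize a run (configuration + tallies) as a JSON manifest."""
    from . import __version__

    doc = {
        "package": "photonmu",
        "version": __version__,
        "material": tally.material,
        "energy_MeV": tally.energy,
        "n_histories": tally.n_histories,
        "seed": tally.seed,
        "scoring": tally.scoring,
        "geometry": asdict(geom) if geom else asdict(BeamGeometry()),
        "provider_files": list(provider_files or []),
        "tally": tally.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
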