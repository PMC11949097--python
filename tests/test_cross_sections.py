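"""Klein-Nishina physics, Compton sampling and the additivity rule.

The quadrature oracle here integrates the angle-differential Klein-Nishina
cross section with scipy, a parametrization independent of both the closed
forms and the eps-differential used by the sampler.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from photonmu import (
    AnalyticComptonProvider,
    CoefficientTriple,
    CrossSectionProvider,
    MaterialComposition,
    TabulatedProvider,
    TabulatedRadiativeFraction,
    ZERO_RADIATIVE_FRACTION,
    analytic_coefficients,
    electrons_per_gram,
    kn_differential,
    kn_total,
    kn_transfer,
    load_tissue,
    mixture_coefficient,
    sample_compton,
)
from photonmu.constants import (
    BARN_CM2,
    ELECTRON_REST_MEV,
    R_ELECTRON_CM,
    SIGMA_THOMSON_CM2,
)

GRID_28 = [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2,
           0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0,
           8.0, 10.0, 15.0, 20.0]


# --- independent oracle: integrate dsigma/dOmega over the polar angle -----
def _dsigma_dmu(cos_t: float, alpha: float) -> float:
    eps = 1.0 / (1.0 + alpha * (1.0 - cos_t))
    sin2 = 1.0 - cos_t**2
    return math.pi * R_ELECTRON_CM**2 * eps**2 * (eps + 1.0 / eps - sin2)


def oracle_total(E: float) -> float:
    a = E / ELECTRON_REST_MEV
    v, _ = quad(_dsigma_dmu, -1, 1, args=(a,), epsabs=0, epsrel=1e-11, limit=400)
    return v / BARN_CM2


def oracle_transfer(E: float) -> float:
    a = E / ELECTRON_REST_MEV

    def recoil_weighted(cos_t: float) -> float:
        eps = 1.0 / (1.0 + a * (1.0 - cos_t))
        return (1.0 - eps) * _dsigma_dmu(cos_t, a)

    v, _ = quad(recoil_weighted, -1, 1, epsabs=0, epsrel=1e-11, limit=400)
    return v / BARN_CM2


class TestKleinNishina:
    @pytest.mark.parametrize("E", GRID_28)
    def test_total_matches_quadrature_to_5_sig_figs(self, E):
        assert kn_total(E) == pytest.approx(oracle_total(E), rel=1e-5)

    @pytest.mark.parametrize("E", GRID_28)
    def test_transfer_matches_quadrature_to_5_sig_figs(self, E):
        assert kn_transfer(E) == pytest.approx(oracle_transfer(E), rel=1e-5)

    def test_thomson_limit(self):
        assert kn_total(1e-9) == pytest.approx(SIGMA_THOMSON_CM2 / BARN_CM2, rel=1e-8)
        assert kn_total(1e-9) == pytest.approx(0.66525, rel=1e-4)

    def test_reference_values(self):
        # frozen from the quadrature oracle
        assert kn_total(ELECTRON_REST_MEV) == pytest.approx(0.2865, rel=2e-4)
        assert kn_total(1.0) == pytest.approx(0.2112, rel=2e-4)
        assert kn_transfer(1.0) == pytest.approx(0.09294, rel=2e-4)
        assert kn_transfer(1.0) / kn_total(1.0) == pytest.approx(0.4400, rel=2e-4)
        assert kn_transfer(0.1) / kn_total(0.1) == pytest.approx(0.138, rel=2e-3)

    def test_total_strictly_decreasing(self):
        vals = [kn_total(E) for E in GRID_28]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_transfer_fraction_monotone_and_vanishes_at_low_energy(self):
        fracs = [kn_transfer(E) / kn_total(E) for E in GRID_28]
        assert all(b > a for a, b in zip(fracs, fracs[1:]))
        assert kn_transfer(1e-6) / kn_total(1e-6) < 1e-5

    @given(st.floats(1e-4, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_transfer_bounded_by_total(self, E):
        assert 0.0 < kn_transfer(E) < kn_total(E)

    @pytest.mark.parametrize("func", [kn_total, kn_transfer])
    def test_nonpositive_energy_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.0)
        with pytest.raises(ValueError):
            func(-1.0)


class TestComptonSampling:
    def test_kinematic_support(self):
        """E' stays within [E/(1+2a), E]; at alpha=1 the floor is E/3."""
        E = ELECTRON_REST_MEV  # alpha = 1
        rng = np.random.default_rng(7)
        e_prime, theta = sample_compton(E, rng, size=50_000)
        assert e_prime.min() >= E / 3.0 - 1e-12
        assert e_prime.max() <= E + 1e-12
        assert np.all((theta >= 0) & (theta <= np.pi))

    def test_energy_angle_consistency(self):
        E = 0.8
        a = E / ELECTRON_REST_MEV
        rng = np.random.default_rng(11)
        e_prime, theta = sample_compton(E, rng, size=10_000)
        predicted = E / (1.0 + a * (1.0 - np.cos(theta)))
        np.testing.assert_allclose(e_prime, predicted, rtol=1e-9)

    def test_mean_transferred_fraction_at_1mev(self):
        """Sampled mean of (E-E')/E matches sigma_tr/sigma within 3 SE."""
        E, n = 1.0, 1_000_000
        rng = np.random.default_rng(3)
        e_prime, _ = sample_compton(E, rng, size=n)
        frac = (E - e_prime) / E
        expected = kn_transfer(E) / kn_total(E)
        se = frac.std(ddof=1) / math.sqrt(n)
        assert abs(frac.mean() - expected) < 3 * se

    def test_histogram_matches_analytic_density(self):
        """50-bin chi-square of sampled E' against the Klein-Nishina density."""
        E, n = 0.5, 1_000_000
        a = E / ELECTRON_REST_MEV
        rng = np.random.default_rng(5)
        e_prime, _ = sample_compton(E, rng, size=n)
        eps = e_prime / E
        edges = np.linspace(1.0 / (1.0 + 2.0 * a), 1.0, 51)
        observed, _ = np.histogram(eps, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = kn_differential(E, centers)
        probs = dens * np.diff(edges)
        probs /= probs.sum()
        chi2 = float(((observed - n * probs) ** 2 / (n * probs)).sum())
        # 49 dof; p > 0.001
        assert chi2 < stats.chi2.ppf(0.999, df=49)

    def test_scalar_call(self):
        e_prime, theta = sample_compton(1.0, np.random.default_rng(0))
        assert isinstance(e_prime, float) and isinstance(theta, float)


class TestMixtureRule:
    def test_single_element_identity(self):
        mat = MaterialComposition("m", 1.0, {"O": 1.0})
        assert mixture_coefficient(mat, {"O": 0.123}) == 0.123

    def test_weighted_sum(self):
        mat = MaterialComposition("m", 1.0, {"H": 0.5, "O": 0.5})
        assert mixture_coefficient(mat, {"H": 0.1, "O": 0.3}) == pytest.approx(0.2)

    def test_missing_element_named(self):
        mat = MaterialComposition("m", 1.0, {"H": 0.5, "O": 0.5})
        with pytest.raises(KeyError, match="'O'"):
            mixture_coefficient(mat, {"H": 0.1})

    def test_water_from_elemental_values_near_reference(self, water):
        """H and O elemental Compton coefficients combine to the printed value."""
        from photonmu.cross_sections import element_mass_coefficients

        vals = element_mass_coefficients(
            [AnalyticComptonProvider()], ["H", "O"], 1.0
        )
        mu = mixture_coefficient(water, vals)
        assert mu == pytest.approx(0.07042, rel=0.005)

    @given(st.floats(0.05, 0.95), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_exact_linearity(self, f, v1, v2):
        mat = MaterialComposition("m", 1.0, {"H": f, "C": 1.0 - f})
        got = mixture_coefficient(mat, {"H": v1, "C": v2})
        assert got == pytest.approx(f * v1 + (1 - f) * v2, abs=1e-14)


class TestAnalyticCoefficients:
    def test_water_1mev_within_1pct_of_reference(self, water):
        tr = analytic_coefficients(water, 1.0)
        assert tr.mu_rho == pytest.approx(0.07042, rel=0.01)
        assert tr.mu_tr_rho == pytest.approx(0.03114, rel=0.01)
        assert tr.mu_en_rho == pytest.approx(0.03111, rel=0.01)

    def test_bone_1mev_within_1pct(self):
        tr = analytic_coefficients(load_tissue("bone-cortical"), 1.0)
        assert tr.mu_rho == pytest.approx(0.06539, rel=0.01)

    def test_ordering_invariant_with_radiative_fraction(self, water):
        g = TabulatedRadiativeFraction([0.01, 20.0], [0.02, 0.05])
        tr = analytic_coefficients(water, 2.0, g_model=g)
        assert tr.mu_rho >= tr.mu_tr_rho > tr.mu_en_rho > 0

    def test_equality_iff_zero_radiative_fraction(self, water):
        tr = analytic_coefficients(water, 2.0, g_model=ZERO_RADIATIVE_FRACTION)
        assert tr.mu_en_rho == tr.mu_tr_rho

    def test_all_zero_providers_give_zero_triple(self, water):
        zero = CrossSectionProvider(
            "photoelectric", lambda s, E: 0.0, lambda s, E: 0.0
        )
        tr = analytic_coefficients(water, 1.0, providers=[zero])
        assert (tr.mu_rho, tr.mu_tr_rho, tr.mu_en_rho) == (0.0, 0.0, 0.0)

    def test_no_providers_rejected(self, water):
        with pytest.raises(ValueError, match="provider"):
            analytic_coefficients(water, 1.0, providers=[])

    def test_compton_mu_scales_as_electron_density(self, water):
        """Same-energy Compton mu/rho ratio equals the electrons-per-gram ratio."""
        bone = load_tissue("bone-cortical")
        r_mu = (
            analytic_coefficients(bone, 1.0).mu_rho
            / analytic_coefficients(water, 1.0).mu_rho
        )
        r_ne = electrons_per_gram(bone) / electrons_per_gram(water)
        assert r_mu == pytest.approx(r_ne, rel=1e-12)

    @given(
        st.sampled_from(["Water", "Soft Tissue", "Bone (Cortical)", "Adipose Tissue"]),
        st.floats(0.01, 20.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_ordering_invariant_property(self, name, E):
        tr = analytic_coefficients(load_tissue(name), E)
        assert tr.mu_rho >= tr.mu_tr_rho >= tr.mu_en_rho >= 0


class TestTabulatedProvider:
    @pytest.fixture
    def csv_table(self, tmp_path):
        path = tmp_path / "O_pe.csv"
        path.write_text(
            "energy_MeV,sigma_cm2_per_atom,sigma_tr_cm2_per_atom\n"
            "0.01,1e-22,1e-22\n0.1,1e-24,9e-25\n1.0,1e-26,8e-27\n"
        )
        return path

    def test_loglog_interpolation(self, csv_table):
        prov = TabulatedProvider("photoelectric", {"O": csv_table})
        # halfway in log E between 0.01 and 0.1 -> halfway in log sigma
        mid = prov.provider.evaluate("O", math.sqrt(0.01 * 0.1))
        assert mid == pytest.approx(math.sqrt(1e-22 * 1e-24), rel=1e-9)

    def test_extrapolation_rejected(self, csv_table):
        prov = TabulatedProvider("photoelectric", {"O": csv_table})
        with pytest.raises(ValueError, match="extrapolation"):
            prov.provider.evaluate("O", 5.0)

    def test_pair_channel_zero_below_threshold(self, tmp_path):
        path = tmp_path / "O_pair.csv"
        path.write_text(
            "energy_MeV,sigma_cm2_per_atom,sigma_tr_cm2_per_atom\n"
            "1.022,0,0\n10,1e-25,9e-26\n20,2e-25,1.9e-25\n"
        )
        prov = TabulatedProvider("pair", {"O": path})
        assert prov.provider.evaluate("O", 0.5) == 0.0
        assert prov.provider.evaluate("O", 15.0) > 0.0

    def test_transfer_exceeding_total_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "energy_MeV,sigma_cm2_per_atom,sigma_tr_cm2_per_atom\n"
            "0.1,1e-24,2e-24\n1,1e-25,1e-26\n"
        )
        with pytest.raises(ValueError, match="sigma_tr"):
            TabulatedProvider("photoelectric", {"O": path})
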