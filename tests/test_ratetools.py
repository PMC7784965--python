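import numpy as np
import pytest

import matbgc as m
from matbgc.errors import FitQualityWarning, InvalidInputError
from matbgc.profiles import DepthProfile
from matbgc.ratetools import (
    GrossRateProfile,
    depth_integrate,
    gross_rate_lightdark,
    layer_balance,
    local_flux,
    select_zonation,
    volumetric_rates,
)
from matbgc.synth import add_noise

from conftest import sample_series

D_O2 = 1.78e-5
D_S = 1.35e-5


def two_zone_profile(r1=-0.3, r2=0.2, zi_cm=0.1, l_cm=0.2, c0=200.0, cl=150.0,
                     d=D_S, dz_cm=0.01):
    """Analytic steady profile with two constant-rate zones (independent of
    the inversion code: coefficients from matching value/slope at the
    interface and the Dirichlet ends)."""
    a = np.array([[1, 0, 0, 0], [0, 0, 1, l_cm], [1, zi_cm, -1, -zi_cm], [0, 1, 0, -1]])
    rhs = np.array([
        c0,
        cl + r2 / (2 * d) * l_cm**2,
        (r1 - r2) / (2 * d) * zi_cm**2,
        (r1 - r2) / d * zi_cm,
    ])
    a1, b1, a2, b2 = np.linalg.solve(a, rhs)
    z = np.arange(0, l_cm + 1e-12, dz_cm)
    c = np.where(
        z <= zi_cm,
        a1 + b1 * z - r1 / (2 * d) * z**2,
        a2 + b2 * z - r2 / (2 * d) * z**2,
    )
    return DepthProfile("S_tot", z * 10, c)


class TestLocalFlux:
    def test_linear_profile_unit_conversion(self):
        """Slope −100 µmol L⁻¹ mm⁻¹ with D_O2 gives J = +1.78e-2 nmol cm⁻² s⁻¹."""
        z = np.arange(0, 1.01, 0.1)
        p = DepthProfile("O2", z, 200.0 - 100.0 * z)
        est = local_flux(p, D_O2, (0.0, 1.0))
        assert est.j == pytest.approx(1.78e-2, rel=1e-9)

    def test_flat_profile_zero_flux(self):
        z = np.arange(0, 1.01, 0.1)
        p = DepthProfile("O2", z, np.full_like(z, 50.0))
        assert local_flux(p, D_O2, (0.0, 1.0)).j == 0.0

    def test_too_few_points_rejected(self):
        p = DepthProfile("O2", [0, 0.5, 1.0], [10, 8, 6])
        with pytest.raises(InvalidInputError):
            local_flux(p, D_O2, (0.0, 0.6))

    def test_curved_window_warns(self):
        z = np.arange(0, 1.01, 0.1)
        p = DepthProfile("O2", z, 100 + 50 * z**2)
        with pytest.warns(FitQualityWarning):
            local_flux(p, D_O2, (0.0, 1.0))

    def test_dbl_flux_recovers_imposed_boundary_flux(self, ap_recovery_downsampled):
        """Fick's-first-law flux in the linear water column matches the
        simulator's imposed boundary flux within 2%."""
        sc, res, ds = ap_recovery_downsampled
        est = local_flux(ds, sc.diffusion["S_tot"], (-1.0, 0.0))
        truth = res.truth.boundary_flux_top["S_tot"]
        assert est.j == pytest.approx(truth, rel=0.02)


class TestVolumetricRates:
    def test_parabola_closed_form(self):
        """C = C0 + a z² in one zone must invert to R = −2aD exactly."""
        a_mm = 10.0  # µmol L⁻¹ mm⁻²  (×100 converts to cm⁻²)
        z = np.arange(0, 2.001, 0.1)
        p = DepthProfile("S_tot", z, 300.0 + a_mm * z**2)
        fit = volumetric_rates(p, 1e-5, zones=1)
        assert fit.rates[0] == pytest.approx(-2 * a_mm * 100 * 1e-5, rel=1e-9)

    def test_linear_profile_zero_rates(self):
        z = np.arange(0, 2.001, 0.1)
        p = DepthProfile("S_tot", z, 300.0 - 50.0 * z)
        fit = volumetric_rates(p, 1e-5, zones=3)
        np.testing.assert_allclose(fit.rates, 0.0, atol=1e-10)

    def test_two_zone_exact_recovery(self):
        p = two_zone_profile()
        fit = volumetric_rates(p, D_S, zones=[0.0, 1.0, 2.0])
        np.testing.assert_allclose(fit.rates, [-0.3, 0.2], rtol=1e-8)

    def test_three_zone_simulator_recovery(self, ap_recovery_downsampled):
        """Noiseless forward–inverse loop: imposed consumption / zero /
        production rates recovered within 5% at 180 µm sampling."""
        sc, res, ds = ap_recovery_downsampled
        fit = volumetric_rates(
            ds.window(0.3, 5.0), sc.diffusion["S_tot"], zones=[0.3, 1.1, 3.0, 5.0]
        )
        assert fit.rates[0] == pytest.approx(-0.2, rel=0.05)
        assert abs(fit.rates[1]) < 0.05 * 0.2
        assert fit.rates[2] == pytest.approx(0.05, rel=0.05)

    def test_noisy_recovery_within_quarter(self, ap_recovery_downsampled):
        sc, res, ds = ap_recovery_downsampled
        noisy = add_noise(ds, 1.0, seed=42)
        fit = volumetric_rates(
            noisy.window(0.3, 5.0), sc.diffusion["S_tot"], zones=[0.3, 1.1, 3.0, 5.0]
        )
        assert fit.rates[0] == pytest.approx(-0.2, rel=0.25)
        assert abs(fit.rates[1]) < 0.25 * 0.2
        assert fit.rates[2] == pytest.approx(0.05, rel=0.25)

    def test_flux_conservation_identity(self):
        """∫R dz over the fit domain equals J(bottom) − J(top) of the fitted
        model (Fick's second law integrated once)."""
        p = two_zone_profile()
        fit = volumetric_rates(p, D_S, zones=[0.0, 1.0, 2.0])
        integral = fit.integrate()
        flux_diff = fit.flux_at(2.0) - fit.flux_at(0.0)
        assert integral == pytest.approx(flux_diff, rel=1e-8)

    def test_too_few_points_per_zone(self):
        p = DepthProfile("S_tot", [0, 0.5, 1.0, 1.5], [10, 9, 8, 7])
        with pytest.raises(InvalidInputError):
            volumetric_rates(p, D_S, zones=8)


class TestSelectZonation:
    def test_single_zone_truth(self):
        z = np.arange(0, 2.001, 0.1)
        p = DepthProfile("S_tot", z, 300.0 + 10.0 * z**2)
        fit = select_zonation(p, 1e-5, max_zones=3)
        assert len(fit.rates) == 1

    def test_two_zone_truth_with_contrast(self):
        p = two_zone_profile()
        fit = select_zonation(p, D_S, max_zones=4, max_candidates=50)
        assert len(fit.rates) == 2
        assert abs(fit.boundaries_mm[1] - 1.0) <= 0.1  # within one grid step
        np.testing.assert_allclose(fit.rates, [-0.3, 0.2], rtol=1e-6)

    def test_noisy_two_zone(self):
        rng = np.random.default_rng(7)
        p = two_zone_profile()
        noisy = DepthProfile(
            "S_tot", p.depths, p.values + rng.normal(0, 0.5, p.values.shape)
        )
        fit = select_zonation(noisy, D_S, max_zones=4, max_candidates=50)
        assert len(fit.rates) == 2
        assert abs(fit.boundaries_mm[1] - 1.0) <= 0.1

    def test_flat_noise_only(self):
        rng = np.random.default_rng(11)
        z = np.arange(0, 2.001, 0.1)
        p = DepthProfile("S_tot", z, 100.0 + rng.normal(0, 0.5, z.shape))
        fit = select_zonation(p, 1e-5, max_zones=3)
        assert len(fit.rates) == 1
        assert abs(fit.rates[0]) < 0.005


class TestLayerBalance:
    def test_linear_profile_balances_to_zero(self):
        z = np.arange(-1.0, 3.01, 0.1)
        p = DepthProfile("S_tot", z, 300.0 - 50.0 * z)
        assert layer_balance(p, D_S, (0.3, 1.1)) == pytest.approx(0.0, abs=1e-12)

    def test_ap_layer_consumption_recovered(self, ap_recovery_downsampled):
        """Flux difference across the cyanobacterial layer equals the imposed
        areal AP (light-driven sulfide consumption) within 3%."""
        sc, res, ds = ap_recovery_downsampled
        bal = layer_balance(ds, sc.diffusion["S_tot"], (0.3, 1.1))
        imposed = -(
            res.truth.zone_areal["S_tot"]["cyano_upper"]
            + res.truth.zone_areal["S_tot"]["cyano_lower"]
        )
        assert bal == pytest.approx(imposed, rel=0.03)

    def test_production_zone_diverging_fluxes(self, ap_recovery_downsampled):
        """Within-mat sulfide production = |upward flux| + |downward flux|
        around the production zone, matching the imposed source within 3%."""
        sc, res, ds = ap_recovery_downsampled
        d = sc.diffusion["S_tot"]
        j_up = local_flux(ds, d, (3.0 - 0.9, 3.0))
        j_down = local_flux(ds, d, (5.0, 5.9))
        assert j_up.j < 0 and j_down.j > 0  # diverging away from the source
        production = abs(j_up.j) + abs(j_down.j)
        imposed = res.truth.zone_areal["S_tot"]["production_zone"]
        assert production == pytest.approx(imposed, rel=0.03)
        # identical to -layer_balance as net production
        bal = layer_balance(ds, d, (3.0, 5.0))
        assert -bal == pytest.approx(production, rel=1e-9)


class TestGrossRateLightDark:
    def test_exact_slope(self):
        t = np.arange(0, 5.01, 0.5)
        assert gross_rate_lightdark(t, 100 - 2.0 * t, mode="OP") == pytest.approx(2.0)

    def test_constant_series_zero(self):
        t = np.arange(0, 5.01, 0.5)
        assert gross_rate_lightdark(t, np.full_like(t, 7.0), mode="AP") == 0.0

    def test_window_exceeding_series_rejected(self):
        t = np.arange(0, 2.01, 0.5)
        with pytest.raises(InvalidInputError):
            gross_rate_lightdark(t, t, window_s=10.0)

    @pytest.mark.parametrize(
        "solute,mode,imposed", [("O2", "OP", 0.5), ("S_tot", "AP", 0.05)]
    )
    def test_simulated_transient_recovery(self, op_lightdark, solute, mode, imposed):
        """Imposed gross rate recovered within 10% at 0.5 s sampling and a
        3 s fit window, at a mid-photic depth."""
        sc, ld = op_lightdark
        t, v = ld.series(solute, 0.7)
        ts, vs = sample_series(t, v, 0.5)
        g = gross_rate_lightdark(ts, vs, window_s=3.0, mode=mode)
        assert g == pytest.approx(imposed, rel=0.10)

    def test_underestimate_grows_with_window(self, op_lightdark):
        """Diffusive relaxation makes longer fit windows underestimate the
        gross rate — monotonically."""
        sc, ld = op_lightdark
        t, v = ld.series("O2", 0.35)  # near the zone edge: fast relaxation
        ts, vs = sample_series(t, v, 0.5)
        gs = [
            gross_rate_lightdark(ts, vs, window_s=w, mode="OP")
            for w in (2.0, 4.0, 8.0, 14.0)
        ]
        assert all(np.diff(gs) <= 1e-12)
        assert gs[-1] < gs[0] < 0.5 + 1e-9


class TestDepthIntegrate:
    def test_constant_rate_over_1mm(self):
        g = GrossRateProfile([0.0, 0.5, 1.0], [1.0, 1.0, 1.0], mode="OP")
        assert depth_integrate(g) == pytest.approx(0.1)

    def test_zero_rates(self):
        g = GrossRateProfile([0.0, 0.5, 1.0], [0.0, 0.0, 0.0], mode="AP")
        assert depth_integrate(g) == 0.0

    def test_subinterval(self):
        g = GrossRateProfile([0.0, 1.0, 2.0], [2.0, 2.0, 2.0], mode="OP")
        assert depth_integrate(g, (0.5, 1.5)) == pytest.approx(0.2)

    def test_rate_profile_integral_equals_flux_difference(self):
        p = two_zone_profile()
        fit = volumetric_rates(p, D_S, zones=[0.0, 1.0, 2.0])
        assert depth_integrate(fit) == pytest.approx(
            fit.flux_at(2.0) - fit.flux_at(0.0), abs=1e-10
        )

    def test_empty_interval_rejected(self):
        g = GrossRateProfile([0.0, 1.0], [1.0, 1.0], mode="OP")
        with pytest.raises(InvalidInputError):
            depth_integrate(g, (1.0, 1.0))
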