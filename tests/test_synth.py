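import numpy as np
import pytest

import matbgc as m
from matbgc.errors import InvalidInputError
from matbgc.profiles import DepthProfile
from matbgc.sip import SIPSeries
from matbgc.synth import (
    Layer,
    MatScenario,
    add_noise,
    apply_sob_migration_rule,
    downsample_profile,
    get_scenario,
    simulate_diel_sip,
    simulate_lightdark,
    solve_steady_state,
)


def simple_scenario(rates_a=0.0, rates_b=0.0, grid=0.05, photo_a=0.0):
    return MatScenario(
        name="simple",
        layers=[
            Layer("A", 1.0, rates={"S_tot": rates_a},
                  photo_rates={"S_tot": photo_a}),
            Layer("B", 1.0, rates={"S_tot": rates_b}),
        ],
        top_bc={"S_tot": 200.0},
        bottom_bc={"S_tot": 100.0},
        grid_mm=grid,
    )


class TestSteadySolver:
    def test_no_reaction_gives_linear_profile(self):
        res = solve_steady_state(simple_scenario())
        c = res.concentrations["S_tot"]
        np.testing.assert_allclose(c, np.linspace(200, 100, len(c)), rtol=1e-12)

    def test_uniform_consumption_parabolic_curvature(self):
        """A single uniform zone yields a parabola whose interior curvature
        matches C″ = −R/D to 1e-10."""
        r = -0.05
        sc = MatScenario(
            name="one",
            layers=[Layer("A", 2.0, rates={"S_tot": r})],
            top_bc={"S_tot": 300.0},
            bottom_bc={"S_tot": 200.0},
            grid_mm=0.05,
        )
        res = solve_steady_state(sc)
        c = res.concentrations["S_tot"]
        h_cm = 0.005
        curv = (c[:-2] - 2 * c[1:-1] + c[2:]) / h_cm**2
        np.testing.assert_allclose(
            curv, -r / sc.diffusion["S_tot"], rtol=1e-10
        )

    def test_exact_on_piecewise_quadratic(self):
        """The scheme (with averaged rates at interface nodes) reproduces the
        analytic two-zone solution to rounding, at every grid."""
        d = 1.35e-5
        r1, r2, zi, l = -0.3, 0.2, 0.1, 0.2
        c0, cl = 200.0, 150.0
        a = np.array([[1, 0, 0, 0], [0, 0, 1, l], [1, zi, -1, -zi], [0, 1, 0, -1]])
        rhs = np.array([
            c0, cl + r2 / (2 * d) * l**2,
            (r1 - r2) / (2 * d) * zi**2, (r1 - r2) / d * zi,
        ])
        a1, b1, a2, b2 = np.linalg.solve(a, rhs)

        def analytic(zcm):
            return np.where(
                zcm <= zi,
                a1 + b1 * zcm - r1 / (2 * d) * zcm**2,
                a2 + b2 * zcm - r2 / (2 * d) * zcm**2,
            )

        for grid in (0.05, 0.025):
            sc = MatScenario(
                name="two",
                layers=[
                    Layer("A", 1.0, rates={"S_tot": r1}),
                    Layer("B", 1.0, rates={"S_tot": r2}),
                ],
                top_bc={"S_tot": c0},
                bottom_bc={"S_tot": cl},
                grid_mm=grid,
            )
            res = solve_steady_state(sc)
            z_cm = (sc.grid() - sc.grid()[0]) * 0.1
            err = np.max(np.abs(res.concentrations["S_tot"] - analytic(z_cm)))
            assert err < 1e-9

    def test_flux_conservation_all_presets(self, library):
        """∫R dz equals the boundary-flux difference within 1e-8 relative
        for every steady preset simulation."""
        for name in ("dark", "low_light_ap", "op_sob_below", "dcmu", "ap_recovery"):
            res = solve_steady_state(library[name])
            t = res.truth
            for sol in res.concentrations:
                lhs = t.areal_total[sol]
                rhs = t.boundary_flux_bottom[sol] - t.boundary_flux_top[sol]
                scale = max(abs(lhs), abs(t.boundary_flux_top[sol]), 1e-9)
                assert abs(lhs - rhs) <= 1e-8 * scale, (name, sol)

    def test_overconsumption_rejected(self):
        sc = simple_scenario(rates_a=-5.0)
        with pytest.raises(InvalidInputError):
            solve_steady_state(sc)

    def test_grid_coarser_than_thinnest_layer_rejected(self):
        with pytest.raises(InvalidInputError):
            MatScenario(
                name="bad",
                layers=[Layer("A", 0.1), Layer("B", 2.0)],
                top_bc={"S_tot": 1.0},
                bottom_bc={"S_tot": 0.0},
                grid_mm=0.05,
            )


class TestLightDark:
    def test_no_photo_term_constant_fields(self):
        sc = simple_scenario(rates_a=0.0)
        ld = simulate_lightdark(sc, duration_s=5.0, dt_s=0.1)
        f = ld.fields["S_tot"]
        np.testing.assert_allclose(f[-1], f[0], atol=1e-9)

    def test_initial_decay_rate_equals_photo_term(self):
        """At t just after darkening, dC/dt at depth equals minus the imposed
        photosynthetic rate (diffusion is still balanced) within 2%."""
        sc = simple_scenario(photo_a=-0.1)  # AP: sulfide consumption in light
        ld = simulate_lightdark(sc, duration_s=2.0, dt_s=0.05)
        t, v = ld.series("S_tot", 0.5)
        slope = (v[1] - v[0]) / (t[1] - t[0])
        assert slope == pytest.approx(0.1, rel=0.02)  # S_tot rises at |AP|

    def test_converges_to_dark_steady_state(self, library):
        """As t → ∞ the transient approaches the photo-off steady solution."""
        sc = library["low_light_ap"]
        steady_off = solve_steady_state(sc, include_photo=False)
        ld = simulate_lightdark(sc, duration_s=80000.0, dt_s=50.0)
        for sol in ld.fields:
            diff = np.max(
                np.abs(ld.fields[sol][-1] - steady_off.concentrations[sol])
            )
            assert diff < 1e-6, sol

    def test_invalid_stepping_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_lightdark(simple_scenario(), duration_s=0.0)


class TestDielSIP:
    def test_zero_fixation_flat_labeling(self):
        from matbgc.synth import DielSIPScenario, Phase

        sc = DielSIPScenario(
            name="null",
            phases=[Phase("dark", 0.0, 8.0, light=0.0, mode="dark", cfix_flux=0.0)],
        )
        res = simulate_diel_sip(sc)
        mat = res.series["mat_bulk"].values
        np.testing.assert_allclose(mat, mat[0])

    def test_doc_strictly_increasing_during_op(self, diel_sip_result):
        doc = diel_sip_result.series["DOC"]
        t = doc.times_h
        op = diel_sip_result.truth.phase_intervals["op_high"]
        inside = (t > op[0]) & (t <= op[1])
        assert np.all(np.diff(doc.values[inside]) > 0)
        before = t <= op[0]
        np.testing.assert_allclose(doc.values[before], 1.0)

    def test_replicate_noise_reproducible(self, library):
        from dataclasses import replace

        sc = replace(library["diel_sip"], noise_sigma_delta=2.0, seed=123)
        a = simulate_diel_sip(sc)
        b = simulate_diel_sip(sc)
        np.testing.assert_array_equal(
            a.series["FA:C17:0"].values, b.series["FA:C17:0"].values
        )


class TestNoise:
    def test_sigma_zero_identity(self, ap_recovery_solution):
        _, res = ap_recovery_solution
        p = res.profiles.s_tot
        q = add_noise(p, 0.0, seed=1)
        np.testing.assert_array_equal(q.values, p.values)

    def test_same_seed_reproducible(self, ap_recovery_solution):
        _, res = ap_recovery_solution
        p = res.profiles.s_tot
        a = add_noise(p, 1.0, seed=5)
        b = add_noise(p, 1.0, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sample_sd_matches_sigma(self):
        t = np.arange(1000.0)
        s = SIPSeries("DOC", t, np.full_like(t, 50.0), scale="delta")
        noisy = add_noise(s, 2.0, seed=9)
        sd = np.std(noisy.values - s.values)
        assert sd == pytest.approx(2.0, rel=0.10)

    def test_negative_sigma_rejected(self):
        s = SIPSeries("DOC", [0.0, 1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            add_noise(s, -1.0, seed=0)


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path):
        import matbgc

        cfg = (
            "name: from_yaml\n"
            "grid_mm: 0.05\n"
            "top_bc: {S_tot: 200.0}\n"
            "bottom_bc: {S_tot: 100.0}\n"
            "layers:\n"
            "  - {name: A, thickness_mm: 1.0, rates: {S_tot: -0.1}}\n"
            "  - {name: B, thickness_mm: 1.0}\n"
        )
        path = tmp_path / "scenario.yaml"
        path.write_text(cfg)
        sc = matbgc.load_scenario(path)
        assert isinstance(sc, MatScenario)
        res = solve_steady_state(sc)
        assert res.truth.zone_rates["S_tot"]["A"] == -0.1

    def test_diel_config_from_dict(self):
        import matbgc

        sc = matbgc.load_scenario({
            "name": "d",
            "phases": [
                {"name": "dark", "t_start_h": 0.0, "t_end_h": 4.0,
                 "light": 0.0, "mode": "dark", "cfix_flux": 0.5},
            ],
        })
        res = simulate_diel_sip(sc)
        assert "mat_bulk" in res.series

    def test_bad_config_rejected(self):
        import matbgc

        with pytest.raises(InvalidInputError):
            matbgc.load_scenario({"name": "x"})


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidInputError):
            get_scenario("nope")

    def test_dark_regime_shapes(self, library):
        """Dark: O₂ confined near the surface; S_tot maximum at depth."""
        res = solve_steady_state(library["dark"])
        sc = library["dark"]
        z = sc.grid()
        o2 = res.concentrations["O2"]
        stot = res.concentrations["S_tot"]
        assert np.interp(1.0, z, o2) < 0.2 * res.scenario.top_bc["O2"]
        assert np.all(o2[z > 2.0] < 1.0)
        assert z[np.argmax(stot)] > 2.0

    def test_op_regime_o2_peak_in_cyano_layer(self, library):
        res = solve_steady_state(library["op_sob_below"])
        z = library["op_sob_below"].grid()
        o2 = res.concentrations["O2"]
        peak_depth = z[np.argmax(o2)]
        assert 0.3 <= peak_depth <= 1.1
        assert o2.max() > res.scenario.top_bc["O2"]

    def test_dcmu_regime_shallow_o2(self, library):
        """With oxygenic photosynthesis inhibited, O₂ barely enters the mat."""
        res = solve_steady_state(library["dcmu"])
        z = library["dcmu"].grid()
        o2 = res.concentrations["O2"]
        assert np.all(o2[z > 0.6] < 1.0)
        # and no O2 source anywhere: maximum at the top boundary
        assert np.argmax(o2) == 0

    def test_downsampling_spacings(self, ap_recovery_solution):
        _, res = ap_recovery_solution
        ds = downsample_profile(res.profiles.s_tot)
        steps = np.diff(ds.depths)
        mat = ds.depths[:-1] >= 0.1
        assert np.allclose(steps[mat], 0.18, atol=0.03)

    def test_migration_rule_triggers_outside_window(self, library):
        from dataclasses import replace

        sc = library["dark"]
        names = [l.name for l in sc.layers]
        surf = sc.layers[names.index("sob_layer")]
        # Stot:O2 ratio inside the window -> no migration
        _, moved = apply_sob_migration_rule(sc)
        assert not moved
        # skew the surface stoichiometry far outside [2/3, 2.5] -> migrate
        skew_layers = list(sc.layers)
        skew_layers[names.index("sob_layer")] = replace(
            surf, rates={"S_tot": -0.09, "O2": -0.005}
        )
        skew = replace(sc, layers=skew_layers)
        moved_sc, moved = apply_sob_migration_rule(skew)
        assert moved
        new_names = {l.name: l for l in moved_sc.layers}
        assert new_names["sob_layer"].rates == {}
        assert new_names["sob_below"].rates["S_tot"] == -0.09
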