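"""Wall stresses, stress-stretch curve assembly, and tangent moduli."""

import numpy as np
import pandas as pd
import pytest

from arterymech.constitutive import stress_derivatives
from arterymech.geometry import (
    DegenerateGeometryError,
    DeformedGeometry,
    UnloadedGeometry,
    loaded_geometry,
)
from arterymech.mechanics import (
    StressStretchCurve,
    axial_stress,
    build_stress_stretch,
    circumferential_stress,
    tangent_modulus,
)
from arterymech.simulate import (
    equilibrium_circ_stretch,
    simulate_force_length_test,
    simulate_pressure_sweep,
)

GEOM = DeformedGeometry(
    r_o=210.0, r_i=188.757, h=21.243, lambda_z=1.7, lambda_theta=1.1077
)


class TestStressFormulas:
    def test_unloaded_stresses_vanish(self):
        assert circumferential_stress(0.0, GEOM) == 0.0
        assert axial_stress(0.0, 0.0, GEOM) == 0.0

    def test_hand_evaluated_hoop_stress(self):
        """sigma_theta = P r_i / h with 1 mmHg = 0.133322 kPa."""
        expected = 100.0 * 0.133322 * 188.757 / 21.243
        assert circumferential_stress(100.0, GEOM) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(118.5, abs=0.05)

    def test_hoop_stress_inverse_in_thickness(self):
        thick = DeformedGeometry(
            r_o=GEOM.r_i + 2 * GEOM.h, r_i=GEOM.r_i, h=2 * GEOM.h,
            lambda_z=1.7, lambda_theta=1.1,
        )
        assert circumferential_stress(100.0, thick) == pytest.approx(
            circumferential_stress(100.0, GEOM) / 2.0, rel=1e-12
        )

    def test_hand_evaluated_axial_stress(self):
        """Capped-tube free body: sigma_z = (f + P pi r_i^2)/(pi h (2 r_i + h))."""
        p_kpa = 100.0 * 0.133322
        expected = (2.0e6 + p_kpa * np.pi * 188.757**2) / (
            np.pi * 21.243 * (2 * 188.757 + 21.243)
        )
        got = axial_stress(2.0, 100.0, GEOM)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(131.0, abs=0.5)

    def test_midwall_lame_solution_agrees_within_thinness_ratio(self):
        """The mean Laplace hoop stress agrees with the thick-wall Lame
        stress evaluated at mid-radius to within O(h/r_i)."""
        p_kpa = 100.0 * 0.133322
        r_i, r_o = GEOM.r_i, GEOM.r_o
        r_m = 0.5 * (r_i + r_o)
        lame = p_kpa * r_i**2 * (r_o**2 + r_m**2) / (r_m**2 * (r_o**2 - r_i**2))
        laplace = circumferential_stress(100.0, GEOM)
        assert abs(laplace - lame) / lame < GEOM.h / GEOM.r_i

    def test_unit_invariance_um_vs_mm(self, rng):
        """Expressing the geometry in mm instead of um changes no stress."""
        for _ in range(20):
            r_i = rng.uniform(100.0, 300.0)
            h = rng.uniform(10.0, 60.0)
            p = rng.uniform(1.0, 150.0)
            f = rng.uniform(0.1, 8.0)
            g_um = DeformedGeometry(r_i + h, r_i, h, 1.7, 1.2)
            g_mm = DeformedGeometry(
                (r_i + h) / 1000.0, r_i / 1000.0, h / 1000.0, 1.7, 1.2
            )
            assert circumferential_stress(p, g_um) == pytest.approx(
                circumferential_stress(p, g_mm), rel=1e-12
            )
            assert axial_stress(f, p, g_um, geometry_unit="um") == pytest.approx(
                axial_stress(f, p, g_mm, geometry_unit="mm"), rel=1e-12
            )

    def test_simulator_round_trip_axial_stress(self, wt_artery):
        """sigma_z recovered from simulated (f, P, OD) equals the analytic
        stress function to 1e-6 relative."""
        sweep = simulate_pressure_sweep(wt_artery, wt_artery.ivs_true)
        lz = wt_artery.ivs_true
        lt = equilibrium_circ_stretch(
            wt_artery.params, wt_artery.unloaded, sweep.pressure_mmhg,
            np.full(sweep.pressure_mmhg.shape, lz),
        )
        _, sz_true = wt_artery.stress_fn(lt, lz)
        for k in range(sweep.pressure_mmhg.size):
            g = loaded_geometry(wt_artery.unloaded, sweep.outer_diameter_um[k], lz)
            sz = axial_stress(sweep.force_mn[k], sweep.pressure_mmhg[k], g)
            assert sz == pytest.approx(sz_true[k], rel=1e-6)


def _sample_frame(artery, axial_pressure=90.0):
    rows = []
    sweep = simulate_pressure_sweep(artery, artery.ivs_true)
    for k in range(sweep.pressure_mmhg.size):
        rows.append(
            dict(test_type="pressure_sweep", pressure_mmHg=sweep.pressure_mmhg[k],
                 axial_stretch=sweep.axial_stretch,
                 outer_diameter_um=sweep.outer_diameter_um[k],
                 force_mN=sweep.force_mn[k])
        )
    for c in simulate_force_length_test(artery, [axial_pressure]):
        for k in range(c.lambda_z.size):
            rows.append(
                dict(test_type="force_length", pressure_mmHg=c.pressure_mmhg,
                     axial_stretch=c.lambda_z[k],
                     outer_diameter_um=c.outer_diameter_um[k],
                     force_mN=c.force_mn[k])
            )
    return pd.DataFrame(rows)


class TestBuildStressStretch:
    def test_circumferential_curve_has_one_point_per_sweep_step(self, wt_artery):
        df = _sample_frame(wt_artery)
        curve = build_stress_stretch(df, wt_artery.unloaded, "circumferential")
        assert len(curve) == 15
        assert np.all(np.diff(curve.stretch) > 0)

    @pytest.mark.parametrize("context", [90.0, 80.0])
    def test_axial_curve_at_context_pressure(self, wt_artery, context):
        df = _sample_frame(wt_artery, axial_pressure=context)
        curve = build_stress_stretch(
            df, wt_artery.unloaded, "axial", context_pressure_mmhg=context
        )
        assert curve.context_pressure_mmhg == context
        assert len(curve) == 9

    def test_missing_context_pressure_fails(self, wt_artery):
        df = _sample_frame(wt_artery, axial_pressure=90.0)
        with pytest.raises(ValueError, match="80"):
            build_stress_stretch(
                df, wt_artery.unloaded, "axial", context_pressure_mmhg=80.0
            )

    def test_stiffer_artery_curve_is_left_shifted(self, wt_artery, stiff_artery):
        """At matched stress level the stiffer vessel sits at smaller
        circumferential stretch."""
        cw = build_stress_stretch(
            _sample_frame(wt_artery), wt_artery.unloaded, "circumferential"
        )
        cs = build_stress_stretch(
            _sample_frame(stiff_artery), stiff_artery.unloaded, "circumferential"
        )
        for level in (50.0, 100.0, 200.0):
            lw = np.interp(level, cw.stress_kpa, cw.stretch)
            ls = np.interp(level, cs.stress_kpa, cs.stretch)
            assert ls < lw


class TestTangentModulus:
    def test_exactly_linear_curve_returns_slope_everywhere(self):
        x = np.linspace(1.0, 1.5, 11)
        curve = StressStretchCurve("axial", x, 3.0 + 42.0 * x)
        for method in ("window", "central"):
            tan = tangent_modulus(curve, method=method)
            np.testing.assert_allclose(tan.e_tan_kpa, 42.0, rtol=1e-10)

    def test_convex_curve_gives_nondecreasing_modulus(self):
        x = np.linspace(1.0, 1.6, 25)
        curve = StressStretchCurve("axial", x, np.exp(3.0 * x))
        tan = tangent_modulus(curve)
        # end points share the one-sided window of their neighbours, so the
        # sequence is nondecreasing rather than strictly increasing there
        assert np.all(np.diff(tan.e_tan_kpa) >= -1e-9)
        interior = tan.e_tan_kpa[2:-2]
        assert np.all(np.diff(interior) > 0)

    def test_matches_analytic_derivative_on_dense_sweep(self, wt_artery):
        """Windowed slope of a densely sampled noiseless circumferential
        curve matches the analytic dsigma/dlambda within 2% (interior)."""
        sweep = simulate_pressure_sweep(wt_artery, wt_artery.ivs_true, 0, 140, 0.5)
        lts, sts = [], []
        for p, od in zip(sweep.pressure_mmhg, sweep.outer_diameter_um):
            g = loaded_geometry(wt_artery.unloaded, od, wt_artery.ivs_true)
            lts.append(g.lambda_theta)
            sts.append(circumferential_stress(p, g))
        curve = StressStretchCurve("circumferential", np.array(lts), np.array(sts))
        tan = tangent_modulus(curve)
        d_t, _ = stress_derivatives(wt_artery.params, tan.stretch, wt_artery.ivs_true)
        rel = np.abs(tan.e_tan_kpa - d_t) / np.abs(d_t)
        assert rel[2:-2].max() < 0.02

    def test_reindexing_and_reversal_invariance(self):
        x = np.linspace(1.0, 1.6, 15)
        y = np.exp(2.0 * x)
        a = tangent_modulus(StressStretchCurve("axial", x, y))
        b = tangent_modulus(StressStretchCurve("axial", x[::-1], y[::-1]))
        np.testing.assert_allclose(a.e_tan_kpa, b.e_tan_kpa, rtol=1e-12)

    def test_window_shrinks_with_warning(self):
        x = np.linspace(1.0, 1.2, 4)
        curve = StressStretchCurve("axial", x, x**2)
        with pytest.warns(UserWarning, match="window"):
            tangent_modulus(curve, window=7)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tangent_modulus(
                StressStretchCurve("axial", np.array([1.0, 1.1]), np.array([0.0, 1.0]))
            )

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            DeformedGeometry(r_o=100.0, r_i=100.0, h=0.0, lambda_z=1.0, lambda_theta=1.0)
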