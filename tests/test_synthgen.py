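"""Synthetic generator: patterns, spreading kinetics, surfaces, I-z stacks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from platelab.core import GeometryError
from platelab.morpho import measure_mask
from platelab.synthgen import (
    PatternSpec,
    SICMSimParams,
    SpreadingParams,
    calibrate_tau,
    deformation,
    dz_def_closed_form,
    gap_from_distance,
    generate_pattern,
    generate_sicm_cohort,
    geometry_factor,
    logistic_area,
    measured_interval,
    sicm_defaults,
    simulate_iz_stack,
    simulate_spreading_sequence,
    spreading_defaults,
    surface_defaults,
    synthesize_platelet_surface,
    thickness_factor,
    trigger_gap,
    draw_spreading_params,
)


class TestPattern:
    def test_covered_fraction_on_large_field(self):
        spec = PatternSpec(field_size=(150.0, 150.0), pixel_size=0.2)
        pat = generate_pattern(spec)
        # one pixel row of quantization over 10 periods
        assert pat.covered_fraction == pytest.approx(4.0 / 15.0, abs=0.2 / 15.0)

    def test_near_full_coverage_degenerate(self):
        spec = PatternSpec(line_width=14.99, period=15.0, field_size=(60, 60), pixel_size=0.2)
        assert generate_pattern(spec).covered_fraction > 0.98  # one-pixel quantization

    def test_orientation_90_transposes_orientation_0(self):
        s0 = PatternSpec(field_size=(30, 30), pixel_size=0.1, orientation=0.0)
        s90 = PatternSpec(field_size=(30, 30), pixel_size=0.1, orientation=90.0)
        assert np.array_equal(generate_pattern(s90).mask, generate_pattern(s0).mask.T)

    def test_field_smaller_than_period_rejected(self):
        with pytest.raises(GeometryError):
            generate_pattern(PatternSpec(field_size=(10.0, 10.0)))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec(line_width=16.0, period=15.0)


class TestLogisticKinetics:
    def test_quantile_spacing_closed_form_vs_dense_evaluation(self):
        # untruncated logistic: t75 - t25 = 2 ln(3) tau
        tau = 1.0
        t = np.linspace(-60, 140, 400001)
        a = logistic_area(t, 5.0, 30.0, 40.0, tau)
        norm = (a - 5.0) / 25.0
        t25 = np.interp(0.25, norm, t)
        t75 = np.interp(0.75, norm, t)
        assert t75 - t25 == pytest.approx(2 * math.log(3) * tau, abs=1e-3)
        assert t75 - t25 == pytest.approx(2.197, abs=1e-3)

    def test_tau_to_zero_step_growth_interval_vanishes(self):
        assert measured_interval(1e-6, 20.0, 40.0) < 1e-4

    @pytest.mark.parametrize("target,t_half", [(15.0, 12.0), (8.7, 10.0), (5.0, 8.0)])
    def test_calibrated_tau_reproduces_target_interval(self, target, t_half):
        tau, th = calibrate_tau(target, t_half, 40.0)
        assert measured_interval(tau, th, 40.0) == pytest.approx(target, abs=1e-6)
        assert th + 3 * tau <= 40.0 + 1e-9

    def test_params_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpreadingParams(condition="confined", a0=10.0, af=15.0)  # Af < 2 A0
        with pytest.raises(ValueError):
            SpreadingParams(condition="control", tau=12.0, t_half=20.0, duration=40.0)


class TestSpreadingSequence:
    def test_confined_minor_plateaus_at_line_width(self, default_pattern, rng):
        spec = spreading_defaults("confined")
        params = draw_spreading_params(spec, default_pattern, rng)
        seq, truth = simulate_spreading_sequence(default_pattern, params)
        # ground-truth minor axis saturates at the 4-um line width within
        # ~5 min of onset and stays there
        assert truth.minor_plateau == pytest.approx(4.0, abs=0.01)
        t_after = truth.t_min >= truth.t0 + 7.0
        assert np.all(truth.minor[t_after] == pytest.approx(4.0, abs=0.05))

    def test_rasterized_area_tracks_analytic_area(self, default_pattern, rng):
        spec = spreading_defaults("control")
        params = draw_spreading_params(spec, default_pattern, rng)
        seq, truth = simulate_spreading_sequence(default_pattern, params)
        areas = seq.masks.sum(axis=(1, 2)) * seq.pixel_size**2
        big = truth.area >= 5.0
        assert np.allclose(areas[big], truth.area[big], rtol=0.02)

    def test_measured_axes_match_ground_truth_within_3pct(self, default_pattern, rng):
        spec = spreading_defaults("confined")
        params = draw_spreading_params(spec, default_pattern, rng)
        seq, truth = simulate_spreading_sequence(default_pattern, params)
        for k in [40, 80, 160]:  # areas >= 10 um^2 territory
            if truth.area[k] < 10.0:
                continue
            m = measure_mask(seq.masks[k], seq.pixel_size)
            assert m.major_axis == pytest.approx(truth.major[k], rel=0.03)
            assert m.minor_axis == pytest.approx(truth.minor[k], rel=0.03)

    def test_oversized_ellipse_rejected(self, default_pattern):
        params = SpreadingParams(
            condition="control", a0=90.0, af=900.0, tau=4.0, t_half=10.0
        )
        with pytest.raises(GeometryError):
            simulate_spreading_sequence(default_pattern, params)


class TestSurface:
    def test_default_confined_volume_and_median_modulus(self, default_pattern):
        surf = surface_defaults("confined")
        height, modulus, truth = synthesize_platelet_surface(
            default_pattern, surf, "confined"
        )
        # defaults: ~30 um^2 footprint, 0.4 um mean height -> ~12 fL
        assert truth["area_um2"] == pytest.approx(30.0, rel=0.05)
        assert truth["mean_height_um"] == pytest.approx(0.4, rel=0.05)
        assert truth["volume_fl"] == pytest.approx(12.0, rel=0.08)
        # median over the generated map equals the configured base modulus
        fp = height > 0
        assert truth["median_modulus_kpa"] == pytest.approx(
            np.median(modulus[fp]), rel=1e-12
        )
        assert truth["median_modulus_kpa"] == pytest.approx(2.3, abs=1e-9)
        # paraboloid cap: pixel heights ~uniform, skewness ~0
        assert abs(truth["height_skewness"]) < 0.1

    def test_control_surface_flat_dominated_positive_skew(self, default_pattern):
        surf = surface_defaults("control")
        height, modulus, truth = synthesize_platelet_surface(
            default_pattern, surf, "control"
        )
        assert truth["volume_fl"] == pytest.approx(14.0, rel=0.08)
        assert truth["height_skewness"] > 0.5
        assert truth["median_modulus_kpa"] == pytest.approx(4.2)

    def test_zero_band_width_means_uniform_modulus(self, default_pattern):
        surf = surface_defaults("confined")
        surf = type(surf)(**{**surf.__dict__, "edge_band_width": 0.0})
        height, modulus, truth = synthesize_platelet_surface(
            default_pattern, surf, "confined"
        )
        inside = height > 0
        assert np.unique(modulus[inside]).size == 1

    def test_height_map_zero_outside_footprint(self, default_pattern):
        height, modulus, truth = synthesize_platelet_surface(
            default_pattern, surface_defaults("confined"), "confined"
        )
        assert np.all(height[~truth["footprint"]] == 0.0)

    def test_substrate_must_be_rigid(self):
        with pytest.raises(ValueError):
            type(surface_defaults("control"))(substrate_modulus=10.0)


class TestForwardModel:
    def test_trigger_gap_algebraic_vs_brute_force_root(self):
        # I(g)/I_sat = trigger  =>  g = lambda_c * trigger / (1 - trigger)
        lam_c = 20.0
        g98 = trigger_gap(0.98, lam_c)
        assert g98 == pytest.approx(49.0 * lam_c, rel=1e-12)
        root = brentq(lambda g: g / (g + lam_c) - 0.98, 1e-6, 1e6, xtol=1e-10)
        assert g98 == pytest.approx(root, abs=1e-6)
        assert trigger_gap(0.99, lam_c) - g98 == pytest.approx(50.0 * lam_c, rel=1e-12)

    def test_gap_solver_inverts_deformation_identity(self, rng):
        lam_p = 500.0
        for _ in range(20):
            w_max = rng.uniform(0, 900)
            g = rng.uniform(1.0, 5000.0)
            d = g - deformation(g, w_max, lam_p)
            assert gap_from_distance(d, w_max, lam_p) == pytest.approx(g, rel=1e-10)

    @given(st.floats(1.0, 1e5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_thickness_factor_properties(self, h):
        phi = thickness_factor(h, 100.0)
        assert 0.0 < phi < 1.0
        assert thickness_factor(h * 1.5, 100.0) > phi
        assert thickness_factor(1e9, 100.0) == pytest.approx(1.0, abs=1e-6)

    def test_current_monotone_in_z_noiseless(self, quiet_sim):
        h = np.array([[0.0, 0.3], [0.6, 0.1]])
        E = np.array([[1e6, 3.0], [2.0, 5.0]])
        stack = simulate_iz_stack(h, E, quiet_sim)
        for i in range(2):
            for j in range(2):
                cur = stack.current[i, j]
                cur = cur[np.isfinite(cur)]
                assert np.all(np.diff(cur) < 0)  # z descending => I decreasing

    def test_softer_pixel_larger_current_at_same_height(self, quiet_sim):
        h = np.full((1, 2), 0.5)
        E = np.array([[2.0, 8.0]])
        stack = simulate_iz_stack(h, E, quiet_sim)
        soft, stiff = stack.current[0, 0], stack.current[0, 1]
        k = min(np.isfinite(soft).sum(), np.isfinite(stiff).sum()) - 1
        assert np.all(soft[:k] >= stiff[:k] - 1e-7)
        assert np.any(soft[:k] > stiff[:k] + 1e-5)

    def test_zero_pressure_removes_modulus_contrast(self):
        sim = SICMSimParams(noise_sigma=0.0, tilt=(0.0, 0.0), pressure=0.0)
        h = np.full((1, 2), 0.5)
        E = np.array([[2.0, 2000.0]])
        stack = simulate_iz_stack(h, E, sim)
        a, b = stack.current[0, 0], stack.current[0, 1]
        k = min(np.isfinite(a).sum(), np.isfinite(b).sum()) - 1
        assert np.allclose(a[:k], b[:k], atol=1e-9)

    def test_geometry_factor_closed_form(self):
        lam_c, lam_p = 20.0, 500.0
        g98, g99 = 49 * lam_c, 99 * lam_c
        expect = lam_p * (g99 - g98) / ((lam_p + g98) * (lam_p + g99))
        assert geometry_factor(lam_c, lam_p) == pytest.approx(expect, rel=1e-12)
        # dz_def = w(g98) - w(g99) = w_max * C_geom
        w_max = 360.0
        dw = deformation(g98, w_max, lam_p) - deformation(g99, w_max, lam_p)
        assert dw == pytest.approx(w_max * geometry_factor(lam_c, lam_p), rel=1e-12)
        assert dz_def_closed_form(10.0, SICMSimParams()) == pytest.approx(
            90.0 * geometry_factor(lam_c, lam_p), rel=1e-12
        )


class TestCohorts:
    def test_same_seed_same_ground_truth(self, default_pattern):
        def truth_list(seed):
            rng = np.random.default_rng(seed)
            spec = spreading_defaults("confined", n=3)
            return [
                (t.spreading_time, t.final_aspect, t.final_angle, t.area[-1])
                for _, t in (
                    (simulate_spreading_sequence(default_pattern, draw_spreading_params(spec, default_pattern, rng)))
                    for _ in range(3)
                )
            ]

        assert truth_list(123) == truth_list(123)
        assert truth_list(123) != truth_list(124)

    def test_requested_cohort_size_honoured(self, rng):
        spec = sicm_defaults("control", n=4)
        out = list(generate_sicm_cohort(spec, rng))
        assert len(out) == 4

    def test_cohort_truth_medians_near_configured_targets(self, default_pattern):
        rng = np.random.default_rng(5)
        spec = spreading_defaults("confined", n=30)
        st_, area = [], []
        for _ in range(30):
            p = draw_spreading_params(spec, default_pattern, rng)
            st_.append(measured_interval(p.tau, p.t_half, p.duration))
            area.append(p.area(p.duration))
        # Monte-Carlo tolerance on n=30 medians of ~5-15 % lognormal jitter
        assert np.median(st_) == pytest.approx(15.0, abs=0.6)
        assert np.median(area) == pytest.approx(30.0, rel=0.08)
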