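"""Topography extraction, modulus inversion, leveling, per-platelet stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from platelab.sicmproc import (
    SICMAnalysisParams,
    TopographyMap,
    correct_bottom_effect,
    extract_dz,
    extract_topography,
    invert_modulus,
    level_tilt,
    platelet_statistics,
    segment_platelets,
    smooth_within_mask,
)
from platelab.synthgen import (
    SICMSimParams,
    deformation,
    dz_def_closed_form,
    simulate_iz_stack,
    surface_defaults,
    synthesize_platelet_surface,
    thickness_factor,
    trigger_gap,
)


def rigid_stack(shape=(6, 6), height=None, sim=None):
    sim = sim or SICMSimParams(noise_sigma=0.0, tilt=(0.0, 0.0))
    h = np.zeros(shape) if height is None else height
    return simulate_iz_stack(h, np.full(shape, 1.0e6), sim)


class TestTopography:
    def test_flat_rigid_surface_constant_map(self, quiet_sim):
        topo = extract_topography(rigid_stack(sim=quiet_sim))
        assert np.nanvar(topo) == pytest.approx(0.0, abs=1e-12)

    def test_step_recovered_within_one_z_step(self, quiet_sim):
        h = np.zeros((6, 6))
        h[:, 3:] = 0.3
        topo = extract_topography(rigid_stack(height=h, sim=quiet_sim))
        step = topo[:, 3:].mean() - topo[:, :3].mean()
        assert step == pytest.approx(300.0, abs=quiet_sim.z_step)

    def test_soft_pixel_recorded_lower_by_trigger_indentation(self, quiet_sim):
        # equal true height; the soft pixel triggers lower by w(g98)
        h = np.full((1, 2), 0.5)
        E = np.array([[3.0, 1.0e6]])
        stack = simulate_iz_stack(h, E, quiet_sim)
        topo = extract_topography(stack)
        e_eff = 3.0 / thickness_factor(500.0, quiet_sim.h_c)
        w_max = quiet_sim.c_d * quiet_sim.pressure * quiet_sim.r_i / e_eff
        w98 = float(deformation(trigger_gap(0.98, 20.0), w_max, 500.0))
        # ~1 nm window-curvature bias on soft pixels (no deformation
        # correction at the topography stage) — negligible against the
        # 50-nm segmentation criterion and the um-scale heights
        assert topo[0, 1] - topo[0, 0] == pytest.approx(w98, abs=2.0)


class TestExtractDz:
    def test_noiseless_rigid_dz_is_50_lambda_c(self, quiet_sim):
        dz = extract_dz(rigid_stack(sim=quiet_sim))
        assert np.nanmax(np.abs(dz - 50.0 * quiet_sim.lambda_c)) < quiet_sim.z_step / 10.0

    def test_dz_monotone_decreasing_in_modulus(self, quiet_sim):
        h = np.full((1, 2), 100.0)
        stack = simulate_iz_stack(h, np.array([[2.0, 4.0]]), quiet_sim)
        dz = extract_dz(stack)
        assert dz[0, 0] > dz[0, 1]

    @pytest.mark.parametrize("e_kpa", [1.0, 2.0, 4.0, 8.0, 16.0])
    def test_dz_def_matches_closed_form_within_1pct(self, quiet_sim, e_kpa):
        h = np.full((3, 3), 100.0)  # thick: phi ~ 1
        stack = simulate_iz_stack(h, np.full((3, 3), e_kpa), quiet_sim)
        dz_def = np.nanmean(extract_dz(stack)) - 50.0 * quiet_sim.lambda_c
        e_eff = e_kpa / thickness_factor(100.0e3, quiet_sim.h_c)
        expect = float(dz_def_closed_form(e_eff, quiet_sim))
        assert dz_def == pytest.approx(expect, rel=0.01)


class TestInvertModulus:
    def test_round_trip_uniform_thick_sample(self, quiet_sim):
        h = np.full((4, 6), 10.0)
        h[:, :2] = 0.0  # substrate strip for the rigid reference
        E = np.full((4, 6), 4.2)
        E[:, :2] = 1.0e6
        stack = simulate_iz_stack(h, E, quiet_sim)
        dz = extract_dz(stack)
        e_app, dz_def, ref = invert_modulus(
            dz, stack, substrate_mask=h == 0.0
        )
        sample = e_app[:, 2:]
        e_eff = 4.2 / thickness_factor(10.0e3, quiet_sim.h_c)
        assert np.nanmedian(sample) == pytest.approx(e_eff, rel=0.05)
        assert ref == pytest.approx(1000.0, abs=0.1)

    def test_substrate_pixels_masked_rigid(self, quiet_sim):
        stack = rigid_stack(sim=quiet_sim)
        dz = extract_dz(stack)
        e_app, dz_def, _ = invert_modulus(dz, stack, rigid_reference=1000.0)
        assert np.isnan(e_app).all()  # dz_def ~ 0 <= floor everywhere

    def test_pressure_cancels_in_recovered_modulus(self):
        for p_kpa in (5.0, 10.0):
            sim = SICMSimParams(noise_sigma=0.0, tilt=(0.0, 0.0), pressure=p_kpa)
            h = np.full((2, 2), 50.0)
            stack = simulate_iz_stack(h, np.full((2, 2), 3.0), sim)
            dz = extract_dz(stack)
            e_app, dz_def, _ = invert_modulus(dz, stack, rigid_reference=1000.0)
            if p_kpa == 5.0:
                dz5, e5 = np.nanmean(dz_def), np.nanmedian(e_app)
            else:
                assert np.nanmean(dz_def) == pytest.approx(2 * dz5, rel=0.01)
                assert np.nanmedian(e_app) == pytest.approx(e5, rel=0.01)

    def test_missing_reference_raises(self, quiet_sim):
        stack = rigid_stack(sim=quiet_sim)
        with pytest.raises(ValueError):
            invert_modulus(extract_dz(stack), stack)


class TestLevelTilt:
    def test_pure_plane_levels_to_zero(self):
        x = np.arange(32) * 0.4
        plane = 12.0 + 18.0 * x[None, :] + 7.0 * x[:, None]
        topo = level_tilt(plane, pixel_size=0.4)
        assert np.abs(topo.height).max() < 1e-9

    def test_tilt_coefficients_recovered_with_platelet_on_top(self, rng):
        # plane + platelet occupying ~20 % of the field + noise
        nx = 48
        x = (np.arange(nx) + 0.5) * 0.4 - nx * 0.4 / 2
        X, Y = np.meshgrid(x, x)
        plane = 5.0 + 20.0 * X + 10.0 * Y
        platelet = np.zeros_like(plane)
        platelet[(X**2 + Y**2) < 3.0**2] = 400.0
        raw = plane + platelet + rng.normal(0, 5.0, plane.shape)
        topo = level_tilt(raw, pixel_size=0.4)
        assert topo.tilt_params[1] == pytest.approx(20.0, rel=0.01)
        assert topo.tilt_params[2] == pytest.approx(10.0, rel=0.01)
        substrate = platelet == 0
        assert np.sqrt(np.mean(topo.height[substrate] ** 2)) * 1e3 < 5.0  # nm RMS

    def test_leveling_idempotent(self, rng):
        raw = 3.0 + rng.normal(0, 8.0, (40, 40))
        raw[10:20, 10:25] += 500.0
        t1 = level_tilt(raw, 0.4)
        t2 = level_tilt(t1.height * 1e3, 0.4)
        rms_change = np.sqrt(np.mean((t2.height - t1.height) ** 2)) * 1e3
        assert rms_change < 1.0  # nm


class TestSegmentation:
    def _topo(self, height_um):
        return TopographyMap(height=height_um, tilt_params=(0, 0, 0), pixel_size=0.4)

    def test_flat_field_no_labels(self):
        labels = segment_platelets(self._topo(np.zeros((20, 20))))
        assert labels.max() == 0

    def test_two_separated_platelets_two_labels(self):
        h = np.zeros((30, 30))
        h[2:10, 2:10] = 0.4
        h[20:28, 20:28] = 0.4
        labels = segment_platelets(self._topo(h))
        assert labels.max() == 2

    def test_min_area_removes_specks(self):
        h = np.zeros((30, 30))
        h[5, 5] = 0.4  # single pixel = 0.16 um^2 < 2 um^2
        h[15:25, 15:25] = 0.4
        labels = segment_platelets(self._topo(h))
        assert labels.max() == 1
        assert labels[5, 5] == 0

    def test_synthetic_platelet_iou_against_truth(self, default_pattern, quiet_sim):
        height, modulus, truth = synthesize_platelet_surface(
            default_pattern, surface_defaults("control"), "control"
        )
        # sample to the SICM grid (0.4 um) by striding the 0.1-um maps
        h4, m4 = height[::4, ::4], modulus[::4, ::4]
        stack = simulate_iz_stack(h4, m4, quiet_sim)
        raw = extract_topography(stack)
        topo = level_tilt(raw, 0.4)
        labels = segment_platelets(topo)
        assert labels.max() == 1
        fp = truth["footprint"][::4, ::4]
        inter = ((labels == 1) & fp).sum()
        union = ((labels == 1) | fp).sum()
        assert inter / union >= 0.9


class TestBottomEffectCorrection:
    def _topo(self, h_um):
        return TopographyMap(height=h_um, tilt_params=(0, 0, 0), pixel_size=0.4)

    def test_h_equals_hc_halves_apparent_modulus(self):
        e_app = np.full((2, 2), 8.0)
        topo = self._topo(np.full((2, 2), 0.1))  # h = h_c = 100 nm
        e_corr = correct_bottom_effect(e_app, topo, h_c=100.0)
        assert np.allclose(e_corr, 4.0)

    def test_thick_limit_leaves_modulus_unchanged(self):
        e_app = np.full((2, 2), 8.0)
        e_corr = correct_bottom_effect(e_app, self._topo(np.full((2, 2), 50.0)), 100.0)
        assert np.allclose(e_corr, 8.0, rtol=0.003)

    def test_nonpositive_height_masked(self):
        e_app = np.full((1, 2), 8.0)
        topo = self._topo(np.array([[0.5, -0.01]]))
        e_corr = correct_bottom_effect(e_app, topo, 100.0)
        assert np.isfinite(e_corr[0, 0]) and np.isnan(e_corr[0, 1])

    def test_round_trip_thin_lamellipodium(self, quiet_sim):
        # h = 150 nm, true E = 4 kPa: E_app overestimates by (h+h_c)/h
        h = np.full((3, 3), 0.15)
        stack = simulate_iz_stack(h, np.full((3, 3), 4.0), quiet_sim)
        dz = extract_dz(stack)
        e_app, _, _ = invert_modulus(dz, stack, rigid_reference=1000.0)
        assert np.nanmedian(e_app) == pytest.approx(4.0 * 250.0 / 150.0, rel=0.03)
        e_corr = correct_bottom_effect(e_app, self._topo(h), quiet_sim.h_c)
        assert np.nanmedian(e_corr) == pytest.approx(4.0, rel=0.10)


class TestPlateletStatistics:
    def _inputs(self, h_um, labels=None):
        topo = TopographyMap(height=h_um, tilt_params=(0, 0, 0), pixel_size=0.4)
        labels = labels if labels is not None else (h_um > 0.05).astype(np.uint16)
        return labels, topo

    def test_uniform_slab_volume_exact_and_skewless(self):
        h = np.zeros((20, 20))
        px = 0.4
        n = int(round(30.0 / px**2))  # ~30 um^2
        h.flat[:n] = 0.4
        labels, topo = self._inputs(h)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert rec.volume_fl == pytest.approx(rec.area_um2 * 0.4, rel=1e-12)
        assert rec.volume_fl == pytest.approx(12.0, rel=0.01)
        assert rec.height_skewness == 0.0

    def test_p99_on_hand_computed_sample(self):
        h = np.zeros((1, 10))
        h[0, :9] = 0.1
        h[0, 9] = 1.0
        labels = np.ones((1, 10), dtype=np.uint16)
        topo = TopographyMap(height=h, tilt_params=(0, 0, 0), pixel_size=0.4)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert rec.max_height_um == pytest.approx(np.percentile(h[0], 99))
        # linear-interpolation quantile: 0.1 + 0.91*(1.0-0.1)
        assert rec.max_height_um == pytest.approx(0.1 + 0.91 * 0.9, rel=1e-9)

    def test_volume_conservation_sum_identity(self, rng):
        h = np.abs(rng.normal(0.4, 0.2, (25, 25)))
        labels = np.ones_like(h, dtype=np.uint16)
        topo = TopographyMap(height=h, tilt_params=(0, 0, 0), pixel_size=0.4)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert rec.volume_fl == pytest.approx(float((h * 0.16).sum()), rel=1e-12)

    def test_quantile_and_skewness_match_brute_force(self, rng):
        vals = rng.lognormal(0.0, 0.6, 1000)
        h = vals.reshape(25, 40)
        labels = np.ones_like(h, dtype=np.uint16)
        topo = TopographyMap(height=h, tilt_params=(0, 0, 0), pixel_size=0.4)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert rec.max_height_um == pytest.approx(np.quantile(vals, 0.99), rel=1e-12)
        assert rec.height_skewness == pytest.approx(sps.skew(vals, bias=True), rel=1e-9)

    def test_all_undefined_modulus_flagged(self):
        h = np.full((5, 5), 0.4)
        labels, topo = self._inputs(h)
        e_corr = np.full((5, 5), np.nan)
        rec = platelet_statistics(labels, topo, e_corr).iloc[0]
        assert np.isnan(rec.median_modulus_kpa)
        assert bool(rec.modulus_undefined)

    def test_dome_skew_near_zero_rim_skew_positive(self):
        yy, xx = np.mgrid[:40, :40]
        r2 = ((xx - 20) / 15.0) ** 2 + ((yy - 20) / 15.0) ** 2
        dome = np.where(r2 <= 1, 0.8 * (1 - r2), 0.0)  # paraboloid: uniform heights
        labels, topo = self._inputs(dome)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert abs(rec.height_skewness) < 0.1
        rim = np.where(r2 <= 1, 0.25, 0.0)  # flat rim with a small tall core
        rim[(r2 <= 0.05)] = 1.0
        labels, topo = self._inputs(rim)
        rec = platelet_statistics(labels, topo, None).iloc[0]
        assert rec.height_skewness > 0.5


class TestSmoothing:
    def test_mask_respected_and_mean_preserved(self, rng):
        field = rng.normal(5.0, 1.0, (30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        sm = smooth_within_mask(field, mask, size=5)
        assert np.isnan(sm[~mask]).all()
        assert np.nanmean(sm[mask]) == pytest.approx(field[mask].mean(), abs=0.05)
        assert np.nanstd(sm[mask]) < field[mask].std()
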