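"""I-z stack processing: topography, elastic modulus, per-platelet stats.

The processing chain converts a grid of I-z approach curves into leveled
topography and corrected elastic-modulus maps and reduces them to
per-platelet morpho-mechanical records:

1. :func:`extract_topography` — z-position of the trigger crossing.
2. :func:`extract_dz` — z-distance between the 99 % and 98 % current
   levels of each curve (the "slope" a trigger-based instrument
   records).
3. :func:`level_tilt` — iterative plane fit excluding elevated pixels.
4. :func:`segment_platelets` — height criterion (> 50 nm) + connected
   components.
5. :func:`invert_modulus` — apparent modulus from the deformation
   distance, self-calibrated against the rigid substrate.
6. :func:`correct_bottom_effect` — height-dependent correction removing
   the apparent stiffening of thin regions on the rigid substrate.
7. :func:`platelet_statistics` — median modulus, 99th-percentile height,
   volume, height skewness per platelet.

Calibration stand-in
--------------------
The slope-to-modulus calibration implemented here is the exact inverse
of the package's forward model: ``E_app = c_d P r_i C_geom / dz_def``
with ``dz_def = dz - dz_rigid`` and the geometry factor C_geom of
:func:`platelab.synthgen.geometry_factor`.  For real instruments these
constants are calibration parameters supplied by the user.

Noise handling: current levels are located by weighted local-linear
inverse regression of the transformed current ``u = I/(I_sat - I)``
inside a window around the raw crossing, after subtracting the
(iteratively estimated) indentation contribution that makes the
regression exactly linear under the current law.  The estimator is
exact on noiseless data and averages the per-sample current noise over
~100 samples on noisy curves — necessary because the I-z slope between
the 99 % and 98 % levels is shallow, so single-crossing interpolation
would carry tens of nm of noise into the deformation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import IZStack
from .synthgen import geometry_factor, thickness_factor, trigger_gap

__all__ = [
    "SICMAnalysisParams",
    "TopographyMap",
    "extract_topography",
    "extract_dz",
    "smooth_within_mask",
    "invert_modulus",
    "level_tilt",
    "segment_platelets",
    "correct_bottom_effect",
    "platelet_statistics",
]


@dataclass(frozen=True)
class SICMAnalysisParams:
    """Calibration constants of the modulus inversion (lengths in nm).

    Defaults mirror the simulator constants; for real data they are
    instrument calibration parameters.  ``dz_floor`` (nm) is the
    smallest resolvable deformation distance: pixels at or below it are
    reported as rigid/undefined rather than as absurdly stiff.  When
    None it defaults to two z-steps of the analyzed stack.
    """

    r_i: float = 90.0
    c_d: float = 1.0
    lambda_c: float = 20.0
    lambda_p: float = 500.0
    h_c: float = 100.0
    level_hi: float = 0.99
    dz_floor: Optional[float] = None
    window_lo: float = 600.0  # nm, one-sided fit window above the trigger
    window_hi: float = 600.0  # nm, fit window below the level_hi crossing
    height_threshold_um: float = 0.05  # segmentation criterion (> 50 nm)
    min_area_um2: float = 2.0


@dataclass
class TopographyMap:
    """Leveled topography (um) with the fitted tilt plane."""

    height: np.ndarray  # (ny, nx) um, substrate ~ 0
    tilt_params: tuple[float, float, float]  # intercept (nm), slope x/y (nm/um)
    pixel_size: float
    n_iter: int = 0


# ---------------------------------------------------------------------------
# level-crossing extraction
# ---------------------------------------------------------------------------


def _first_crossing(stack: IZStack, level_frac: float) -> np.ndarray:
    """z (nm) of the first downward crossing of level_frac * i_sat.

    Linear interpolation between the bracketing samples; NaN where the
    curve starts below the level (no crossing observed).
    """
    level = level_frac * stack.i_sat
    I = stack.current
    z = stack.z
    with np.errstate(invalid="ignore"):
        below = I < level  # NaN compares False
    k = np.argmax(below, axis=-1)
    ok = below.any(axis=-1) & (k > 0)
    k_safe = np.clip(k, 1, z.size - 1)
    i0 = np.take_along_axis(I, (k_safe - 1)[..., None], axis=-1)[..., 0]
    i1 = np.take_along_axis(I, k_safe[..., None], axis=-1)[..., 0]
    z0, z1 = z[k_safe - 1], z[k_safe]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (level - i0) / (i1 - i0)
    zc = z0 + frac * (z1 - z0)
    return np.where(ok, zc, np.nan)


def estimate_current_noise(stack: IZStack, n_samples: int = 80) -> float:
    """Per-sample current noise variance from far-field second differences.

    The first samples of every curve sit in the flat far field; second
    differences there are ~pure noise with variance ``6 sigma^2``.
    """
    head = stack.current[..., : min(n_samples, stack.z.size)].astype(float)
    d2 = np.diff(head, n=2, axis=-1)
    d2 = d2[np.isfinite(d2)]
    if d2.size < 10:
        return 0.0
    return float(np.var(d2) / 6.0)


def extract_topography(
    stack: IZStack, params: SICMAnalysisParams = SICMAnalysisParams()
) -> np.ndarray:
    """Raw (unleveled) topography: trigger-crossing z per pixel, in nm.

    The crossing is located by the same windowed inverse regression used
    for the deformation distance (initialized at the raw interpolated
    crossing): on noiseless curves the two coincide exactly, on noisy
    curves the regression removes the early-stop bias and most of the
    variance of the single-sample crossing.  Pixels whose curve never
    crosses the trigger are NaN (with a warning); the constant trigger
    gap is absorbed later by the plane fit of :func:`level_tilt`.
    """
    zc = _first_crossing(stack, stack.trigger)
    n_bad = int(np.isnan(zc).sum())
    if n_bad:
        warnings.warn(f"{n_bad} pixel(s) never crossed the trigger; masked")
    fitted = _window_fit_level(
        stack,
        stack.trigger,
        zc,
        -2.0 * stack.z_step,
        params.window_lo,
        params.lambda_c,
        params.lambda_p,
        np.zeros(stack.current.shape[:2]),
        noise_var=estimate_current_noise(stack),
    )
    return np.where(np.isfinite(zc) & np.isfinite(fitted), fitted, np.nan)


def _window_fit_level(
    stack: IZStack,
    level_frac: float,
    center: np.ndarray,
    lo_off: float,
    hi_off: float,
    lambda_c: float,
    lambda_p: float,
    w_max_est: np.ndarray,
    noise_var: float = 0.0,
) -> np.ndarray:
    """Locate the z of a current level by weighted local-linear inverse
    regression of the transformed current.

    For the hyperbolic current law, ``u = I/(i_sat - I)`` equals
    ``g/lambda_c``; subtracting the (estimated) indentation,
    ``y = u - w(lambda_c u)/lambda_c``, gives ``y = (z - z_surf)/lambda_c``
    — *exactly* linear in z for every pixel when ``w_max_est`` matches
    the pixel's true indentation amplitude (and for rigid pixels with
    ``w_max_est = 0``).  y is therefore fitted linearly in z over the
    samples with ``center + lo_off <= z <= center + hi_off`` and solved
    for the level value; inverse-variance weights ``(i_sat - I)^4``
    (the u-transform noise scaling) keep the flat far-field part of the
    window from dominating.
    """
    z = stack.z
    step = stack.z_step
    ns = z.size
    npx = stack.current.shape[0] * stack.current.shape[1]
    I = stack.current.reshape(npx, ns)
    cen = np.where(np.isfinite(center.reshape(npx)), center.reshape(npx), z[ns // 2])

    K = int(round((hi_off - lo_off) / step)) + 1
    # start index of the window (z descending: smaller index = larger z)
    s = np.round((z[0] - (cen + hi_off)) / step).astype(int)
    s = np.clip(s, 0, max(ns - K, 0))
    idx = s[:, None] + np.arange(min(K, ns))[None, :]
    zw = z[idx]
    Iw = np.take_along_axis(I, idx, axis=1).astype(float)

    margin = np.maximum(stack.i_sat - Iw, 1e-4 * stack.i_sat)
    u = Iw / margin
    if noise_var > 0.0:
        # the u transform is convex in I, so noise inflates E[u] by
        # ~ sigma^2 i_sat / (i_sat - I)^3; subtract the estimated bias
        u = u - noise_var * stack.i_sat / margin**3
    wm = w_max_est.reshape(npx)[:, None]
    g_obs = lambda_c * np.maximum(u, 1.0)
    y = u - wm * lambda_p / ((lambda_p + g_obs) * lambda_c)

    finite = np.isfinite(Iw)
    # inverse-variance weights ~ (i_sat - I)^4 from a *smoothed* current:
    # raw-sample weights are anticorrelated with the noise and select
    # against positive noise excursions, biasing the fit low
    filled = np.where(finite, Iw, 0.0)
    norm = ndi.uniform_filter1d(finite.astype(float), size=21, axis=1, mode="nearest")
    i_smooth = ndi.uniform_filter1d(filled, size=21, axis=1, mode="nearest") / np.maximum(
        norm, 1e-12
    )
    margin_s = np.maximum(stack.i_sat - i_smooth, 1e-4 * stack.i_sat)
    weights = np.where(finite, margin_s**4, 0.0)
    y = np.where(finite, y, 0.0)

    scale = (hi_off - lo_off) / 2.0
    x = (zw - cen[:, None]) / scale
    s0 = weights.sum(axis=1)
    s1 = (weights * x).sum(axis=1)
    s2 = (weights * x * x).sum(axis=1)
    t0 = (weights * y).sum(axis=1)
    t1 = (weights * y * x).sum(axis=1)
    det = s0 * s2 - s1 * s1
    enough = (finite.sum(axis=1) >= 5) & (det > 0)
    det = np.where(enough, det, 1.0)
    c0 = (s2 * t0 - s1 * t1) / det
    c1 = (s0 * t1 - s1 * t0) / det

    u_level = level_frac / (1.0 - level_frac)
    g_level = lambda_c * u_level
    y_level = u_level - w_max_est.reshape(npx) * lambda_p / (
        (lambda_p + g_level) * lambda_c
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        x_star = (y_level - c0) / c1
    bad = ~enough | ~np.isfinite(x_star) | (np.abs(x_star) > 3.0)
    x_star = np.where(bad, np.nan, x_star)
    return (cen + x_star * scale).reshape(stack.current.shape[:2])


def extract_dz(
    stack: IZStack, params: SICMAnalysisParams = SICMAnalysisParams()
) -> np.ndarray:
    """Deformation-sensitive slope distance dz = z(99 %) - z(98 %), in nm.

    Both levels are located by the windowed inverse regression of
    :func:`_window_fit_level`; the window for the upper level is centred
    at the expected offset ``g(level_hi) - g(trigger)`` above the raw
    trigger crossing.  The per-pixel indentation amplitude entering the
    regression's deformation correction is unknown a priori, so the
    extraction is iterated: each pass re-estimates ``w_max`` from the
    excess of dz over the rigid gap difference and refits (three passes;
    the fixed point is reached essentially immediately).  Pixels whose
    curve starts below the upper level are NaN.
    """
    if params.level_hi <= stack.trigger:
        raise ValueError("level_hi must exceed the trigger level")
    z_raw = _first_crossing(stack, stack.trigger)
    g_t = trigger_gap(stack.trigger, params.lambda_c)
    g_hi = trigger_gap(params.level_hi, params.lambda_c)
    c_geom = geometry_factor(
        params.lambda_c, params.lambda_p, stack.trigger, params.level_hi
    )

    noise_var = estimate_current_noise(stack)
    w_est = np.zeros(stack.current.shape[:2])
    dz = np.full(stack.current.shape[:2], np.nan)
    center_hi = z_raw + (g_hi - g_t)
    for _ in range(3):
        z_lo = _window_fit_level(
            stack,
            stack.trigger,
            z_raw,
            -2.0 * stack.z_step,
            params.window_lo,
            params.lambda_c,
            params.lambda_p,
            w_est,
            noise_var=noise_var,
        )
        z_hi = _window_fit_level(
            stack,
            params.level_hi,
            center_hi,
            -params.window_hi,
            0.5 * params.window_hi,
            params.lambda_c,
            params.lambda_p,
            w_est,
            noise_var=noise_var,
        )
        dz = z_hi - z_lo
        with np.errstate(invalid="ignore"):
            dz = np.where(dz > 0, dz, np.nan)
            w_est = np.clip((dz - (g_hi - g_t)) / c_geom, 0.0, None)
        w_est = np.where(np.isfinite(w_est), w_est, 0.0)
        # re-centre the upper window on the measured crossing so window
        # placement (and its small residual bias) is identical for soft
        # and rigid pixels
        center_hi = np.where(np.isfinite(z_hi), z_hi, center_hi)
    return dz


def smooth_within_mask(field: np.ndarray, mask: np.ndarray, size: int = 5) -> np.ndarray:
    """Average a noisy per-pixel field over a size x size neighbourhood,
    using only pixels inside ``mask`` (normalized convolution).

    Used to pool the deformation distance over neighbouring platelet
    pixels before modulus inversion: the per-pixel dz noise (set by the
    shallow I-z slope between the current levels) is several times the
    nm-scale deformation signal of stiff samples, and averaging within
    the platelet avoids diluting edges with substrate pixels.  Pixels
    outside the mask (or with no valid neighbour) are NaN.
    """
    valid = mask & np.isfinite(field)
    num = ndi.uniform_filter(np.where(valid, field, 0.0), size=size)
    den = ndi.uniform_filter(valid.astype(float), size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~mask | (den <= 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# modulus inversion and correction
# ---------------------------------------------------------------------------


def invert_modulus(
    dz: np.ndarray,
    stack: IZStack,
    params: SICMAnalysisParams = SICMAnalysisParams(),
    rigid_reference: Optional[float] = None,
    substrate_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Apparent elastic modulus from the deformation distance.

    ``dz_def = dz - rigid_reference`` (floored at ``dz_floor``); then
    ``E_app = c_d P r_i C_geom / dz_def`` in kPa.  The rigid reference
    is the median dz over substrate pixels unless supplied directly.

    Returns ``(E_app, dz_def, rigid_reference)``; pixels with
    ``dz_def <= dz_floor`` are NaN (rigid/undefined).
    """
    if rigid_reference is None:
        if substrate_mask is None or not np.any(substrate_mask & np.isfinite(dz)):
            raise ValueError(
                "rigid_reference not estimable: no substrate pixels and none supplied"
            )
        rigid_reference = float(np.nanmedian(dz[substrate_mask]))
    floor = params.dz_floor if params.dz_floor is not None else 2.0 * stack.z_step
    dz_def = dz - rigid_reference
    c_geom = geometry_factor(
        params.lambda_c, params.lambda_p, stack.trigger, params.level_hi
    )
    scale = params.c_d * stack.pressure_kpa * params.r_i * c_geom
    with np.errstate(invalid="ignore", divide="ignore"):
        e_app = np.where(dz_def > floor, scale / dz_def, np.nan)
    return e_app, dz_def, rigid_reference


def correct_bottom_effect(
    e_app: np.ndarray,
    topo: TopographyMap,
    h_c: float = 100.0,
    platelet_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Substrate (bottom-effect) correction ``E_corr = E_app * phi(h)``.

    ``phi(h) = h/(h + h_c)`` with the platelet height h from the leveled
    topography; applied on platelet pixels only (``platelet_mask``;
    default: all pixels with E_app defined).  Pixels with h <= 0 are
    masked.
    """
    h_nm = topo.height * 1e3
    if platelet_mask is None:
        platelet_mask = np.isfinite(e_app)
    phi = thickness_factor(np.maximum(h_nm, 0.0), h_c)
    e_corr = np.where(platelet_mask & (h_nm > 0), e_app * phi, np.nan)
    return e_corr


# ---------------------------------------------------------------------------
# leveling and segmentation
# ---------------------------------------------------------------------------


def level_tilt(
    raw_height_nm: np.ndarray,
    pixel_size: float,
    exclude_above_nm: float = 50.0,
    max_iter: int = 10,
) -> TopographyMap:
    """Iteratively fit and subtract the substrate tilt plane.

    A least-squares plane is fitted to all (finite) pixels; pixels more
    than ``exclude_above_nm`` above the plane are excluded and the plane
    refitted, iterating until the exclusion set is stable (or
    ``max_iter``, with a warning).  The output heights are in um with
    the substrate at ~0.
    """
    raw = np.asarray(raw_height_nm, dtype=float)
    ny, nx = raw.shape
    x = (np.arange(nx) + 0.5) * pixel_size - nx * pixel_size / 2.0
    y = (np.arange(ny) + 0.5) * pixel_size - ny * pixel_size / 2.0
    X, Y = np.meshgrid(x, y)
    design = np.column_stack([np.ones(raw.size), X.ravel(), Y.ravel()])
    finite = np.isfinite(raw.ravel())
    include = finite.copy()
    coef = np.zeros(3)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        coef, *_ = np.linalg.lstsq(design[include], raw.ravel()[include], rcond=None)
        resid = raw.ravel() - design @ coef
        new_include = finite & (resid <= exclude_above_nm)
        if np.array_equal(new_include, include):
            break
        include = new_include
    else:
        warnings.warn("tilt leveling did not converge; using last iterate")
    leveled = (raw - (coef[0] + coef[1] * X + coef[2] * Y)) / 1e3
    return TopographyMap(
        height=leveled,
        tilt_params=(float(coef[0]), float(coef[1]), float(coef[2])),
        pixel_size=pixel_size,
        n_iter=n_iter,
    )


def segment_platelets(
    topo: TopographyMap,
    min_area_um2: float = 2.0,
    height_threshold_um: float = 0.05,
) -> np.ndarray:
    """Label platelets by the height criterion (> 50 nm above substrate).

    8-connected component labeling of ``height > threshold``; components
    smaller than ``min_area_um2`` are removed.  Returns a uint16 label
    grid (0 = substrate).
    """
    with np.errstate(invalid="ignore"):
        fg = topo.height > height_threshold_um
    labels, nlab = ndi.label(fg, structure=np.ones((3, 3), int))
    if nlab:
        min_px = int(np.ceil(min_area_um2 / topo.pixel_size**2))
        counts = np.bincount(labels.ravel(), minlength=nlab + 1)
        relabel = np.zeros(nlab + 1, dtype=np.uint16)
        keep = [lab for lab in range(1, nlab + 1) if counts[lab] >= min_px]
        for new, lab in enumerate(keep, start=1):
            relabel[lab] = new
        labels = relabel[labels]
    return labels.astype(np.uint16)


# ---------------------------------------------------------------------------
# per-platelet statistics
# ---------------------------------------------------------------------------


def _skewness(values: np.ndarray) -> float:
    """Population (Fisher) skewness; 0 for constant samples by convention."""
    centred = values - values.mean()
    m2 = np.mean(centred**2)
    scale = max(float(np.abs(values).max()), 1e-30)
    if m2 <= (1e-9 * scale) ** 2:  # constant sample up to rounding
        return 0.0
    return float(np.mean(centred**3) / m2**1.5)


def platelet_statistics(
    labels: np.ndarray,
    topo: TopographyMap,
    e_corr: Optional[np.ndarray],
    pixel_size: Optional[float] = None,
) -> pd.DataFrame:
    """Per-platelet morpho-mechanical records.

    For every label: area (px count x pixel_size^2, um^2), median
    corrected modulus over defined pixels (kPa; NaN + flag when no pixel
    has a defined modulus), maximum height as the 99th percentile of the
    pixel heights (um, linear-interpolation quantile), volume as mean
    height x area (fL = um^3), and the Fisher skewness of the pixel
    heights.
    """
    px = pixel_size if pixel_size is not None else topo.pixel_size
    rows = []
    for lab in range(1, int(labels.max()) + 1):
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            continue
        h = topo.height[sel]
        area = n * px**2
        ii, jj = np.nonzero(sel)
        row = {
            "label": lab,
            "area_um2": area,
            "max_height_um": float(np.percentile(h, 99)),
            "volume_fl": float(h.mean() * area),
            "height_skewness": _skewness(h),
            "centroid_x_um": float((jj.mean() + 0.5) * px),
            "centroid_y_um": float((ii.mean() + 0.5) * px),
        }
        if e_corr is not None:
            vals = e_corr[sel]
            vals = vals[np.isfinite(vals)]
            row["median_modulus_kpa"] = float(np.median(vals)) if vals.size else np.nan
            row["n_modulus_px"] = int(vals.size)
            row["modulus_undefined"] = vals.size == 0
        rows.append(row)
    return pd.DataFrame(rows)
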