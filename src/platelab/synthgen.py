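"""Synthetic-data generator with known ground truth.

Everything the analysis modules consume can be generated here: line
patterns, time-lapse spreading sequences, platelet topography/modulus
fields, and per-pixel I-z approach-curve stacks.  The generator defaults
are parameterized to the study conditions of the confinement experiment
they emulate (4-um fibrinogen lines at 15-um period, 15-s frames over
40 min, 0.4-um SICM pixels, 98 % current trigger, 10 kPa pipette
pressure) and to the printed condition medians (final area ~30 um^2,
spreading times 15 / 8.7 min, corrected moduli 2.3 / 4.2 kPa, volumes
~12 / 14 fL).

Spreading model
---------------
Each platelet is an ellipse whose area follows a logistic law

    A(t) = A0 + (Af - A0) / (1 + exp(-(t - t_half)/tau)).

The aspect ratio relaxes from ``aspect0`` to ``aspect_final`` with
timescale ``aspect_tau``; the unconstrained minor axis follows from area
and aspect and is then clipped at ``minor_cap`` (the line width for
confined platelets), with the major axis set so the ellipse keeps the
analytic area.  The orientation relaxes exponentially toward the final
angle (wrapped-normal around the pattern direction for confined
platelets, uniform for controls).  ``tau`` is calibrated per platelet so
that the 25-75 % spreading-time statistic *as measured on the sampled
observation window* equals the configured target.

SICM forward model
------------------
The ion current follows the hyperbolic law ``I/I_sat = g/(g + lambda_c)``
in the tip-sample gap g.  The applied pressure indents the sample by
``w(g) = w_max * lambda_p/(lambda_p + g)`` with
``w_max = c_d * P * r_i / E_eff``; thin samples on rigid substrate look
stiffer through the thickness factor ``phi(h) = h/(h + h_c)`` via
``E_eff = E/phi(h)``.  For a tip at height z above the (tilted) surface
the gap solves ``g = (z - z_surf) + w(g)``, which is quadratic in g and
solved in closed form.  Curves are sampled on a shared descending z grid
at ``z_step`` and stop at the first sample below the trigger, exactly as
the instrument does; the pressure-induced topography bias (soft pixels
trigger lower by w(g_trigger)) is deliberately left in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import GeometryError, IZStack, MaskSequence, PatternMask

__all__ = [
    "PatternSpec",
    "SpreadingParams",
    "SpreadingCohortSpec",
    "SurfaceSpec",
    "SICMSimParams",
    "GroundTruthTrace",
    "generate_pattern",
    "simulate_spreading_sequence",
    "synthesize_platelet_surface",
    "simulate_iz_stack",
    "spreading_defaults",
    "surface_defaults",
    "draw_spreading_params",
    "generate_spreading_cohort",
    "SICMCohortSpec",
    "sicm_defaults",
    "generate_sicm_cohort",
    "make_cohort",
    "logistic_area",
    "calibrate_tau",
    "measured_interval",
    "thickness_factor",
    "trigger_gap",
    "deformation",
    "gap_from_distance",
    "geometry_factor",
    "dz_def_closed_form",
    "apparent_trigger_height",
]


# ---------------------------------------------------------------------------
# pattern masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of the printed fibrinogen line pattern (lengths in um)."""

    line_width: float = 4.0
    period: float = 15.0
    orientation: float = 0.0  # direction of the lines, deg in (-90, 90]
    field_size: tuple[float, float] = (25.6, 25.6)  # (width, height)
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        if self.line_width <= 0 or self.pixel_size <= 0:
            raise ValueError("line_width and pixel_size must be positive")
        if self.period <= self.line_width:
            raise ValueError("period must exceed line_width")
        if not -90.0 < self.orientation <= 90.0:
            raise ValueError("orientation must lie in (-90, 90]")


def _pixel_centres(nx: int, ny: int, pixel_size: float):
    """Pixel-centre coordinates (um), origin at the field centre."""
    x = (np.arange(nx) + 0.5) * pixel_size - nx * pixel_size / 2.0
    y = (np.arange(ny) + 0.5) * pixel_size - ny * pixel_size / 2.0
    return np.meshgrid(x, y)


def generate_pattern(spec: PatternSpec) -> PatternMask:
    """Rasterize a periodic line pattern.

    A pixel is covered when the signed distance of its centre across the
    line direction is within ``line_width/2`` of a line centre; one line
    centre passes through the field centre.  Rejects fields smaller than
    one pattern period.
    """
    width, height = spec.field_size
    if min(width, height) < spec.period:
        raise GeometryError("field is smaller than one pattern period")
    nx = int(round(width / spec.pixel_size))
    ny = int(round(height / spec.pixel_size))
    X, Y = _pixel_centres(nx, ny, spec.pixel_size)
    theta = math.radians(spec.orientation)
    # signed distance across the line direction (0 at the field centre)
    d = -X * math.sin(theta) + Y * math.cos(theta)
    offset = np.abs(((d + spec.period / 2.0) % spec.period) - spec.period / 2.0)
    mask = offset <= spec.line_width / 2.0
    return PatternMask(
        mask=mask,
        pixel_size=spec.pixel_size,
        line_width=spec.line_width,
        period=spec.period,
        orientation=spec.orientation,
    )


def _across_line_distance(pattern: PatternMask, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Signed distance of points from the nearest line centre (um)."""
    theta = math.radians(pattern.orientation)
    d = -X * math.sin(theta) + Y * math.cos(theta)
    return ((d + pattern.period / 2.0) % pattern.period) - pattern.period / 2.0


# ---------------------------------------------------------------------------
# logistic spreading kinetics
# ---------------------------------------------------------------------------


def logistic_area(t, a0: float, af: float, t_half: float, tau: float):
    """Logistic area growth A(t); t and timescales in minutes."""
    t = np.asarray(t, dtype=float)
    frac = 1.0 / (1.0 + np.exp(-(t - t_half) / tau))
    return a0 + (af - a0) * frac


def _crossing_time(q: float, t_half: float, tau: float, duration: float) -> float:
    """Time at which the *windowed* normalized area crosses level q.

    The normalization uses A(0) and A(duration) as 0 and 100 %, exactly
    as the analysis stage defines the spreading time.
    """
    s0 = 1.0 / (1.0 + math.exp(min(t_half / tau, 700.0)))
    s1 = 1.0 / (1.0 + math.exp(max(-(duration - t_half) / tau, -700.0)))
    s = s0 + q * (s1 - s0)
    return t_half + tau * math.log(s / (1.0 - s))

def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def measured_interval(tau: float, t_half: float, duration: float) -> float:
    """Analytic 25-75 % spreading time of the sampled logistic (min)."""
    return _crossing_time(0.75, t_half, tau, duration) - _crossing_time(
        0.25, t_half, tau, duration
    )


def calibrate_tau(
    target_min: float, t_half: float, duration: float
) -> tuple[float, float]:
    """Choose (tau, t_half) so the measured 25-75 % time equals the target.

    For an untruncated logistic the interval is ``2 ln(3) tau``; inside a
    finite observation window the normalization by A(0) and A(duration)
    shifts it, so tau is found by root solving.  When the preferred
    ``t_half`` would violate ``t_half + 3 tau <= duration`` it is moved
    earlier to keep the growth inside the window.
    """

    def interval(tau: float) -> float:
        th = min(t_half, duration - 3.0 * tau)
        if th <= 0:
            return math.inf
        return measured_interval(tau, th, duration)

    lo, hi = 0.02 * target_min, 0.85 * target_min
    tau = brentq(lambda x: interval(x) - target_min, lo, hi, xtol=1e-10)
    return tau, min(t_half, duration - 3.0 * tau)


# ---------------------------------------------------------------------------
# per-platelet spreading parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpreadingParams:
    """Concrete kinetic and geometric parameters of one platelet.

    Areas in um^2, lengths in um, times in minutes (``frame_interval``
    in seconds), angles in degrees (axial).
    """

    condition: str  # "confined" or "control"
    a0: float = 5.0
    af: float = 30.0
    tau: float = 4.4
    t_half: float = 10.0
    minor_cap: float = math.inf  # = line width for confined platelets
    frame_interval: float = 15.0  # s
    duration: float = 40.0  # min
    aspect0: float = 1.3
    aspect_final: float = 1.05
    aspect_tau: float = 5.0  # min
    theta0: float = 0.0  # orientation at t = 0, deg
    theta_final: float = 0.0
    angle_tau: float = 4.0  # min; relaxation toward theta_final
    center: tuple[float, float] = (0.0, 0.0)  # um, from field centre

    def __post_init__(self) -> None:
        if self.condition not in ("confined", "control"):
            raise ValueError("condition must be 'confined' or 'control'")
        if self.af < 2.0 * self.a0:
            raise ValueError("Af must be at least 2*A0 for a spreading platelet")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.t_half + 3.0 * self.tau - 1e-9:
            raise ValueError("duration must be at least t_half + 3*tau")

    # -- analytic trajectories ------------------------------------------------

    def area(self, t_min):
        return logistic_area(t_min, self.a0, self.af, self.t_half, self.tau)

    def aspect(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return self.aspect_final + (self.aspect0 - self.aspect_final) * np.exp(
            -np.maximum(t, 0.0) / self.aspect_tau
        )

    def axes(self, t_min):
        """Analytic (major, minor) full axis lengths in um."""
        area = self.area(t_min)
        minor_raw = np.sqrt(4.0 * area / (np.pi * self.aspect(t_min)))
        minor = np.minimum(minor_raw, self.minor_cap)
        major = 4.0 * area / (np.pi * minor)
        return major, minor

    def orientation(self, t_min):
        from .morpho import wrap_axial

        t = np.asarray(t_min, dtype=float)
        delta = wrap_axial(self.theta0 - self.theta_final)
        return wrap_axial(self.theta_final + delta * np.exp(-np.maximum(t, 0.0) / self.angle_tau))


@dataclass
class GroundTruthTrace:
    """Analytic per-frame trajectory and exact kinetic summary."""

    t_min: np.ndarray
    area: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    orientation: np.ndarray
    spreading_time: float  # exact 25-75 % interval of the analytic A(t)
    t0: float  # exact 25 %-above-initial onset time (min)
    final_aspect: float
    final_angle: float
    minor_plateau: float  # analytic minor averaged over the last 10 min
    params: SpreadingParams


def _ground_truth(params: SpreadingParams) -> GroundTruthTrace:
    nframes = int(round(params.duration * 60.0 / params.frame_interval)) + 1
    t = np.arange(nframes) * params.frame_interval / 60.0
    area = params.area(t)
    major, minor = params.axes(t)
    orient = params.orientation(t)
    st = measured_interval(params.tau, params.t_half, params.duration)
    a_start = float(params.area(0.0))
    s_t0 = (1.25 * a_start - params.a0) / (params.af - params.a0)
    t0 = params.t_half + params.tau * math.log(s_t0 / (1.0 - s_t0))
    last10 = t >= params.duration - 10.0
    return GroundTruthTrace(
        t_min=t,
        area=area,
        major=major,
        minor=minor,
        orientation=np.asarray(orient, dtype=float),
        spreading_time=st,
        t0=t0,
        final_aspect=float(major[-1] / minor[-1]),
        final_angle=float(np.asarray(orient)[-1]),
        minor_plateau=float(minor[last10].mean()),
        params=params,
    )


def _rasterize_ellipse(
    shape: tuple[int, int],
    pixel_size: float,
    center: tuple[float, float],
    major: float,
    minor: float,
    orientation_deg: float,
) -> np.ndarray:
    """Pixel-centre-inside rasterization of an ellipse (centre in um from
    the field centre)."""
    ny, nx = shape
    X, Y = _pixel_centres(nx, ny, pixel_size)
    th = math.radians(orientation_deg)
    dx, dy = X - center[0], Y - center[1]
    xi = dx * math.cos(th) + dy * math.sin(th)
    eta = -dx * math.sin(th) + dy * math.cos(th)
    a, b = major / 2.0, minor / 2.0
    half_w, half_h = nx * pixel_size / 2.0, ny * pixel_size / 2.0
    ext_x = math.hypot(a * math.cos(th), b * math.sin(th))
    ext_y = math.hypot(a * math.sin(th), b * math.cos(th))
    if (
        abs(center[0]) + ext_x > half_w + 1e-9
        or abs(center[1]) + ext_y > half_h + 1e-9
    ):
        raise GeometryError("ellipse exceeds the field")
    return (xi / a) ** 2 + (eta / b) ** 2 <= 1.0


def simulate_spreading_sequence(
    pattern: PatternMask, params: SpreadingParams
) -> tuple[MaskSequence, GroundTruthTrace]:
    """Rasterize one platelet's spreading trajectory on the pattern grid."""
    truth = _ground_truth(params)
    shape = pattern.mask.shape
    masks = np.empty((truth.t_min.size,) + shape, dtype=bool)
    for k in range(truth.t_min.size):
        masks[k] = _rasterize_ellipse(
            shape,
            pattern.pixel_size,
            params.center,
            truth.major[k],
            truth.minor[k],
            truth.orientation[k],
        )
    seq = MaskSequence(
        masks=masks, timestamps=truth.t_min * 60.0, pixel_size=pattern.pixel_size
    )
    return seq, truth


# ---------------------------------------------------------------------------
# cohort-level spreading configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpreadingCohortSpec:
    """Distributional parameters for one condition's spreading cohort.

    Medians follow the study conditions; log-normal jitter provides
    platelet-to-platelet variability while preserving the medians.
    """

    condition: str
    n: int
    area_median: float = 30.0
    area_sigma_log: float = 0.15
    a0_median: float = 5.0
    a0_sigma_log: float = 0.15
    spreading_time_median: float = 8.7
    time_sigma_log: float = 0.05
    t_half: float = 10.0
    aspect0: float = 1.3
    aspect_final_median: float = 1.05
    aspect_sigma_log: float = 0.08
    aspect_tau: float = 5.0
    angle_sigma: Optional[float] = None  # deg; None = uniform orientation
    angle_tau: float = 4.0
    duration: float = 40.0
    frame_interval: float = 15.0
    center_jitter: float = 0.15  # um, across-line placement sd (confined)
    along_jitter: float = 2.0  # um, placement range along the line / field


def spreading_defaults(condition: str, n: Optional[int] = None) -> SpreadingCohortSpec:
    """Study-condition cohort defaults (n = 30 confined / 38 control)."""
    if condition == "confined":
        return SpreadingCohortSpec(
            condition="confined",
            n=30 if n is None else n,
            spreading_time_median=15.0,
            t_half=12.0,
            angle_sigma=6.0,
        )
    if condition == "control":
        return SpreadingCohortSpec(
            condition="control",
            n=38 if n is None else n,
            spreading_time_median=8.7,
            t_half=10.0,
            angle_sigma=None,
        )
    raise ValueError("condition must be 'confined' or 'control'")


def draw_spreading_params(
    spec: SpreadingCohortSpec, pattern: PatternMask, rng: np.random.Generator
) -> SpreadingParams:
    """Draw one platelet's parameters from the cohort distributions.

    Draw order (fixed for reproducibility): final area, initial area,
    spreading-time target, final aspect, initial orientation, final
    orientation, centre position.
    """
    af_obs = spec.area_median * math.exp(rng.normal(0.0, spec.area_sigma_log))
    a0 = spec.a0_median * math.exp(rng.normal(0.0, spec.a0_sigma_log))
    target = spec.spreading_time_median * math.exp(rng.normal(0.0, spec.time_sigma_log))
    tau, t_half = calibrate_tau(target, spec.t_half, spec.duration)
    # feasibility cap: within a finite window the logistic cannot be both
    # slow enough to exceed ~15.6 min (25-75 %) and still double its
    # observed initial area; clamp the slowest draws at the boundary
    s1_bound = 1.0 / (1.0 + math.exp(-3.0))
    tau_max = spec.duration / (3.0 - _logit(s1_bound / 2.25))
    if tau > tau_max:
        tau = tau_max
        t_half = min(spec.t_half, spec.duration - 3.0 * tau)
    # area_median parameterizes the observable final-frame area; the
    # logistic asymptote Af is set so that A(duration) hits it exactly
    s0 = 1.0 / (1.0 + math.exp(t_half / tau))
    s1 = 1.0 / (1.0 + math.exp(-(spec.duration - t_half) / tau))
    # clamp A0 so the *observed* first-frame area A(0) = A0 + r (Af_obs - A0)
    # leaves headroom for the factor-2 spreading criterion to fire
    r = s0 / s1
    if r < 1.0 / 2.2:
        a0 = min(a0, max(af_obs * (1.0 / 2.2 - r) / (1.0 - r), 0.5))
    else:
        a0 = 0.5
    af = a0 + (af_obs - a0) / s1
    aspect_final = max(
        spec.aspect_final_median * math.exp(rng.normal(0.0, spec.aspect_sigma_log)),
        1.0,
    )
    theta0 = rng.uniform(-90.0, 90.0)
    if spec.angle_sigma is None:
        theta_final = theta0
        minor_cap = math.inf
        cx = rng.uniform(-spec.along_jitter, spec.along_jitter)
        cy = rng.uniform(-spec.along_jitter, spec.along_jitter)
        center = (cx, cy)
    else:
        from .morpho import wrap_axial

        theta_final = float(
            wrap_axial(pattern.orientation + rng.normal(0.0, spec.angle_sigma))
        )
        minor_cap = pattern.line_width
        along = rng.uniform(-spec.along_jitter, spec.along_jitter)
        across = rng.normal(0.0, spec.center_jitter)
        th = math.radians(pattern.orientation)
        center = (
            along * math.cos(th) - across * math.sin(th),
            along * math.sin(th) + across * math.cos(th),
        )
    return SpreadingParams(
        condition=spec.condition,
        a0=a0,
        af=af,
        tau=tau,
        t_half=t_half,
        minor_cap=minor_cap,
        frame_interval=spec.frame_interval,
        duration=spec.duration,
        aspect0=spec.aspect0,
        aspect_final=aspect_final,
        theta0=theta0,
        theta_final=theta_final,
        angle_tau=spec.angle_tau,
        center=center,
    )


def generate_spreading_cohort(
    spec: SpreadingCohortSpec,
    pattern: PatternMask,
    rng: np.random.Generator,
) -> Iterator[tuple[MaskSequence, GroundTruthTrace]]:
    """Yield (sequence, ground truth) pairs for one condition.

    Sequences are yielded one at a time so cohorts never need to be held
    in memory at once.
    """
    for _ in range(spec.n):
        params = draw_spreading_params(spec, pattern, rng)
        yield simulate_spreading_sequence(pattern, params)


# ---------------------------------------------------------------------------
# platelet surfaces (topography + modulus ground truth)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceSpec:
    """Shape and mechanics of one synthetic platelet surface.

    Heights in um, moduli in kPa, lengths in um.  Confined platelets are
    paraboloid caps clipped to the line (no distinct lamellipodium, so
    their pixel-height distribution is uniform and the height skewness is
    ~0); controls are a flat lamellipodial rim of height
    ``lamellipodium_height`` with a central cosine-squared dome of peak
    ``body_height`` inside ``body_fraction`` of the footprint radius
    (flat-dominated, positive skewness).
    """

    footprint_area: float = 30.0
    body_height: float = 0.8
    lamellipodium_height: float = 0.4
    body_fraction: float = 0.55
    modulus_base: float = 4.2
    edge_band_modulus: float = 0.0  # 0 = no band
    edge_band_width: float = 0.0  # um, from the pattern line edge
    substrate_modulus: float = 1.0e6

    def __post_init__(self) -> None:
        if self.body_height < 0 or self.lamellipodium_height < 0:
            raise ValueError("heights must be non-negative")
        if self.modulus_base <= 0 or self.substrate_modulus <= 0:
            raise ValueError("moduli must be positive")
        if self.substrate_modulus < 1e3 * self.modulus_base:
            raise ValueError("substrate must be effectively rigid (>= 1e3 x base)")


def surface_defaults(condition: str) -> SurfaceSpec:
    """Study-condition surface defaults.

    Mean heights are set so footprint area x mean height reproduces the
    printed volumes (12 fL confined, ~14 fL control over ~30 um^2);
    modulus bases are the printed condition medians, with a stiffened
    band near the line edges for confined platelets.
    """
    if condition == "confined":
        # paraboloid: mean height = body_height / 2 = 0.4 um -> 12 fL
        return SurfaceSpec(
            footprint_area=30.0,
            body_height=0.8,
            lamellipodium_height=0.0,
            modulus_base=2.3,
            edge_band_modulus=4.6,
            edge_band_width=0.5,
        )
    if condition == "control":
        # rim 0.4 um + dome to 1.14 um over 55 % of the radius -> mean 0.467 um
        return SurfaceSpec(
            footprint_area=30.0,
            body_height=1.14,
            lamellipodium_height=0.4,
            body_fraction=0.55,
            modulus_base=4.2,
        )
    raise ValueError("condition must be 'confined' or 'control'")


def synthesize_platelet_surface(
    pattern: PatternMask,
    surf: SurfaceSpec,
    condition: str,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate (height map [um], modulus map [kPa], ground truth).

    The maps live on the pattern's grid.  The modulus map holds
    ``substrate_modulus`` outside the footprint, ``modulus_base``
    inside, overridden by ``edge_band_modulus`` within
    ``edge_band_width`` of a pattern line edge (confined only).
    """
    ny, nx = pattern.mask.shape
    px = pattern.pixel_size
    X, Y = _pixel_centres(nx, ny, px)
    if condition == "confined":
        semi_minor = pattern.line_width / 2.0
        semi_major = surf.footprint_area / (math.pi * semi_minor)
        th = math.radians(pattern.orientation)
        dx, dy = X - center[0], Y - center[1]
        xi = dx * math.cos(th) + dy * math.sin(th)
        eta = -dx * math.sin(th) + dy * math.cos(th)
        rho2 = (xi / semi_major) ** 2 + (eta / semi_minor) ** 2
        footprint = rho2 <= 1.0
        height = np.where(footprint, surf.body_height * (1.0 - rho2), 0.0)
    elif condition == "control":
        radius = math.sqrt(surf.footprint_area / math.pi)
        r = np.hypot(X - center[0], Y - center[1])
        footprint = r <= radius
        body_r = surf.body_fraction * radius
        bump = np.cos(0.5 * np.pi * np.minimum(r / body_r, 1.0)) ** 2
        height = np.where(
            footprint,
            surf.lamellipodium_height
            + (surf.body_height - surf.lamellipodium_height) * bump,
            0.0,
        )
    else:
        raise ValueError("condition must be 'confined' or 'control'")
    if abs(center[0]) > nx * px / 2 or abs(center[1]) > ny * px / 2:
        raise GeometryError("platelet centre outside the field")

    modulus = np.full((ny, nx), surf.substrate_modulus, dtype=float)
    modulus[footprint] = surf.modulus_base
    if condition == "confined" and surf.edge_band_width > 0 and surf.edge_band_modulus > 0:
        d_line = _across_line_distance(pattern, X, Y)
        on_line = np.abs(d_line) <= pattern.line_width / 2.0
        near_edge = (pattern.line_width / 2.0 - np.abs(d_line)) <= surf.edge_band_width
        band = footprint & on_line & near_edge
        modulus[band] = surf.edge_band_modulus

    h = height[footprint]
    area = float(footprint.sum()) * px**2
    centred = h - h.mean()
    m2 = float(np.mean(centred**2))
    skew = float(np.mean(centred**3) / m2**1.5) if m2 > 0 else 0.0
    truth = {
        "condition": condition,
        "area_um2": area,
        "mean_height_um": float(h.mean()),
        "volume_fl": float(h.mean() * area),
        "height_p99_um": float(np.percentile(h, 99)),
        "height_skewness": skew,
        "median_modulus_kpa": float(np.median(modulus[footprint])),
        "footprint": footprint,
    }
    return height, modulus, truth


# ---------------------------------------------------------------------------
# SICM forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SICMSimParams:
    """Forward-model constants for I-z curve synthesis.

    All lengths in nm except ``pixel_size`` (um); pressures in kPa;
    currents normalized to ``i_sat``.  ``tilt`` is the sample plane slope
    in nm per um of (x, y).  The defaults are the package's simulator
    constants, chosen so the deformation distance is a few tens of nm
    for kPa-scale moduli at 10 kPa — resolvable at the 5-nm sampling.
    """

    r_i: float = 90.0  # inner tip radius
    lambda_c: float = 20.0  # current decay length
    lambda_p: float = 500.0  # pressure-interaction decay length
    c_d: float = 1.0  # deformation coefficient
    h_c: float = 100.0  # thickness-factor constant
    pressure: float = 10.0  # kPa
    i_sat: float = 1.0
    trigger: float = 0.98
    z_step: float = 5.0
    noise_sigma: float = 1.0e-3  # per-sample current noise, fraction of i_sat
    pixel_size: float = 0.4  # um
    tilt: tuple[float, float] = (20.0, 10.0)  # nm/um in x and y

    def __post_init__(self) -> None:
        if not 0.0 < self.trigger < 1.0:
            raise ValueError("trigger must lie in (0, 1)")
        if min(self.lambda_c, self.lambda_p, self.z_step) <= 0:
            raise ValueError("lambda_c, lambda_p and z_step must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def thickness_factor(h_nm, h_c: float):
    """phi(h) = h/(h + h_c); in (0, 1), increasing, -> 1 as h -> inf."""
    h = np.asarray(h_nm, dtype=float)
    return h / (h + h_c)


def trigger_gap(level: float, lambda_c: float) -> float:
    """Gap at which I/I_sat = level, from the hyperbolic current law."""
    return lambda_c * level / (1.0 - level)


def deformation(g, w_max, lambda_p: float):
    """Pressure-induced indentation w(g) = w_max * lambda_p/(lambda_p + g)."""
    return np.asarray(w_max) * lambda_p / (lambda_p + np.asarray(g, dtype=float))


def gap_from_distance(d, w_max, lambda_p: float):
    """Solve g - w(g) = d for the gap g (closed-form quadratic root).

    Monotone in d; valid for d >= -w_max (tip at or above the indented
    contact point).
    """
    d = np.asarray(d, dtype=float)
    w = np.asarray(w_max, dtype=float)
    d = np.maximum(d, -w)  # clamp below contact; curves stop before this
    b = lambda_p - d
    disc = b * b + 4.0 * lambda_p * (d + w)
    return 0.5 * (-b + np.sqrt(np.maximum(disc, 0.0)))


def geometry_factor(
    lambda_c: float, lambda_p: float, level_lo: float = 0.98, level_hi: float = 0.99
) -> float:
    """Dimensionless factor linking dz_def to w_max.

    Between the two current levels the indentation difference is
    ``w(g_lo) - w(g_hi) = w_max * C_geom`` with

        C_geom = lambda_p (g_hi - g_lo) / ((lambda_p + g_lo)(lambda_p + g_hi)).
    """
    g_lo = trigger_gap(level_lo, lambda_c)
    g_hi = trigger_gap(level_hi, lambda_c)
    return lambda_p * (g_hi - g_lo) / ((lambda_p + g_lo) * (lambda_p + g_hi))


def dz_def_closed_form(e_eff_kpa, sim: SICMSimParams, level_hi: float = 0.99):
    """Closed-form deformation distance dz_def = c_d P r_i C_geom / E_eff (nm)."""
    c = geometry_factor(sim.lambda_c, sim.lambda_p, sim.trigger, level_hi)
    return sim.c_d * sim.pressure * sim.r_i * c / np.asarray(e_eff_kpa, dtype=float)


def _effective_modulus(height_um: np.ndarray, modulus_kpa: np.ndarray, sim: SICMSimParams):
    """E_eff = E/phi(h) on sample pixels; phi = 1 on the bare substrate."""
    h_nm = np.asarray(height_um, dtype=float) * 1e3
    phi = np.where(h_nm > 0, thickness_factor(np.maximum(h_nm, 1e-9), sim.h_c), 1.0)
    return np.asarray(modulus_kpa, dtype=float) / phi


def apparent_trigger_height(
    height_um: np.ndarray, modulus_kpa: np.ndarray, sim: SICMSimParams
) -> np.ndarray:
    """Noiseless trigger topography relative to the substrate (um).

    The trigger is reached lower on soft pixels by w(g_trigger); this is
    the topography an ideal (noise-free, untilted) measurement records,
    and the reference for recovery checks since the bias is part of the
    measurement process being emulated.
    """
    e_eff = _effective_modulus(height_um, modulus_kpa, sim)
    w_max = sim.c_d * sim.pressure * sim.r_i / e_eff
    g_t = trigger_gap(sim.trigger, sim.lambda_c)
    w_t = deformation(g_t, w_max, sim.lambda_p)
    w_sub = float(
        deformation(g_t, sim.c_d * sim.pressure * sim.r_i / 1.0e6, sim.lambda_p)
    )  # negligible reference indentation of a rigid substrate
    return np.asarray(height_um, dtype=float) - (w_t - w_sub) * 1e-3


def simulate_iz_stack(
    height_um: np.ndarray,
    modulus_kpa: np.ndarray,
    sim: SICMSimParams,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> IZStack:
    """Synthesize the full I-z approach-curve stack over the field.

    Curves share a descending z grid (nm) spanning from the far field
    (well above the 99 % current level of the highest pixel) down past
    the lowest trigger point; each pixel's curve ends at its first
    sample below the trigger (later samples are NaN), mirroring the
    instrument's approach stop.
    """
    height_um = np.asarray(height_um, dtype=float)
    modulus_kpa = np.asarray(modulus_kpa, dtype=float)
    if height_um.shape != modulus_kpa.shape:
        raise ValueError("height and modulus maps are not congruent")
    if rng is None:
        rng = np.random.default_rng(seed)
    ny, nx = height_um.shape
    X, Y = _pixel_centres(nx, ny, sim.pixel_size)
    z_surf = height_um * 1e3 + sim.tilt[0] * X + sim.tilt[1] * Y

    e_eff = _effective_modulus(height_um, modulus_kpa, sim)
    w_max = sim.c_d * sim.pressure * sim.r_i / e_eff
    g_t = trigger_gap(sim.trigger, sim.lambda_c)
    g99 = trigger_gap(0.99, sim.lambda_c)
    z_trig = z_surf + g_t - deformation(g_t, w_max, sim.lambda_p)
    z_99 = z_surf + g99 - deformation(g99, w_max, sim.lambda_p)

    z_max = float(z_99.max()) + 800.0
    z_min = float(z_trig.min()) - 400.0
    ns = int(math.ceil((z_max - z_min) / sim.z_step)) + 1
    z = z_max - np.arange(ns) * sim.z_step

    d = z[None, None, :] - z_surf[..., None]
    g = gap_from_distance(d, w_max[..., None], sim.lambda_p)
    current = sim.i_sat * g / (g + sim.lambda_c)
    if sim.noise_sigma > 0:
        current = current + rng.normal(0.0, sim.noise_sigma * sim.i_sat, current.shape)

    current = current.astype(np.float32)  # storage precision, also used for the stop rule
    below = current < np.float32(sim.trigger * sim.i_sat)
    if not below.any(axis=-1).all():
        raise RuntimeError("a pixel never crossed the trigger; z grid too short")
    stop = np.argmax(below, axis=-1)
    past = np.arange(ns)[None, None, :] > stop[..., None]
    current[past] = np.nan
    return IZStack(
        current=current,
        z=z,
        i_sat=sim.i_sat,
        trigger=sim.trigger,
        pressure_kpa=sim.pressure,
        pixel_size_um=sim.pixel_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SICM cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SICMCohortSpec:
    """Distributional parameters for one condition's SICM cohort.

    One platelet per 64x64-px stack; per-platelet log-normal jitter on
    area, heights and modulus preserves the configured medians.
    """

    condition: str
    n: int
    surface: SurfaceSpec = field(default_factory=lambda: surface_defaults("control"))
    sim: SICMSimParams = field(default_factory=SICMSimParams)
    grid_shape: tuple[int, int] = (64, 64)
    area_sigma_log: float = 0.12
    height_sigma_log: float = 0.08
    modulus_sigma_log: float = 0.08
    center_jitter: float = 1.5  # um


def sicm_defaults(condition: str, n: Optional[int] = None) -> SICMCohortSpec:
    """Study-condition SICM cohorts (n = 27 confined / 15 control)."""
    if condition == "confined":
        return SICMCohortSpec(
            condition="confined",
            n=27 if n is None else n,
            surface=surface_defaults("confined"),
        )
    if condition == "control":
        return SICMCohortSpec(
            condition="control",
            n=15 if n is None else n,
            surface=surface_defaults("control"),
        )
    raise ValueError("condition must be 'confined' or 'control'")


def generate_sicm_cohort(
    spec: SICMCohortSpec, rng: np.random.Generator
) -> Iterator[tuple[IZStack, dict]]:
    """Yield (stack, ground truth) pairs for one condition.

    Draw order per platelet: area, body height, lamellipodium height,
    modulus, centre offsets, then the per-sample current noise.  The
    ground truth dict holds both the geometric surface statistics and
    the *apparent* (noiseless forward-predicted) statistics that include
    the retained pressure-induced topography bias.
    """
    ny, nx = spec.grid_shape
    px = spec.sim.pixel_size
    pattern = generate_pattern(
        PatternSpec(field_size=(nx * px, ny * px), pixel_size=px)
    )
    for _ in range(spec.n):
        area = spec.surface.footprint_area * math.exp(
            rng.normal(0.0, spec.area_sigma_log)
        )
        h_jit = math.exp(rng.normal(0.0, spec.height_sigma_log))
        e_jit = math.exp(rng.normal(0.0, spec.modulus_sigma_log))
        surf = replace(
            spec.surface,
            footprint_area=area,
            body_height=spec.surface.body_height * h_jit,
            lamellipodium_height=spec.surface.lamellipodium_height * h_jit,
            modulus_base=spec.surface.modulus_base * e_jit,
            edge_band_modulus=spec.surface.edge_band_modulus * e_jit,
        )
        if spec.condition == "confined":
            th = math.radians(pattern.orientation)
            along = rng.uniform(-spec.center_jitter, spec.center_jitter)
            center = (along * math.cos(th), along * math.sin(th))
        else:
            center = tuple(rng.uniform(-spec.center_jitter, spec.center_jitter, 2))
        height, modulus, truth = synthesize_platelet_surface(
            pattern, surf, spec.condition, center=center
        )
        stack = simulate_iz_stack(height, modulus, spec.sim, rng=rng)
        footprint = truth.pop("footprint")
        h_app = apparent_trigger_height(height, modulus, spec.sim)
        visible = footprint & (h_app > 0.05)
        ha = h_app[visible]
        truth.update(
            apparent_area_um2=float(visible.sum()) * px**2,
            apparent_mean_height_um=float(ha.mean()),
            apparent_volume_fl=float(ha.mean() * visible.sum() * px**2),
            apparent_height_p99_um=float(np.percentile(ha, 99)),
            target_modulus_kpa=surf.modulus_base,
        )
        yield stack, truth


# ---------------------------------------------------------------------------
# batch fixtures
# ---------------------------------------------------------------------------


def make_cohort(
    out_dir,
    seed: int,
    spreading: Optional[dict[str, SpreadingCohortSpec]] = None,
    sicm: Optional[dict[str, SICMCohortSpec]] = None,
    pattern_spec: Optional[PatternSpec] = None,
    overwrite: bool = False,
) -> dict[str, pd.DataFrame]:
    """Write reproducible cohort fixtures for both conditions.

    Produces, under ``out_dir``: the pattern mask (TIFF + JSON sidecar),
    one multi-page TIFF + timestamp sidecar per spreading sequence, one
    HDF5 stack per SICM platelet, and ground-truth CSV tables.  The same
    seed yields byte-identical ground-truth tables.  Returns the truth
    tables keyed by ``"spreading"`` and ``"sicm"``.
    """
    from pathlib import Path

    from . import io as plio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spreading is None:
        spreading = {c: spreading_defaults(c) for c in ("confined", "control")}
    if sicm is None:
        sicm = {c: sicm_defaults(c) for c in ("confined", "control")}
    if pattern_spec is None:
        pattern_spec = PatternSpec()
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}

    pattern = generate_pattern(pattern_spec)
    plio.write_pattern(out / "pattern.tif", pattern, overwrite=overwrite)

    rows = []
    for cond, spec in spreading.items():
        for i, (seq, truth) in enumerate(
            generate_spreading_cohort(spec, pattern, rng)
        ):
            name = f"spreading_{cond}_{i:03d}"
            plio.write_mask_sequence(out / f"{name}.tif", seq, overwrite=overwrite)
            rows.append(
                {
                    "condition": cond,
                    "platelet": i,
                    "file": f"{name}.tif",
                    "initial_area_um2": truth.area[0],
                    "final_area_um2": truth.area[-1],
                    "spreading_time_min": truth.spreading_time,
                    "t0_min": truth.t0,
                    "final_aspect_ratio": truth.final_aspect,
                    "final_angle_deg": truth.final_angle,
                    "minor_plateau_um": truth.minor_plateau,
                }
            )
    tables["spreading"] = pd.DataFrame(rows)
    tables["spreading"].to_csv(out / "spreading_truth.csv", index=False)

    rows = []
    for cond, spec in sicm.items():
        for i, (stack, truth) in enumerate(generate_sicm_cohort(spec, rng)):
            name = f"sicm_{cond}_{i:03d}"
            plio.write_iz_stack(out / f"{name}.h5", stack, overwrite=overwrite)
            rows.append({"condition": cond, "platelet": i, "file": f"{name}.h5", **truth})
    tables["sicm"] = pd.DataFrame(rows)
    tables["sicm"].to_csv(out / "sicm_truth.csv", index=False)
    return tables
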