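"""Shape and spreading-kinetics morphometry for platelet mask sequences.

The measurement chain implemented here follows the standard analysis of
micropattern spreading experiments: each binary platelet mask is reduced
to an area-matched equivalent ellipse computed from its second central
image moments; platelets are followed through a time-lapse sequence with
a greedy nearest-neighbour tracker; a platelet counts as *spreading* if
its area at least doubles during the observation; and kinetic metrics
(25-75 % spreading time, early axis growth rates, final alignment) are
read off the per-track traces.

Conventions
-----------
* Lengths in micrometres, areas in square micrometres, times in seconds
  inside traces; kinetic metrics are reported in minutes.
* Orientations are axial angles in degrees on the half-open interval
  (-90, 90], measured from the +x axis (image columns); the pattern
  direction defines 0 deg for alignment angles.
* Area is always pixel count times pixel_size**2 — the ellipse is fitted
  to have exactly that area, never the other way round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ShapeMeasurement",
    "ShapeTrace",
    "SpreadingMetrics",
    "measure_mask",
    "wrap_axial",
    "alignment_angle",
    "overlap_fraction",
    "track_platelets",
    "classify_spreading",
    "spreading_time",
    "early_growth_rates",
]


class EmptyMaskError(ValueError):
    """Raised when a shape operation receives an empty mask."""


@dataclass(frozen=True)
class ShapeMeasurement:
    """Equivalent-ellipse measurement of one binary mask.

    ``major_axis``/``minor_axis`` are full axis lengths (um) of the
    moment ellipse rescaled to have exactly the mask's pixel area.
    ``overlap`` is the fraction of mask pixels on the pattern (set by
    :func:`overlap_fraction`, otherwise None).  ``degenerate`` flags
    one-pixel-thin masks whose minor axis was floored at one pixel.
    """

    area: float
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float
    aspect_ratio: float
    overlap: Optional[float] = None
    degenerate: bool = False


@dataclass
class ShapeTrace:
    """Per-track time series of shape measurements."""

    track_id: int
    t: np.ndarray  # seconds, strictly increasing
    area: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    orientation: np.ndarray
    centroid: np.ndarray  # (n, 2) in um
    frames: np.ndarray  # frame indices
    is_spreading: bool = False
    t0: Optional[float] = None  # spreading onset (s), set if is_spreading

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class SpreadingMetrics:
    """Per-platelet spreading summary (times in min, rates in um/min)."""

    track_id: int
    spreading_time: float
    early_major_rate: Optional[float]
    early_minor_rate: Optional[float]
    final_aspect_ratio: float
    final_alignment_angle: float
    initial_area: float
    final_area: float


def wrap_axial(angle_deg) -> np.ndarray | float:
    """Map an angle (deg) to the axial interval (-90, 90]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = ((a + 90.0) % 180.0) - 90.0
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def measure_mask(mask: np.ndarray, pixel_size: float) -> ShapeMeasurement:
    """Fit an area-matched equivalent ellipse to a binary mask.

    The second central moments (mu20, mu02, mu11) of the pixel-centre
    point set give the orientation ``0.5 * atan2(2 mu11, mu20 - mu02)``
    and raw semi-axes ``a0 = 2 sqrt(lam1)``, ``b0 = 2 sqrt(lam2)`` from
    the eigenvalues ``lam1 >= lam2`` of the moment matrix.  Both axes are
    then rescaled by ``s = sqrt(area / (pi a0 b0))`` so that the reported
    ellipse has exactly the platelet's pixel area.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n == 0:
        raise EmptyMaskError("cannot measure an empty mask")
    x = (cols + 0.5) * pixel_size
    y = (rows + 0.5) * pixel_size
    area = n * pixel_size**2
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    orientation = wrap_axial(np.rad2deg(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)))

    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    tr, det = mu20 + mu02, mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = max(tr / 2.0 - np.sqrt(disc), 0.0)
    a0 = 2.0 * np.sqrt(lam1)
    b0 = 2.0 * np.sqrt(lam2)

    degenerate = False
    if b0 * a0 <= 0:  # 1-pixel-thin mask: floor the minor axis at one pixel
        degenerate = True
        b0 = pixel_size / 2.0
        if a0 <= 0:  # single pixel
            a0 = pixel_size / 2.0
    s = np.sqrt(area / (np.pi * a0 * b0))
    major = 2.0 * a0 * s
    minor = 2.0 * b0 * s
    if minor < pixel_size:
        degenerate = True
        minor = pixel_size
    return ShapeMeasurement(
        area=float(area),
        centroid=(float(cx), float(cy)),
        major_axis=float(major),
        minor_axis=float(minor),
        orientation=float(orientation),
        aspect_ratio=float(major / minor),
        degenerate=degenerate,
    )


def alignment_angle(orientation_deg: float, pattern_orientation_deg: float) -> float:
    """Axial difference between a platelet orientation and the pattern
    direction, mapped to (-90, 90]."""
    return float(
        wrap_axial(np.asarray(wrap_axial(orientation_deg)) - np.asarray(wrap_axial(pattern_orientation_deg)))
    )


def overlap_fraction(mask: np.ndarray, pattern: np.ndarray) -> float:
    """Fraction of mask pixels that lie on the (pattern) fibrinogen mask."""
    mask = np.asarray(mask, dtype=bool)
    pattern = np.asarray(pattern, dtype=bool)
    if mask.shape != pattern.shape:
        raise ValueError("mask and pattern grids are not congruent")
    n = mask.sum()
    if n == 0:
        raise EmptyMaskError("cannot compute overlap of an empty mask")
    return float(np.logical_and(mask, pattern).sum() / n)


def _frame_objects(mask: np.ndarray, pixel_size: float):
    """Label one frame and measure each connected component."""
    labels, nlab = ndi.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3), int))
    out = []
    for lab in range(1, nlab + 1):
        out.append(measure_mask(labels == lab, pixel_size))
    return out


def track_platelets(
    masks: Sequence[np.ndarray] | np.ndarray,
    timestamps: Sequence[float],
    pixel_size: float,
    d_max: float = 2.0,
    min_length: int = 3,
) -> list[ShapeTrace]:
    """Track platelets through a mask sequence by nearest-neighbour matching.

    Objects in consecutive frames are matched greedily by centroid
    distance; a match is accepted only if the displacement is at most
    ``d_max`` (um per frame).  Unmatched objects start new tracks, and
    tracks shorter than ``min_length`` frames are discarded.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    measured = [_frame_objects(m, pixel_size) for m in masks]
    if len(measured) != timestamps.size:
        raise ValueError("number of frames and timestamps differ")

    tracks: list[dict] = []  # each: {"frames": [], "meas": [], "open": bool}
    active: list[int] = []  # indices into tracks for objects in previous frame
    for fi, objs in enumerate(measured):
        cand = []
        for ti_pos, ti in enumerate(active):
            prev = tracks[ti]["meas"][-1]
            for oi, obj in enumerate(objs):
                d = np.hypot(
                    obj.centroid[0] - prev.centroid[0], obj.centroid[1] - prev.centroid[1]
                )
                if d <= d_max:
                    cand.append((d, ti, oi))
        cand.sort(key=lambda c: c[0])
        used_tracks, used_objs = set(), set()
        next_active = []
        for d, ti, oi in cand:
            if ti in used_tracks or oi in used_objs:
                continue
            used_tracks.add(ti)
            used_objs.add(oi)
            tracks[ti]["frames"].append(fi)
            tracks[ti]["meas"].append(objs[oi])
            next_active.append(ti)
        for oi, obj in enumerate(objs):
            if oi not in used_objs:
                tracks.append({"frames": [fi], "meas": [obj]})
                next_active.append(len(tracks) - 1)
        active = next_active

    out = []
    for tid, tr in enumerate(tracks):
        if len(tr["frames"]) < min_length:
            continue
        meas = tr["meas"]
        frames = np.asarray(tr["frames"])
        out.append(
            ShapeTrace(
                track_id=len(out),
                t=timestamps[frames],
                area=np.array([m.area for m in meas]),
                major=np.array([m.major_axis for m in meas]),
                minor=np.array([m.minor_axis for m in meas]),
                orientation=np.array([m.orientation for m in meas]),
                centroid=np.array([m.centroid for m in meas]),
                frames=frames,
            )
        )
    return out


def classify_spreading(trace: ShapeTrace) -> bool:
    """Classify a track as spreading and set its onset time.

    A platelet is *spreading* iff its maximum area reaches at least twice
    the initial (first-frame) area.  The onset ``t0`` is the first time
    the area reaches 1.25x the initial area, linearly interpolated
    between the bracketing frames.
    """
    if len(trace) < 3:
        raise ValueError("classify_spreading needs a trace of length >= 3")
    a0 = trace.area[0]
    spreading = bool(trace.area.max() >= 2.0 * a0)
    trace.is_spreading = spreading
    trace.t0 = _first_upward_crossing(trace.t, trace.area, 1.25 * a0) if spreading else None
    return spreading


def _first_upward_crossing(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    """Time of the first upward crossing of `level`, linearly interpolated."""
    if y[0] >= level:
        return float(t[0])
    above = y >= level
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    # the first index k with y[k] < level <= y[k+1]
    for k in idx:
        if y[k + 1] > y[k]:
            frac = (level - y[k]) / (y[k + 1] - y[k])
            return float(t[k] + frac * (t[k + 1] - t[k]))
        return float(t[k + 1])
    return None


def spreading_time(trace: ShapeTrace) -> float:
    """25-75 % spreading time in minutes.

    The initial and final areas (first and last frame) define 0 and
    100 %; the spreading time is the interval between the first upward
    crossings of the 25 % and 75 % levels of that range, each located by
    linear interpolation between the bracketing frames.  Returns NaN for
    traces that never reach the 75 % level (flagged as excluded).
    """
    if not trace.is_spreading:
        raise ValueError("spreading_time is defined only for spreading traces")
    a_init, a_final = trace.area[0], trace.area[-1]
    if a_final <= a_init:
        return float("nan")
    norm = (trace.area - a_init) / (a_final - a_init)
    t25 = _first_upward_crossing(trace.t, norm, 0.25)
    t75 = _first_upward_crossing(trace.t, norm, 0.75)
    if t25 is None or t75 is None:
        return float("nan")
    return (t75 - t25) / 60.0


def early_growth_rates(
    trace: ShapeTrace, window_min: float = 5.0
) -> tuple[Optional[float], Optional[float]]:
    """Early major/minor axis growth rates (um/min).

    Ordinary least-squares slope of the axis lengths versus time over
    the frames with ``t0 <= t <= t0 + window_min`` minutes.  Returns
    (None, None) when fewer than 3 frames fall in the window.
    """
    if not trace.is_spreading or trace.t0 is None:
        raise ValueError("early_growth_rates is defined only for spreading traces")
    sel = (trace.t >= trace.t0) & (trace.t <= trace.t0 + window_min * 60.0)
    if sel.sum() < 3:
        return None, None
    t_min = trace.t[sel] / 60.0
    major_rate = np.polyfit(t_min, trace.major[sel], 1)[0]
    minor_rate = np.polyfit(t_min, trace.minor[sel], 1)[0]
    return float(major_rate), float(minor_rate)
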