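"""End-to-end orchestration: config, cohort runs, and report tables.

Two pipelines reproduce the figure-level statistics of the confinement
study from synthetic (or user-supplied) data:

* :func:`run_spreading_pipeline` — time-lapse mask sequences ->
  tracking -> spreading classification -> kinetic metrics -> Dunn
  comparisons (spreading time, growth rates) and Rayleigh uniformity of
  the final alignment angles.
* :func:`run_sicm_pipeline` — I-z stacks -> topography -> leveling ->
  segmentation -> modulus inversion -> bottom-effect correction ->
  per-platelet records -> Dunn comparisons across conditions.

Both are deterministic given ``(config, seed)``.  Outputs are long- and
wide-format CSV tables plus a nested dict of statistics (Dunn tables,
Rayleigh results, box summaries per condition).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import morpho, stats
from .core import IZStack, MaskSequence, PatternMask
from .io import read_iz_stack, read_mask_sequence, read_pattern, write_iz_stack  # noqa: F401
from .sicmproc import (
    SICMAnalysisParams,
    correct_bottom_effect,
    extract_dz,
    extract_topography,
    invert_modulus,
    level_tilt,
    platelet_statistics,
    segment_platelets,
    smooth_within_mask,
)
from .synthgen import (
    PatternSpec,
    SICMCohortSpec,
    SpreadingCohortSpec,
    generate_pattern,
    generate_sicm_cohort,
    generate_spreading_cohort,
    sicm_defaults,
    spreading_defaults,
)

__all__ = [
    "RunConfig",
    "config_from_dict",
    "load_config",
    "run_spreading_pipeline",
    "run_sicm_pipeline",
    "analyze_spreading_sequence",
    "process_iz_stack",
    "read_iz_stack",
    "write_iz_stack",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Versioned run configuration.

    ``mode`` is one of ``simulate`` (write fixtures), ``analyze``
    (consume files under ``input_dir``) or ``full`` (simulate in memory
    and analyze).  Acquisition defaults mirror the study conditions;
    the invented simulator constants live in the ``model_constants``
    block of the YAML schema.
    """

    schema_version: int = 1
    mode: str = "full"
    seed: int = 0
    out_dir: Optional[str] = None
    input_dir: Optional[str] = None
    pattern: PatternSpec = field(default_factory=PatternSpec)
    spreading: dict = field(
        default_factory=lambda: {c: spreading_defaults(c) for c in ("confined", "control")}
    )
    sicm: dict = field(
        default_factory=lambda: {c: sicm_defaults(c) for c in ("confined", "control")}
    )
    analysis: SICMAnalysisParams = field(default_factory=SICMAnalysisParams)
    d_max_um: float = 2.0
    min_track_length: int = 3

    def digest(self) -> str:
        """Stable hash of the configuration (logged with every run)."""
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _update_dataclass(base, updates: dict):
    fields = {f.name for f in dataclasses.fields(base)}
    unknown = set(updates) - fields
    if unknown:
        raise ValueError(f"unknown config keys for {type(base).__name__}: {sorted(unknown)}")
    coerced = {}
    for key, val in updates.items():
        cur = getattr(base, key)
        if isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            val = tuple(val)
        coerced[key] = val
    return dataclasses.replace(base, **coerced)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a (YAML-loaded) nested dict."""
    raw = dict(raw or {})
    version = raw.pop("schema_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config schema_version {version}")
    cfg = RunConfig()
    model_constants = raw.pop("model_constants", {})
    pattern = raw.pop("pattern", {})
    spreading = raw.pop("spreading", {})
    sicm = raw.pop("sicm", {})
    analysis = raw.pop("analysis", {})
    cfg = _update_dataclass(cfg, raw)
    cfg.pattern = _update_dataclass(cfg.pattern, pattern)
    for cond, upd in spreading.items():
        base = cfg.spreading.get(cond, spreading_defaults(cond))
        cfg.spreading[cond] = _update_dataclass(base, upd)
    for cond, upd in sicm.items():
        base = cfg.sicm.get(cond, sicm_defaults(cond))
        sim_upd = dict(model_constants)
        sim_upd.update(upd.pop("sim", {}))
        if sim_upd:
            upd = dict(upd, sim=_update_dataclass(base.sim, sim_upd))
        cfg.sicm[cond] = _update_dataclass(base, upd)
    if model_constants:
        shared = {
            k: v
            for k, v in model_constants.items()
            if k in {f.name for f in dataclasses.fields(SICMAnalysisParams)}
        }
        analysis = {**shared, **analysis}
    cfg.analysis = _update_dataclass(cfg.analysis, analysis)
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# spreading pipeline
# ---------------------------------------------------------------------------


def _final_frame_overlap(seq: MaskSequence, pattern: PatternMask, centroid) -> float:
    """Overlap of the final-frame component nearest a track centroid."""
    final = seq.masks[-1]
    labels, nlab = ndi.label(final, structure=np.ones((3, 3), int))
    if nlab == 0:
        return float("nan")
    j = int(centroid[0] / seq.pixel_size)
    i = int(centroid[1] / seq.pixel_size)
    i = np.clip(i, 0, final.shape[0] - 1)
    j = np.clip(j, 0, final.shape[1] - 1)
    lab = labels[i, j]
    if lab == 0:  # centroid off the object (concave shapes): nearest component
        ii, jj = np.nonzero(labels)
        k = np.argmin((ii - i) ** 2 + (jj - j) ** 2)
        lab = labels[ii[k], jj[k]]
    return morpho.overlap_fraction(labels == lab, pattern.mask)


def analyze_spreading_sequence(
    seq: MaskSequence,
    pattern: PatternMask,
    d_max_um: float = 2.0,
    min_track_length: int = 3,
) -> list[dict]:
    """Track and measure one field of view; one row per spreading track.

    Nonspreading tracks are excluded from kinetic metrics (a row with
    ``is_spreading=False`` and NaN metrics is still emitted so cohort
    counts remain auditable).
    """
    tracks = morpho.track_platelets(
        seq.masks, seq.timestamps, seq.pixel_size, d_max=d_max_um, min_length=min_track_length
    )
    rows = []
    for trace in tracks:
        spreading = morpho.classify_spreading(trace)
        row = {
            "track_id": trace.track_id,
            "is_spreading": spreading,
            "initial_area_um2": float(trace.area[0]),
            "final_area_um2": float(trace.area[-1]),
            "n_frames": len(trace),
        }
        if spreading:
            st = morpho.spreading_time(trace)
            major_rate, minor_rate = morpho.early_growth_rates(trace)
            row.update(
                spreading_time_min=st,
                early_major_rate_um_min=np.nan if major_rate is None else major_rate,
                early_minor_rate_um_min=np.nan if minor_rate is None else minor_rate,
                final_major_um=float(trace.major[-1]),
                final_minor_um=float(trace.minor[-1]),
                final_aspect_ratio=float(trace.major[-1] / trace.minor[-1]),
                final_alignment_angle_deg=morpho.alignment_angle(
                    trace.orientation[-1], pattern.orientation
                ),
                minor_plateau_um=float(
                    trace.minor[trace.t >= trace.t[-1] - 600.0].mean()
                ),
                overlap=_final_frame_overlap(seq, pattern, trace.centroid[-1]),
            )
        else:
            row.update(
                spreading_time_min=np.nan,
                early_major_rate_um_min=np.nan,
                early_minor_rate_um_min=np.nan,
                final_major_um=np.nan,
                final_minor_um=np.nan,
                final_aspect_ratio=np.nan,
                final_alignment_angle_deg=np.nan,
                minor_plateau_um=np.nan,
                overlap=np.nan,
            )
        rows.append(row)
    return rows


_SPREADING_DUNN_METRICS = [
    "spreading_time_min",
    "early_major_rate_um_min",
    "early_minor_rate_um_min",
    "final_aspect_ratio",
    "final_area_um2",
]


def _group_stats(table: pd.DataFrame, metrics: list[str], angle_col: Optional[str] = None) -> dict:
    """Dunn tables, box summaries and (optionally) Rayleigh tests."""
    report: dict = {"dunn": {}, "box": {}, "n": table.groupby("condition").size().to_dict()}
    conditions = sorted(table["condition"].unique())
    for metric in metrics:
        groups = {
            c: table.loc[table["condition"] == c, metric].dropna().to_numpy()
            for c in conditions
        }
        groups = {c: v for c, v in groups.items() if v.size >= 2}
        if len(groups) >= 2:
            report["dunn"][metric] = stats.dunn_test(groups)
        report["box"][metric] = {
            c: stats.box_summary(v) for c, v in groups.items() if v.size
        }
    if angle_col is not None:
        report["rayleigh"] = {}
        for c in conditions:
            angles = table.loc[table["condition"] == c, angle_col].dropna().to_numpy()
            if angles.size >= 5:
                report["rayleigh"][c] = stats.rayleigh_test(angles, axial=True)
    return report


def _spreading_inputs(config: RunConfig, rng) -> Iterator[tuple[str, MaskSequence, PatternMask]]:
    if config.mode == "analyze":
        root = Path(config.input_dir)
        pattern = read_pattern(root / "pattern.tif")
        for path in sorted(root.glob("spreading_*.tif")):
            cond = path.stem.split("_")[1]
            yield cond, read_mask_sequence(path), pattern
    else:
        pattern = generate_pattern(config.pattern)
        for cond in sorted(config.spreading):
            for seq, _truth in generate_spreading_cohort(config.spreading[cond], pattern, rng):
                yield cond, seq, pattern


def run_spreading_pipeline(config: RunConfig) -> dict:
    """Run the spreading analysis for all configured conditions.

    Returns ``{"table": cohort table, "stats": report, "log": ...}``;
    writes ``spreading_cohort.csv`` under ``out_dir`` when set.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond, seq, pattern in _spreading_inputs(config, rng):
        for row in analyze_spreading_sequence(
            seq, pattern, config.d_max_um, config.min_track_length
        ):
            rows.append({"condition": cond, **row})
    table = pd.DataFrame(rows)
    table.insert(1, "platelet", table.groupby("condition").cumcount())
    spreaders = table[table["is_spreading"]]
    if spreaders.empty:
        report = {"warning": "no spreading platelets"}
    else:
        report = _group_stats(
            spreaders, _SPREADING_DUNN_METRICS, angle_col="final_alignment_angle_deg"
        )
    log = {"config_hash": config.digest(), "seed": config.seed}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "spreading_cohort.csv", index=False)
        _write_report(out / "spreading_stats", report, log)
    return {"table": table, "stats": report, "log": log}


# ---------------------------------------------------------------------------
# SICM pipeline
# ---------------------------------------------------------------------------


def process_iz_stack(stack: IZStack, params: SICMAnalysisParams = SICMAnalysisParams()) -> dict:
    """Full single-stack processing chain.

    Returns the leveled topography, label grid, apparent and corrected
    modulus maps, the rigid reference, and the per-platelet records.
    """
    raw = extract_topography(stack)
    topo = level_tilt(raw, stack.pixel_size_um)
    labels = segment_platelets(
        topo, min_area_um2=params.min_area_um2, height_threshold_um=params.height_threshold_um
    )
    # zero-offset refinement: the plane fit excludes pixels > 50 nm above
    # the plane, which truncates the right tail of the (skewed) trigger
    # noise and leaves the substrate mean a few nm above zero; re-zero on
    # the untruncated substrate (all unlabeled pixels) so platelet
    # heights are measured against the substrate mean rather than a
    # truncated estimate of it
    offset = float(np.nanmean(topo.height[labels == 0]))
    topo.height = topo.height - offset
    labels = segment_platelets(
        topo, min_area_um2=params.min_area_um2, height_threshold_um=params.height_threshold_um
    )
    dz = extract_dz(stack, params)
    with np.errstate(invalid="ignore"):
        substrate = (labels == 0) & (topo.height <= params.height_threshold_um)
    # pool dz over neighbouring platelet pixels: per-pixel dz noise is
    # comparable to the deformation signal of stiff samples
    platelet = labels > 0
    dz_pooled = np.where(platelet, smooth_within_mask(dz, platelet), dz)
    e_app, dz_def, rigid_ref = invert_modulus(
        dz_pooled, stack, params, substrate_mask=substrate
    )
    e_corr = correct_bottom_effect(e_app, topo, params.h_c, platelet_mask=labels > 0)
    records = platelet_statistics(labels, topo, e_corr)
    return {
        "topography": topo,
        "labels": labels,
        "dz": dz,
        "dz_def": dz_def,
        "e_app": e_app,
        "e_corr": e_corr,
        "rigid_reference": rigid_ref,
        "records": records,
    }


_SICM_DUNN_METRICS = [
    "median_modulus_kpa",
    "max_height_um",
    "volume_fl",
    "height_skewness",
]


def _sicm_inputs(config: RunConfig, rng) -> Iterator[tuple[str, IZStack]]:
    if config.mode == "analyze":
        root = Path(config.input_dir)
        for path in sorted(root.glob("sicm_*.h5")):
            yield path.stem.split("_")[1], read_iz_stack(path)
    else:
        for cond in sorted(config.sicm):
            for stack, _truth in generate_sicm_cohort(config.sicm[cond], rng):
                yield cond, stack


def run_sicm_pipeline(config: RunConfig) -> dict:
    """Run the SICM analysis for all configured conditions.

    One row per segmented platelet; stacks with no platelet contribute
    nothing (with a warning entry in the log).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    empty = 0
    for k, (cond, stack) in enumerate(_sicm_inputs(config, rng)):
        result = process_iz_stack(stack, config.analysis)
        rec = result["records"]
        if rec.empty:
            empty += 1
            continue
        rec = rec.copy()
        rec.insert(0, "condition", cond)
        rec.insert(1, "stack", k)
        rows.append(rec)
    if rows:
        table = pd.concat(rows, ignore_index=True)
        report = _group_stats(table, _SICM_DUNN_METRICS)
    else:
        table = pd.DataFrame()
        report = {"warning": "no platelets segmented"}
    log = {"config_hash": config.digest(), "seed": config.seed, "empty_stacks": empty}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sicm_cohort.csv", index=False)
        _write_report(out / "sicm_stats", report, log)
    return {"table": table, "stats": report, "log": log}


def _write_report(prefix: Path, report: dict, log: dict) -> None:
    payload = {"log": log}
    for key, val in report.items():
        if key == "dunn":
            for metric, tab in val.items():
                tab.to_csv(f"{prefix}_dunn_{metric}.csv", index=False)
        elif key == "box":
            payload["box"] = {
                m: {c: dataclasses.asdict(b) | {"outliers": b.outliers.tolist()} for c, b in d.items()}
                for m, d in val.items()
            }
        elif key == "rayleigh":
            payload["rayleigh"] = {c: r._asdict() for c, r in val.items()}
        else:
            payload[key] = val
    Path(f"{prefix}.json").write_text(json.dumps(payload, indent=1, default=str))
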