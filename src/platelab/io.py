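"""File formats: TIFF masks/maps with JSON sidecars, HDF5 I-z stacks.

Layouts
-------
* Pattern mask / height / modulus / label maps: single-page TIFF
  (uint8 for booleans, float32 for physical maps) plus a ``.json``
  sidecar holding the pixel size and geometry metadata.
* Mask sequences: multi-page TIFF (uint8) plus a sidecar with the
  timestamps in seconds.
* I-z stacks: HDF5 with datasets ``/current`` (ny, nx, ns) and ``/z``
  (ns, shared descending grid, nm) and attributes ``I_sat``,
  ``trigger``, ``pressure_kPa``, ``pixel_size_um``, ``seed``.

Ground-truth and cohort tables are plain CSV; the column dictionary is
documented in the docstrings of the functions that write them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile

from .core import IZStack, MaskSequence, PatternMask

__all__ = [
    "SchemaError",
    "write_pattern",
    "read_pattern",
    "write_mask_sequence",
    "read_mask_sequence",
    "write_map",
    "read_map",
    "write_iz_stack",
    "read_iz_stack",
]


class SchemaError(ValueError):
    """Raised when a file is missing a required dataset or attribute."""


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_pattern(path, pattern: PatternMask, overwrite: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, overwrite)
    tifffile.imwrite(path, pattern.mask.astype(np.uint8))
    meta = {
        "pixel_size_um": pattern.pixel_size,
        "line_width_um": pattern.line_width,
        "period_um": pattern.period,
        "orientation_deg": pattern.orientation,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_pattern(path) -> PatternMask:
    path = Path(path)
    mask = tifffile.imread(path).astype(bool)
    try:
        meta = json.loads(_sidecar(path).read_text())
        return PatternMask(
            mask=mask,
            pixel_size=meta["pixel_size_um"],
            line_width=meta["line_width_um"],
            period=meta["period_um"],
            orientation=meta["orientation_deg"],
        )
    except (FileNotFoundError, KeyError) as exc:
        raise SchemaError(f"pattern sidecar missing or incomplete: {exc}") from exc


def write_mask_sequence(path, seq: MaskSequence, overwrite: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, overwrite)
    tifffile.imwrite(path, seq.masks.astype(np.uint8))
    meta = {"pixel_size_um": seq.pixel_size, "timestamps_s": seq.timestamps.tolist()}
    _sidecar(path).write_text(json.dumps(meta))


def read_mask_sequence(path) -> MaskSequence:
    path = Path(path)
    masks = tifffile.imread(path).astype(bool)
    if masks.ndim == 2:
        masks = masks[None]
    try:
        meta = json.loads(_sidecar(path).read_text())
        return MaskSequence(
            masks=masks,
            timestamps=np.asarray(meta["timestamps_s"], dtype=float),
            pixel_size=meta["pixel_size_um"],
        )
    except (FileNotFoundError, KeyError) as exc:
        raise SchemaError(f"sequence sidecar missing or incomplete: {exc}") from exc


def write_map(path, data: np.ndarray, pixel_size: float, units: str, overwrite: bool = False) -> None:
    """Write a float32 (or uint16 label) map with a pixel-size sidecar."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    if data.dtype == np.uint16:
        tifffile.imwrite(path, data)
    else:
        tifffile.imwrite(path, data.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"pixel_size_um": pixel_size, "units": units}))


def read_map(path) -> tuple[np.ndarray, float, str]:
    path = Path(path)
    data = tifffile.imread(path)
    try:
        meta = json.loads(_sidecar(path).read_text())
        return data, meta["pixel_size_um"], meta.get("units", "")
    except (FileNotFoundError, KeyError) as exc:
        raise SchemaError(f"map sidecar missing or incomplete: {exc}") from exc


def write_iz_stack(path, stack: IZStack, overwrite: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, overwrite)
    with h5py.File(path, "w") as f:
        f.create_dataset("current", data=stack.current, compression="gzip", compression_opts=4)
        f.create_dataset("z", data=stack.z)
        f.attrs["I_sat"] = stack.i_sat
        f.attrs["trigger"] = stack.trigger
        f.attrs["pressure_kPa"] = stack.pressure_kpa
        f.attrs["pixel_size_um"] = stack.pixel_size_um
        f.attrs["seed"] = -1 if stack.seed is None else stack.seed


def read_iz_stack(path) -> IZStack:
    """Read an I-z stack; missing pieces raise :class:`SchemaError`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            for ds in ("current", "z"):
                if ds not in f:
                    raise SchemaError(f"I-z stack {path} is missing dataset /{ds}")
            for attr in ("I_sat", "trigger", "pressure_kPa", "pixel_size_um"):
                if attr not in f.attrs:
                    raise SchemaError(f"I-z stack {path} is missing attribute {attr}")
            seed = int(f.attrs.get("seed", -1))
            return IZStack(
                current=f["current"][...],
                z=f["z"][...],
                i_sat=float(f.attrs["I_sat"]),
                trigger=float(f.attrs["trigger"]),
                pressure_kpa=float(f.attrs["pressure_kPa"]),
                pixel_size_um=float(f.attrs["pixel_size_um"]),
                seed=None if seed < 0 else seed,
            )
    except OSError as exc:  # truncated or non-HDF5 file
        raise SchemaError(f"cannot read I-z stack {path}: {exc}") from exc
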