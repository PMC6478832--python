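"""TIFF stack and sidecar I/O.

Volumes travel as multi-page 32-bit float TIFF stacks with plane order = z
ascending; every written stack gets a JSON sidecar recording the grid, the
processing stage and any seed, so a run can be reproduced bit-identically.
Spectra are exported as separate magnitude and phase stacks.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .optics import GridSpec, Spectrum, Volume

__all__ = ["read_stack", "write_stack", "write_spectrum", "read_sidecar"]

logger = logging.getLogger("ssos")

_SUPPORTED_DTYPES = ("uint8", "int8", "uint16", "int16", "float32", "float64")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(path, voxel_xy: float, voxel_z: float) -> Volume:
    """Read a multi-page TIFF as a Volume (plane order mapped to ascending z).

    Accepts 8/16-bit integer or 32/64-bit float pages of uniform shape;
    voxel sizes come from the caller's configuration (which wins over any
    file metadata).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported bit depth: {data.dtype}")
    if data.ndim == 2:
        logger.info("single-page TIFF %s read as a one-plane volume", path.name)
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D stack, got shape {data.shape}")
    grid = GridSpec(shape=tuple(data.shape), voxel_xy=voxel_xy, voxel_z=voxel_z)
    return Volume(data.astype(np.float64), grid)


def write_stack(
    v: Volume,
    path,
    stage: str = "volume",
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> Path:
    """Write a Volume as a float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    bad = int(np.count_nonzero(~np.isfinite(v.values)))
    if bad:
        raise ValueError(f"refusing to write {bad} non-finite voxels")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, v.values.astype(np.float32))
    sidecar = {
        "stage": stage,
        "shape": list(v.grid.shape),
        "voxel_xy_nm": v.grid.voxel_xy,
        "voxel_z_nm": v.grid.voxel_z,
        "seed": seed,
        "config_hash": config_hash,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def write_spectrum(s: Spectrum, base_path, stage: str = "spectrum") -> tuple:
    """Export a Spectrum as magnitude and phase float32 stacks."""
    base = Path(base_path)
    mag = Volume(np.abs(s.values), s.grid)
    phase = Volume(np.angle(s.values), s.grid)
    p_mag = write_stack(mag, base.with_name(base.stem + "_magnitude.tif"), stage=stage)
    p_phase = write_stack(phase, base.with_name(base.stem + "_phase.tif"), stage=stage)
    return p_mag, p_phase


def read_sidecar(path) -> dict:
    """Load the provenance sidecar written next to a stack."""
    return json.loads(_sidecar_path(Path(path)).read_text())
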