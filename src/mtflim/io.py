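"""Stack I/O: multi-page TIFF plus a JSON sidecar carrying page semantics.

Counts cubes are stored as integer TIFF pages (time bins, sweep angles or
movie frames along the page axis) and float maps as float32; the sidecar
records what the pages mean, the pixel size and the time binning, so an
acquisition context can be reconstructed exactly on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .probes import AcquisitionContext

__all__ = ["write_stack", "read_stack", "SidecarError"]

REQUIRED_FIELDS = ("page_semantics", "pixel_size_um")


class SidecarError(ValueError):
    """Malformed or missing sidecar metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: np.ndarray, path, sidecar: dict) -> None:
    """Write a (pages, rows, cols) stack with its JSON sidecar.

    Integer data are stored losslessly (uint16 when they fit, else uint32);
    float data as float32.  ``sidecar`` must carry ``page_semantics`` (e.g.
    ``"time_bins"``, ``"sweep_angles"``, ``"frames"``, ``"maps"``) and
    ``pixel_size_um``.
    """
    path = Path(path)
    for fieldname in REQUIRED_FIELDS:
        if fieldname not in sidecar:
            raise SidecarError(f"sidecar missing required field {fieldname!r}")
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if np.issubdtype(stack.dtype, np.integer):
        dtype = np.uint16 if stack.max(initial=0) < 2**16 else np.uint32
        data = stack.astype(dtype)
    else:
        data = stack.astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack and its sidecar; raises :class:`SidecarError` without one."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise SidecarError(f"no sidecar found at {side}")
    with open(side) as fh:
        sidecar = json.load(fh)
    for fieldname in REQUIRED_FIELDS:
        if fieldname not in sidecar:
            raise SidecarError(f"sidecar missing required field {fieldname!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data, sidecar


def acquisition_from_sidecar(sidecar: dict, **overrides) -> AcquisitionContext:
    """Reconstruct an acquisition context from sidecar time-binning fields."""
    kwargs = dict(pixel_size=float(sidecar["pixel_size_um"]))
    if "n_time_bins" in sidecar:
        kwargs["n_time_bins"] = int(sidecar["n_time_bins"])
    if "time_window_ns" in sidecar:
        kwargs["time_window"] = float(sidecar["time_window_ns"])
    if "pulse_period_ns" in sidecar:
        kwargs["pulse_period"] = float(sidecar["pulse_period_ns"])
    kwargs.update(overrides)
    return AcquisitionContext(**kwargs)
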