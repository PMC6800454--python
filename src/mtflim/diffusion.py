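"""Lateral diffusion on the bilayer and FRAP movie rendering.

Free 2-D diffusion over a time step ``dt`` is exactly a convolution with a
Gaussian kernel of variance ``2 D dt`` per axis, so the stepper composes
Gaussian blurs (periodic boundaries: probe mass is conserved to machine
precision).  The discrete kernel is only accurate when its sigma covers at
least half a pixel, hence the stability check.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .probes import AcquisitionContext

__all__ = ["diffuse", "render_frap_movie", "disk_mask"]

MIN_KERNEL_SIGMA_PX = 0.5


def diffuse(field: np.ndarray, D: float, dt: float, pixel_size: float) -> np.ndarray:
    """Evolve a concentration field by free diffusion for time ``dt``.

    Raises for kernels narrower than half a pixel (inaccurate discrete
    Gaussian); ``D = 0`` or ``dt = 0`` returns the field unchanged.
    """
    if D < 0 or dt < 0:
        raise ValueError("D and dt must be non-negative")
    if D == 0 or dt == 0:
        return np.asarray(field, dtype=float).copy()
    sigma_px = np.sqrt(2.0 * D * dt) / pixel_size
    if sigma_px < MIN_KERNEL_SIGMA_PX:
        raise ValueError(
            f"diffusion kernel sigma {sigma_px:.3f} px < {MIN_KERNEL_SIGMA_PX} px: "
            "increase dt or coarsen pixels"
        )
    return gaussian_filter(np.asarray(field, dtype=float), sigma_px, mode="wrap")


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    return np.hypot(rr - center[0], cc - center[1]) <= radius_px


def render_frap_movie(
    D: float,
    bleach_radius: float,
    acq: AcquisitionContext,
    frame_times,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    bleach_time: float = 0.0,
    bleach_residual: float = 0.0,
    photon_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a bleach-recovery movie of a uniform bilayer.

    A disk of radius ``bleach_radius`` (um) at the field centre is set to
    ``bleach_residual`` at ``bleach_time``; the field then recovers by free
    diffusion.  Returns ``(movie, roi_mask, times)`` where the movie holds
    expected (or Poisson-sampled) photon counts per frame at
    ``acq.exposure_scale`` photons per unit concentration.

    Requires ``D >= 0``, ``bleach_radius > 0`` and a margin of at least three
    bleach radii between the disk and the field edge.
    """
    if bleach_radius <= 0:
        raise ValueError("bleach radius must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    px = acq.pixel_size
    w_px = bleach_radius / px
    if shape is None:
        n = int(np.ceil(8.0 * w_px)) | 1
        shape = (n, n)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    margin = (min(center[0], center[1], shape[0] - 1 - center[0],
                  shape[1] - 1 - center[1]) - w_px) * px
    if margin < 3.0 * bleach_radius:
        raise ValueError("bleach disk needs a margin of >= 3 radii to the edge")

    roi = disk_mask(shape, center, w_px)
    conc = np.ones(shape, dtype=float)
    rng = np.random.default_rng(seed)
    movie = np.empty((len(times),) + shape)
    bleached = False
    t_prev = times[0]
    for i, t in enumerate(times):
        if i > 0 and D > 0 and t > t_prev:
            conc = diffuse(conc, D, t - t_prev, px)
        if not bleached and t >= bleach_time:
            conc = np.where(roi, bleach_residual * conc, conc)
            bleached = True
        frame = conc * acq.exposure_scale + acq.dark_counts
        movie[i] = rng.poisson(frame) if photon_noise else frame
        t_prev = t
    return movie, roi, times
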