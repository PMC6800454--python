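"""Force-orientation analysis of excitation-polarization sweeps.

The per-pixel sweep is fitted as ``I(alpha) = C + A cos(2 (alpha - phi))``
with ``phi`` reported at the intensity *minimum* (the azimuth of the force,
mod 180 degrees).  The modulation ratio ``m = A / C`` maps to the force tilt
from the substrate normal through the dipole-ring geometry:

    m = sin^2(theta) / (2 - sin^2(theta))    <=>
    theta = arcsin( sqrt( 2 m / (1 + m) ) )

Tilts below the sensitivity cone (default 20 degrees) are flagged: the
modulation vanishes quadratically as theta -> 0, so small tilts are
indistinguishable from vertical at realistic photon budgets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .podosomes import PodosomeRecord
from .polarization import PolarizationStack

__all__ = [
    "OrientationMap",
    "fit_modulation",
    "tilt_angle",
    "orientation_from_stack",
    "podosome_tilt_summary",
    "g_factor",
    "anisotropy",
]

DEFAULT_CONE_DEG = 20.0


@dataclass
class OrientationMap:
    offset: np.ndarray  # C
    amplitude: np.ndarray  # A >= 0
    phase_deg: np.ndarray  # azimuth at the intensity minimum, [0, 180); NaN if flat
    tilt_deg: np.ndarray | None = None
    vertical_cone: np.ndarray | None = None
    saturated: np.ndarray | None = None
    residual: np.ndarray | None = None  # per-pixel RMS fit residual


def fit_modulation(
    stack: PolarizationStack, mask: np.ndarray | None = None
) -> OrientationMap:
    """Closed-form least-squares fit of the second-harmonic modulation.

    Solves ``I = C + a cos 2a + b sin 2a`` per pixel via the normal
    equations; amplitude ``A = hypot(a, b)`` and the minimum-intensity phase
    ``phi``.  Pixels where the amplitude is indistinguishable from zero get a
    NaN phase (undefined-azimuth flag).
    """
    K, H, W = stack.images.shape
    if K < 4:
        raise ValueError("need >= 4 usable frames")
    a2 = 2.0 * np.radians(stack.angles_deg)
    X = np.column_stack([np.ones(K), np.cos(a2), np.sin(a2)])
    y = stack.images.reshape(K, -1).astype(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    C = coef[0].reshape(H, W)
    a = coef[1].reshape(H, W)
    b = coef[2].reshape(H, W)
    A = np.hypot(a, b)
    # I = C + A cos(2(alpha - psi)) with psi the maximum; minimum at psi + 90
    psi = 0.5 * np.degrees(np.arctan2(b, a))
    phase = (psi + 90.0) % 180.0
    flat = A <= 1e-9 * np.maximum(C, 1e-300)
    phase[flat] = np.nan
    resid = np.sqrt(((y - X @ coef) ** 2).mean(axis=0)).reshape(H, W)
    if mask is not None:
        out = ~mask
        for arr in (C, A, phase, resid):
            arr[out] = np.nan
    return OrientationMap(offset=C, amplitude=A, phase_deg=phase, residual=resid)


def tilt_angle(
    C, A, cone_angle: float = DEFAULT_CONE_DEG
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map modulation ratio to tilt from the substrate normal.

    Returns ``(theta_deg, vertical_cone, saturated)``; modulation ratios
    above 1 are clipped to the in-plane limit and flagged saturated.
    """
    C = np.asarray(C, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(C[np.isfinite(C)] <= 0):
        raise ValueError("offset C must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = A / C
    saturated = m > 1.0
    m = np.clip(m, 0.0, 1.0)
    theta = np.degrees(np.arcsin(np.sqrt(2.0 * m / (1.0 + m))))
    cone = theta < cone_angle
    return theta, cone, saturated


def orientation_from_stack(
    stack: PolarizationStack,
    mask: np.ndarray | None = None,
    cone_angle: float = DEFAULT_CONE_DEG,
) -> OrientationMap:
    """Fit modulation and derive the tilt map in one pass."""
    omap = fit_modulation(stack, mask)
    theta, cone, sat = tilt_angle(omap.offset, omap.amplitude, cone_angle)
    omap.tilt_deg = theta
    omap.vertical_cone = cone
    omap.saturated = sat
    return omap


def podosome_tilt_summary(
    records: list[PodosomeRecord],
    omap: OrientationMap,
    max_residual: float | None = None,
    histogram_bins: int = 18,
) -> tuple[pd.DataFrame, dict]:
    """Per-podosome mean tilt over ring pixels and the per-cell summary.

    Pixels flagged saturated or with fit residual above ``max_residual`` are
    dropped.  The cell summary is the unweighted mean of podosome means plus
    an angular histogram over [0, 90] degrees and the fraction of podosomes
    whose mean tilt falls inside the vertical cone.
    """
    rows = []
    for rec in records:
        sel = rec.ring_mask.copy()
        if omap.saturated is not None:
            sel &= ~omap.saturated
        if max_residual is not None and omap.residual is not None:
            sel &= omap.residual <= max_residual
        vals = omap.tilt_deg[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        mean_tilt = float(vals.mean())
        cone_frac = float(
            omap.vertical_cone[sel].mean() if omap.vertical_cone is not None else np.nan
        )
        rows.append(
            {
                "podosome_id": rec.id,
                "mean_tilt_deg": mean_tilt,
                "n_pixels": int(vals.size),
                "vertical_cone_fraction": cone_frac,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        hist, edges = np.histogram(
            df["mean_tilt_deg"], bins=histogram_bins, range=(0.0, 90.0)
        )
        summary = {
            "cell_mean_tilt_deg": float(df["mean_tilt_deg"].mean()),
            "n_podosomes": int(len(df)),
            "histogram_counts": hist.tolist(),
            "histogram_edges_deg": edges.tolist(),
            "vertical_cone_fraction": float(df["vertical_cone_fraction"].mean()),
        }
    else:
        summary = {"cell_mean_tilt_deg": np.nan, "n_podosomes": 0}
    return df, summary


def g_factor(reference_par: np.ndarray, reference_perp: np.ndarray) -> float:
    """Polarization bias of the microscope from an isotropic reference dye."""
    par = float(np.mean(reference_par))
    perp = float(np.mean(reference_perp))
    if par <= 0 or perp <= 0:
        raise ValueError("reference intensities must be positive")
    return par / perp


def anisotropy(i_par: np.ndarray, i_perp: np.ndarray, g: float) -> np.ndarray:
    """G-corrected fluorescence anisotropy r = (I_par - G I_perp) / (I_par + 2 G I_perp).

    Pixels with non-positive denominator are masked NaN.
    """
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + 2.0 * g * i_perp
    r = np.full(i_par.shape, np.nan)
    ok = denom > 0
    r[ok] = (i_par[ok] - g * i_perp[ok]) / denom[ok]
    return r
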