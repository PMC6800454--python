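"""Podosome and cluster morphometrics.

Podosome cores are detected as depletion zones — connected regions where the
probe channel drops below a fraction of the local bilayer background —
because the protrusive actin core excludes laterally mobile ligands.
Touching cores are split by a marker-based watershed with a 2-pixel-wide
separating line.  Each core is surrounded by an annular ring mask over which
tension (percent open) and density statistics are accumulated; bright
non-depleting puncta are reported separately as integrin clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import median_abs_deviation
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "PodosomeRecord",
    "ClusterRecord",
    "Track",
    "detect_podosomes",
    "depletion_metrics",
    "ring_tension_stats",
    "detect_clusters",
    "link_tracks",
    "perturbation_response",
    "normalize_by_brightest",
]


@dataclass
class PodosomeRecord:
    id: int
    frame: int
    centroid: tuple[float, float]  # (row, col) pixels
    core_radius: float  # um, effective radius from segmented core area
    depletion_pct: float
    core_mask: np.ndarray = field(repr=False)
    ring_mask: np.ndarray = field(repr=False)
    ring_mean_F: float = np.nan
    ring_mean_density: float = np.nan
    flags: list = field(default_factory=list)


@dataclass
class ClusterRecord:
    id: int
    frame: int
    centroid: tuple[float, float]
    area: float  # um^2
    mean_density: float = np.nan
    mean_F: float = np.nan


@dataclass
class Track:
    id: int
    records: list[PodosomeRecord]
    birth_frame: int
    death_frame: int
    lineage: str = "de-novo"  # or "split"


def detect_podosomes(
    intensity: np.ndarray,
    background: float | np.ndarray,
    pixel_size: float = 0.1,
    threshold_frac: float = 0.7,
    min_area_um2: float = 0.05,
    max_area_um2: float = 3.0,
    ring_width: float = 0.5,
    ring_outer_cap: float = 1.0,
    frame: int = 0,
) -> list[PodosomeRecord]:
    """Segment depletion cores and build per-podosome ring masks.

    Pixels below ``threshold_frac * background`` form candidate cores;
    touching cores are split by watershed and separated with a 2-pixel line;
    components outside the area range are dropped.  The ring is the annulus
    from the effective core radius out to ``core_radius + ring_width``,
    capped at ``ring_outer_cap`` (all in micrometres), excluding every
    segmented core.
    """
    intensity = np.asarray(intensity, dtype=float)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensity image must be finite")
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background reference must be positive")
    mask = intensity < threshold_frac * bg
    if not mask.any():
        return []

    # watershed split of touching cores, seeded at distance-transform maxima
    dist = ndimage.distance_transform_edt(mask)
    min_sep = max(2, int(round(0.3 / pixel_size)))
    peaks = peak_local_max(
        dist, min_distance=min_sep, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels = label(mask)
    else:
        labels = watershed(-dist, markers, mask=mask, watershed_line=True)
        # realize the separating line as a 2-pixel-wide barrier
        line = mask & (labels == 0)
        if line.any():
            labels[binary_dilation(line, disk(1))] = 0

    px_area = pixel_size**2
    records: list[PodosomeRecord] = []
    all_cores = labels > 0
    rr, cc = np.indices(mask.shape)
    next_id = 0
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        core_mask = labels == region.label
        centroid = region.centroid
        core_radius = float(np.sqrt(area_um2 / np.pi))
        d = np.hypot(rr - centroid[0], cc - centroid[1]) * pixel_size
        outer = min(core_radius + ring_width, ring_outer_cap)
        ring = (d > core_radius) & (d <= outer) & ~all_cores
        depletion, _ = depletion_metrics_arrays(
            centroid, core_mask, intensity, bg, pixel_size
        )
        records.append(
            PodosomeRecord(
                id=next_id,
                frame=frame,
                centroid=centroid,
                core_radius=core_radius,
                depletion_pct=depletion,
                core_mask=core_mask,
                ring_mask=ring,
            )
        )
        next_id += 1
    return records


def depletion_metrics_arrays(
    centroid: tuple[float, float],
    core_mask: np.ndarray,
    intensity: np.ndarray,
    background: float | np.ndarray,
    pixel_size: float,
) -> tuple[float, float]:
    """Depletion percent and effective core radius for one podosome.

    The centroid pixel is dilated by 2 pixels and the mean intensity inside
    that disk compared with the background:
    ``depletion = 100 * (1 - mean(disk) / background)``.
    """
    r0, c0 = int(round(centroid[0])), int(round(centroid[1]))
    seed = np.zeros(intensity.shape, dtype=bool)
    if not (0 <= r0 < intensity.shape[0] and 0 <= c0 < intensity.shape[1]):
        raise ValueError("podosome centroid lies outside the image")
    seed[r0, c0] = True
    disk_mask = binary_dilation(seed, disk(2))
    if np.asarray(background).ndim == 0:
        bg_val = float(background)
    else:
        bg_val = float(np.mean(np.asarray(background)[disk_mask]))
    depletion = 100.0 * (1.0 - float(intensity[disk_mask].mean()) / bg_val)
    core_radius = float(np.sqrt(core_mask.sum() * pixel_size**2 / np.pi))
    return depletion, core_radius


def depletion_metrics(
    record: PodosomeRecord,
    intensity: np.ndarray,
    background: float | np.ndarray,
    pixel_size: float = 0.1,
) -> tuple[float, float]:
    """Recompute (depletion_pct, core_radius) for an existing record."""
    return depletion_metrics_arrays(
        record.centroid, record.core_mask, intensity, background, pixel_size
    )


def ring_tension_stats(
    records: list[PodosomeRecord],
    F_map: np.ndarray,
    rho_map: np.ndarray | None,
    valid_mask: np.ndarray,
    min_valid_pixels: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Per-podosome ring means and the per-cell summary.

    Podosomes with fewer than ``min_valid_pixels`` valid ring pixels are
    flagged ``few_valid_ring_pixels`` and excluded from the cell mean, which
    is the unweighted mean of podosome means.
    """
    rows = []
    for rec in records:
        sel = rec.ring_mask & valid_mask & np.isfinite(F_map)
        n = int(sel.sum())
        excluded = n < min_valid_pixels
        if excluded:
            rec.flags.append("few_valid_ring_pixels")
        rec.ring_mean_F = float(np.mean(F_map[sel])) if n else np.nan
        if rho_map is not None and n:
            rec.ring_mean_density = float(np.nanmean(rho_map[sel]))
        rows.append(
            {
                "podosome_id": rec.id,
                "frame": rec.frame,
                "centroid_row": rec.centroid[0],
                "centroid_col": rec.centroid[1],
                "core_radius_um": rec.core_radius,
                "depletion_pct": rec.depletion_pct,
                "ring_mean_F": rec.ring_mean_F,
                "ring_mean_density": rec.ring_mean_density,
                "n_valid_ring_pixels": n,
                "excluded": excluded,
            }
        )
    df = pd.DataFrame(rows)
    kept = df[~df["excluded"]] if len(df) else df
    if len(kept) == 0:
        import warnings

        warnings.warn("no podosome with enough valid ring pixels")
        summary = {"cell_mean_F": np.nan, "cell_mean_density": np.nan, "n_podosomes": 0}
    else:
        summary = {
            "cell_mean_F": float(kept["ring_mean_F"].mean()),
            "cell_mean_density": float(kept["ring_mean_density"].mean()),
            "n_podosomes": int(len(kept)),
        }
    return df, summary


def detect_clusters(
    image: np.ndarray,
    records: list[PodosomeRecord],
    background: float = 1.0,
    threshold_frac: float = 1.5,
    pixel_size: float = 0.1,
    min_area_um2: float = 0.1,
    max_area_um2: float = 5.0,
    exclusion_radius: float = 1.2,
    edge_erosion_px: int = 2,
    F_map: np.ndarray | None = None,
    rho_map: np.ndarray | None = None,
    frame: int = 0,
) -> list[ClusterRecord]:
    """Detect bright puncta (density > background) away from depletion zones.

    Components above ``threshold_frac * background`` within the area range
    are kept if no podosome centroid lies within ``exclusion_radius`` (um) of
    their centroid.  Channel means are taken over the component footprint
    eroded by ``edge_erosion_px`` to avoid diffraction-softened edges.
    """
    image = np.asarray(image, dtype=float)
    bright = image > threshold_frac * background
    labels = label(bright)
    out: list[ClusterRecord] = []
    next_id = 0
    for region in regionprops(labels):
        area_um2 = region.area * pixel_size**2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        cen = region.centroid
        near_podosome = any(
            np.hypot(cen[0] - r.centroid[0], cen[1] - r.centroid[1]) * pixel_size
            < exclusion_radius
            for r in records
        )
        if near_podosome:
            continue
        foot = labels == region.label
        core = binary_erosion(foot, disk(edge_erosion_px)) if edge_erosion_px else foot
        if not core.any():
            core = foot
        rec = ClusterRecord(
            id=next_id, frame=frame, centroid=cen, area=float(area_um2)
        )
        if rho_map is not None:
            rec.mean_density = float(np.nanmean(rho_map[core]))
        if F_map is not None:
            rec.mean_F = float(np.nanmean(F_map[core]))
        out.append(rec)
        next_id += 1
    return out


def link_tracks(
    frames: list[list[PodosomeRecord]],
    gating_radius: float = 0.5,
    pixel_size: float = 0.1,
    split_radius: float = 1.5,
) -> list[Track]:
    """Greedy nearest-centroid linking of per-frame detections.

    Detections within ``gating_radius`` (um) of a live track's last centroid
    extend it (closest pairs first); the rest start new tracks.  A new track
    born within ``split_radius`` of a live track is tagged ``split``.  No gap
    closing: a missed detection terminates the track.
    """
    tracks: list[Track] = []
    live: list[Track] = []
    next_id = 0
    for fi, recs in enumerate(frames):
        pairs = []
        for ti, tr in enumerate(live):
            last = tr.records[-1].centroid
            for ri, rec in enumerate(recs):
                d = np.hypot(last[0] - rec.centroid[0], last[1] - rec.centroid[1])
                d_um = d * pixel_size
                if d_um <= gating_radius:
                    pairs.append((d_um, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d_um, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            live[ti].records.append(recs[ri])
            live[ti].death_frame = fi
            used_t.add(ti)
            used_r.add(ri)
        survivors = [tr for ti, tr in enumerate(live) if ti in used_t]
        for ti, tr in enumerate(live):
            if ti not in used_t:
                tracks.append(tr)
        new_live = survivors
        for ri, rec in enumerate(recs):
            if ri in used_r:
                continue
            lineage = "de-novo"
            for tr in survivors:
                last = tr.records[-1].centroid
                if (
                    np.hypot(last[0] - rec.centroid[0], last[1] - rec.centroid[1])
                    * pixel_size
                    <= split_radius
                ):
                    lineage = "split"
                    break
            new_live.append(
                Track(
                    id=next_id,
                    records=[rec],
                    birth_frame=fi,
                    death_frame=fi,
                    lineage=lineage,
                )
            )
            next_id += 1
        live = new_live
    tracks.extend(live)
    tracks.sort(key=lambda t: t.id)
    return tracks


def perturbation_response(
    tracks: list[Track],
    roi_mask: np.ndarray,
    t_event: float,
    frame_times: list[float],
    mad_exclusion: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-podosome percent radius change across a perturbation.

    For each track spanning ``t_event``, the radius change is
    ``100 * (r_after - r_before) / r_before`` using the nearest frames before
    and after the event.  Tracks are grouped proximal (centroid inside the
    ROI at the pre-event frame) versus distal, and outliers beyond
    median +/- 3 median absolute deviations are excluded per group.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    rows = []
    for tr in tracks:
        t_by_frame = {rec.frame: rec for rec in tr.records}
        pre = [f for f in t_by_frame if frame_times[f] < t_event]
        post = [f for f in t_by_frame if frame_times[f] > t_event]
        if not pre or not post:
            continue
        f0, f1 = max(pre), min(post)
        r0 = t_by_frame[f0].core_radius
        r1 = t_by_frame[f1].core_radius
        if r0 <= 0:
            continue
        cen = t_by_frame[f0].centroid
        proximal = bool(roi_mask[int(round(cen[0])), int(round(cen[1]))])
        rows.append(
            {
                "track_id": tr.id,
                "pct_radius_change": 100.0 * (r1 - r0) / r0,
                "group": "proximal" if proximal else "distal",
            }
        )
    df = pd.DataFrame(rows)
    if len(df) and mad_exclusion:
        keep = np.ones(len(df), dtype=bool)
        for grp, sub in df.groupby("group"):
            x = sub["pct_radius_change"].to_numpy()
            med = np.median(x)
            mad = median_abs_deviation(x)
            if mad > 0:
                keep[sub.index[np.abs(x - med) > 3 * mad]] = False
        df = df[keep].reset_index(drop=True)
    summary = (
        {
            grp: float(sub["pct_radius_change"].mean())
            for grp, sub in df.groupby("group")
        }
        if len(df)
        else {}
    )
    return df, summary


def normalize_by_brightest(values: np.ndarray, cell_ids: np.ndarray) -> np.ndarray:
    """Normalize per-podosome values by the brightest podosome of each cell."""
    values = np.asarray(values, dtype=float)
    cell_ids = np.asarray(cell_ids)
    out = np.empty_like(values)
    for cid in np.unique(cell_ids):
        sel = cell_ids == cid
        out[sel] = values[sel] / values[sel].max()
    return out
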