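"""Synthetic ground-truth scenes.

A scene is the latent state the imaging physics is rendered from: a relative
probe-density field (1 = bare bilayer), a fraction-open field (mechanically
unfolded probes), a per-pixel force-orientation field, and the geometric
truth of every podosome and integrin cluster placed in the cell footprint.

Podosome geometry follows the ring model used throughout: a depleted
protrusive core (default effective radius 0.3 um, density well below
background) surrounded by a tensile ring reaching out to 1 um in which a
fixed fraction of probes (default 10%) is open.  Clusters are bright puncta
(density > 1) without tension and without a depletion zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SceneConfig", "PodosomeTruth", "ClusterTruth", "Scene", "build_scene"]


@dataclass(frozen=True)
class PodosomeTruth:
    centroid: tuple[float, float]  # (row, col) pixels
    core_radius: float  # um
    ring_outer_radius: float  # um
    ring_fraction_open: float
    core_density: float


@dataclass(frozen=True)
class ClusterTruth:
    centroid: tuple[float, float]  # (row, col) pixels
    radius: float  # um
    density: float


@dataclass
class SceneConfig:
    """Parameters of a synthetic cell-on-bilayer scene.

    Radii are in micrometres and converted through ``pixel_size``.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.1  # um
    n_podosomes: int = 5
    core_radius: float = 0.3  # um
    ring_outer_radius: float = 1.0  # um
    ring_fraction_open: float = 0.10
    core_density: float = 0.05  # relative to background
    ring_density: float = 1.0
    n_clusters: int = 0
    cluster_radius: float = 0.5  # um
    cluster_density: float = 2.0
    cell_margin: float = 1.2  # um kept clear of the field edge
    min_separation: float = 0.2  # um of clearance between placed structures
    tilt_deg: float = 21.0  # force tilt from substrate normal on open pixels
    azimuth_mode: str = "radial"  # "radial" | "constant" | "random"
    azimuth_deg: float = 0.0
    background_density: float = 1.0
    max_attempts: int = 2000


@dataclass
class Scene:
    shape: tuple[int, int]
    pixel_size: float
    density_field: np.ndarray
    fraction_open_field: np.ndarray
    tilt_field: np.ndarray  # degrees from substrate normal
    azimuth_field: np.ndarray  # degrees, in-plane
    podosome_truth: list[PodosomeTruth]
    cluster_truth: list[ClusterTruth]
    cell_mask: np.ndarray
    seed: int

    def copy(self) -> "Scene":
        return Scene(
            shape=self.shape,
            pixel_size=self.pixel_size,
            density_field=self.density_field.copy(),
            fraction_open_field=self.fraction_open_field.copy(),
            tilt_field=self.tilt_field.copy(),
            azimuth_field=self.azimuth_field.copy(),
            podosome_truth=list(self.podosome_truth),
            cluster_truth=list(self.cluster_truth),
            cell_mask=self.cell_mask.copy(),
            seed=self.seed,
        )

    def validate(self) -> None:
        if np.any(self.density_field < 0):
            raise ValueError("density_field must be non-negative")
        f = self.fraction_open_field
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fraction_open_field must lie in [0, 1]")
        if np.any(f[~self.cell_mask] != 0):
            raise ValueError("fraction_open_field must vanish outside the cell")
        for p in self.podosome_truth:
            if not p.core_radius < p.ring_outer_radius:
                raise ValueError("podosome core radius must be < ring radius")


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails within max attempts."""


def _radial_distance(shape: tuple[int, int], centroid: tuple[float, float]) -> np.ndarray:
    rr, cc = np.indices(shape)
    return np.hypot(rr - centroid[0], cc - centroid[1])


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    pixel_size: float,
    radii_um: list[float],
    margin_um: float,
    min_sep_um: float,
    max_attempts: int,
    seed: int,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centres; radii are per-structure."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r_um in radii_um:
        pad = (r_um + margin_um) / pixel_size
        lo_r, hi_r = pad, shape[0] - 1 - pad
        lo_c, hi_c = pad, shape[1] - 1 - pad
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError(
                f"field {shape} too small for radius {r_um} um (seed {seed})"
            )
        for _ in range(max_attempts):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            ok = True
            for (pr, pc), prad in zip(centers, placed_r):
                if np.hypot(r - pr, c - pc) * pixel_size < r_um + prad + min_sep_um:
                    ok = False
                    break
            if ok:
                centers.append((r, c))
                placed_r.append(r_um)
                break
        else:
            raise PlacementError(
                f"could not place structure of radius {r_um} um after "
                f"{max_attempts} attempts (seed {seed})"
            )
    return centers


def build_scene(config: SceneConfig, seed: int) -> Scene:
    """Build a seeded ground-truth scene from ``config``.

    Identical (config, seed) pairs give bitwise-identical scenes.
    """
    if config.n_podosomes < 0 or config.n_clusters < 0:
        raise ValueError("structure counts must be non-negative")
    if config.core_radius <= 0 or config.ring_outer_radius <= config.core_radius:
        raise ValueError("require 0 < core_radius < ring_outer_radius")

    rng = np.random.default_rng(seed)
    shape = tuple(config.shape)
    px = config.pixel_size

    margin_px = config.cell_margin / px
    rr, cc = np.indices(shape)
    cell_mask = (
        (rr >= margin_px)
        & (rr <= shape[0] - 1 - margin_px)
        & (cc >= margin_px)
        & (cc <= shape[1] - 1 - margin_px)
    )

    density = np.full(shape, config.background_density, dtype=float)
    fraction_open = np.zeros(shape, dtype=float)
    tilt = np.zeros(shape, dtype=float)
    azimuth = np.zeros(shape, dtype=float)

    radii = [config.ring_outer_radius] * config.n_podosomes + [
        config.cluster_radius
    ] * config.n_clusters
    centers = _place_centers(
        rng, shape, px, radii, config.cell_margin, config.min_separation,
        config.max_attempts, seed,
    )
    pod_centers = centers[: config.n_podosomes]
    clu_centers = centers[config.n_podosomes:]

    podosomes: list[PodosomeTruth] = []
    for ctr in pod_centers:
        d = _radial_distance(shape, ctr) * px
        core = d <= config.core_radius
        ring = (d > config.core_radius) & (d <= config.ring_outer_radius)
        density[core] = config.core_density * config.background_density
        density[ring] = config.ring_density * config.background_density
        fraction_open[ring] = config.ring_fraction_open
        tilt[ring] = config.tilt_deg
        if config.azimuth_mode == "radial":
            az = np.degrees(np.arctan2(cc - ctr[1], rr - ctr[0])) % 180.0
            azimuth[ring] = az[ring]
        elif config.azimuth_mode == "random":
            azimuth[ring] = rng.uniform(0.0, 180.0, size=int(ring.sum()))
        else:
            azimuth[ring] = config.azimuth_deg
        podosomes.append(
            PodosomeTruth(
                centroid=ctr,
                core_radius=config.core_radius,
                ring_outer_radius=config.ring_outer_radius,
                ring_fraction_open=config.ring_fraction_open,
                core_density=config.core_density * config.background_density,
            )
        )

    clusters: list[ClusterTruth] = []
    for ctr in clu_centers:
        d = _radial_distance(shape, ctr) * px
        foot = d <= config.cluster_radius
        density[foot] = config.cluster_density * config.background_density
        clusters.append(
            ClusterTruth(centroid=ctr, radius=config.cluster_radius,
                         density=config.cluster_density * config.background_density)
        )

    fraction_open[~cell_mask] = 0.0

    scene = Scene(
        shape=shape,
        pixel_size=px,
        density_field=density,
        fraction_open_field=fraction_open,
        tilt_field=tilt,
        azimuth_field=azimuth,
        podosome_truth=podosomes,
        cluster_truth=clusters,
        cell_mask=cell_mask,
        seed=seed,
    )
    scene.validate()
    return scene
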