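"""Perturbation time-lapses: photocleavage, tension-gauge-tether rupture and
bleaching, followed by diffusive replenishment.

The maintained scene pattern (podosome depletion cores, rings, clusters) is
treated as a quasi-steady state actively held by the cell; perturbations
create a *deviation* from that pattern which relaxes by free lateral
diffusion.  Photocleaving a region releases probes from the bilayer there
(density and open fraction drop to a residual); the hole then refills from
the surrounding reservoir exactly like a FRAP spot, and probes arriving
under a load-bearing ring are re-opened, so tension signal recovers on the
diffusive timescale.  Cleaved podosomes additionally retract: their ground
truth core radius shrinks by a response factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .diffusion import diffuse, disk_mask
from .probes import AcquisitionContext, ProbeSpecies
from .scene import PodosomeTruth, Scene

__all__ = [
    "PerturbationEvent",
    "EventTimeline",
    "make_timeline",
    "apply_perturbation",
    "render_timeline_tension",
    "render_timeline_intensity",
]


@dataclass(frozen=True)
class PerturbationEvent:
    time: float  # s
    kind: str  # "photocleave" | "tgt_sink" | "bleach"
    center: tuple[float, float]  # (row, col) pixels
    radius: float  # um
    residual: float = 0.0  # fraction of density / open probes surviving
    sink_rate: float = 0.0  # 1/s, tgt_sink removal rate
    force_pn: float = 0.0  # simulated per-receptor force for tgt_sink
    core_response_factor: float = 1.0  # cleaved podosome core shrink factor


@dataclass
class EventTimeline:
    base_scene: Scene
    frame_times: np.ndarray  # s, strictly increasing
    diffusion_coefficient: float  # um^2 / s
    events: list[PerturbationEvent] = field(default_factory=list)
    frames: list[Scene] = field(default_factory=list)

    def validate(self) -> None:
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")


def make_timeline(
    scene: Scene, frame_times, D: float
) -> EventTimeline:
    """Unperturbed timeline: every frame is the maintained base scene."""
    times = np.asarray(frame_times, dtype=float)
    tl = EventTimeline(
        base_scene=scene,
        frame_times=times,
        diffusion_coefficient=D,
        frames=[scene.copy() for _ in times],
    )
    tl.validate()
    return tl


def _shrink_podosome_cores(
    scene: Scene, roi: np.ndarray, factor: float
) -> tuple[Scene, np.ndarray]:
    """Shrink the truth core radius of podosomes whose centroid is in the ROI.

    Repaints the density field of each affected podosome: pixels between the
    new and old core radius revert to ring density.
    """
    out = scene.copy()
    for i, pod in enumerate(out.podosome_truth):
        r0, c0 = pod.centroid
        if not roi[int(round(r0)), int(round(c0))]:
            continue
        new_core = pod.core_radius * factor
        rr, cc = np.indices(out.shape)
        d = np.hypot(rr - r0, cc - c0) * out.pixel_size
        regrow = (d > new_core) & (d <= pod.core_radius)
        ring_val = np.median(
            out.density_field[(d > pod.core_radius) & (d <= pod.ring_outer_radius)]
        )
        out.density_field[regrow] = ring_val
        out.fraction_open_field[regrow] = pod.ring_fraction_open
        out.podosome_truth[i] = replace(pod, core_radius=new_core)
    return out, roi


def apply_perturbation(
    timeline: EventTimeline, event: PerturbationEvent
) -> EventTimeline:
    """Apply an event and re-evolve all frames at or after its time.

    The density field of each post-event frame is the maintained pattern
    plus a diffusively relaxing deviation created by the event; the open
    fraction drops to the residual at the event frame and is restored by the
    maintaining podosome afterwards.  ``tgt_sink`` with a per-receptor force
    below the probe's rupture tolerance leaves the timeline unchanged.
    """
    timeline.validate()
    times = timeline.frame_times
    if not (times[0] <= event.time <= times[-1]):
        raise ValueError("event time outside timeline span")
    if event.kind not in ("photocleave", "tgt_sink", "bleach"):
        raise ValueError(f"unknown event kind {event.kind!r}")

    base = timeline.base_scene
    roi = disk_mask(base.shape, event.center, event.radius / base.pixel_size)
    if not roi.any():
        raise ValueError("event ROI lies outside the field")

    tl = EventTimeline(
        base_scene=base,
        frame_times=times,
        diffusion_coefficient=timeline.diffusion_coefficient,
        events=timeline.events + [event],
        frames=[f.copy() for f in timeline.frames],
    )

    maintained = base
    if event.kind == "photocleave" and event.core_response_factor != 1.0:
        maintained, _ = _shrink_podosome_cores(base, roi, event.core_response_factor)

    D = timeline.diffusion_coefficient
    px = base.pixel_size
    deviation = None  # density deviation from the maintained pattern
    t_prev = None
    for i, t in enumerate(times):
        if t < event.time:
            continue
        if deviation is None:
            # event frame: carve the hole out of the current frame's density
            current = tl.frames[i]
            new_density = current.density_field.copy()
            new_f = current.fraction_open_field.copy()
            if event.kind in ("photocleave", "bleach"):
                new_density[roi] *= event.residual
                if event.kind == "photocleave":
                    new_f[roi] *= event.residual
            elif event.kind == "tgt_sink":
                sink = roi & (current.fraction_open_field > 0)
                dt_frame = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
                new_density[sink] *= np.exp(-event.sink_rate * dt_frame)
            deviation = new_density - maintained.density_field
            frame_scene = maintained.copy()
            frame_scene.density_field = maintained.density_field + deviation
            frame_scene.fraction_open_field = new_f
            tl.frames[i] = frame_scene
        else:
            dt = t - t_prev
            if D > 0 and dt > 0:
                deviation = diffuse(deviation, D, dt, px)
            frame_scene = maintained.copy()
            frame_scene.density_field = np.clip(
                maintained.density_field + deviation, 0.0, None
            )
            tl.frames[i] = frame_scene
        t_prev = t
    return tl


def apply_tgt_sink(
    timeline: EventTimeline, event: PerturbationEvent, probe: ProbeSpecies
) -> EventTimeline:
    """Tension-gauge-tether rupture: only acts if the simulated per-receptor
    force reaches the probe's rupture tolerance."""
    if probe.t_tol is None or event.force_pn < probe.t_tol:
        return timeline  # no rupture: timeline unchanged
    return apply_perturbation(timeline, event)


def _tension_frame(
    scene: Scene, probe: ProbeSpecies, acq: AcquisitionContext
) -> np.ndarray:
    sigma_px = acq.psf_sigma / acq.pixel_size
    signal = scene.density_field * scene.fraction_open_field
    if sigma_px > 0:
        signal = gaussian_filter(signal, sigma_px, mode="nearest")
    return signal * probe.brightness_open * acq.exposure_scale + acq.dark_counts


def render_timeline_tension(
    timeline: EventTimeline,
    probe: ProbeSpecies,
    acq: AcquisitionContext,
    seed: int | None = None,
) -> np.ndarray:
    """Open-probe (tension-channel) intensity stack over the timeline.

    Noiseless expected counts by default; Poisson-sampled when a seed is
    given.
    """
    frames = np.stack([_tension_frame(s, probe, acq) for s in timeline.frames])
    if seed is None:
        return frames
    return np.random.default_rng(seed).poisson(frames).astype(np.uint32)


def render_timeline_intensity(
    timeline: EventTimeline,
    probe: ProbeSpecies,
    acq: AcquisitionContext,
    seed: int | None = None,
) -> np.ndarray:
    """Total probe intensity stack (density channel, quencher-free probes)."""
    sigma_px = acq.psf_sigma / acq.pixel_size
    out = []
    for s in timeline.frames:
        sig = s.density_field.copy()
        if sigma_px > 0:
            sig = gaussian_filter(sig, sigma_px, mode="nearest")
        out.append(sig * probe.brightness_open * acq.exposure_scale + acq.dark_counts)
    frames = np.stack(out)
    if seed is None:
        return frames
    return np.random.default_rng(seed).poisson(frames).astype(np.uint32)
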