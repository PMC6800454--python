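"""Perturbation timelines: photocleavage, TGT rupture, diffusive refill."""

import numpy as np
import pytest

from mtflim.diffusion import disk_mask
from mtflim.frap import roi_timeseries
from mtflim.probes import AcquisitionContext, ProbeSpecies, default_hairpin_probe
from mtflim.scene import SceneConfig, build_scene
from mtflim.timeline import (
    PerturbationEvent,
    apply_perturbation,
    apply_tgt_sink,
    make_timeline,
    render_timeline_tension,
)


@pytest.fixture
def scene():
    return build_scene(SceneConfig(shape=(120, 120), n_podosomes=2), seed=31)


def _times():
    return np.concatenate([[-1.0, -0.5], np.arange(0.0, 8.0, 0.25)])


def test_photocleave_zero_residual_empties_roi(scene):
    tl = make_timeline(scene, _times(), D=1.4)
    pod = scene.podosome_truth[0]
    ev = PerturbationEvent(time=0.0, kind="photocleave", center=pod.centroid,
                           radius=1.0, residual=0.0)
    tl2 = apply_perturbation(tl, ev)
    roi = disk_mask(scene.shape, pod.centroid, 1.0 / scene.pixel_size)
    i_event = int(np.searchsorted(tl2.frame_times, 0.0))
    assert np.all(tl2.frames[i_event].density_field[roi] == 0.0)
    assert np.all(tl2.frames[i_event].fraction_open_field[roi] == 0.0)
    # pre-event frames untouched
    assert np.array_equal(tl2.frames[0].density_field, scene.density_field)


def test_refill_monotone_after_cleavage(scene):
    tl = make_timeline(scene, _times(), D=1.4)
    pod = scene.podosome_truth[0]
    ev = PerturbationEvent(time=0.0, kind="photocleave", center=pod.centroid,
                           radius=1.0, residual=0.0)
    tl2 = apply_perturbation(tl, ev)
    roi = disk_mask(scene.shape, pod.centroid, 1.0 / scene.pixel_size)
    means = [f.density_field[roi].mean() for f in tl2.frames[2:]]
    assert np.all(np.diff(means) >= -1e-12)
    assert means[-1] > 0.5 * means[0] + 0.1  # substantial recovery


def test_mass_conserved_without_events(scene):
    tl = make_timeline(scene, _times(), D=1.4)
    totals = [f.density_field.sum() for f in tl.frames]
    assert np.max(np.abs(np.diff(totals))) / totals[0] < 1e-6


def test_tgt_below_tolerance_leaves_timeline_unchanged(scene):
    probe = ProbeSpecies(name="tgt-56", f_half=np.inf, t_tol=56.0)
    tl = make_timeline(scene, _times(), D=1.4)
    ev = PerturbationEvent(time=0.0, kind="tgt_sink",
                           center=scene.podosome_truth[0].centroid,
                           radius=1.0, sink_rate=2.0, force_pn=19.0)
    tl2 = apply_tgt_sink(tl, ev, probe)
    assert tl2 is tl  # unchanged object: no rupture below T_tol


def test_tgt_above_tolerance_removes_density_where_open(scene):
    probe = ProbeSpecies(name="tgt-12", f_half=np.inf, t_tol=12.0)
    tl = make_timeline(scene, _times(), D=1.4)
    pod = scene.podosome_truth[0]
    ev = PerturbationEvent(time=0.0, kind="tgt_sink", center=pod.centroid,
                           radius=1.0, sink_rate=2.0, force_pn=19.0)
    tl2 = apply_tgt_sink(tl, ev, probe)
    i_event = int(np.searchsorted(tl2.frame_times, 0.0))
    roi = disk_mask(scene.shape, pod.centroid, 1.0 / scene.pixel_size)
    sink = roi & (scene.fraction_open_field > 0)
    assert np.all(
        tl2.frames[i_event].density_field[sink] < scene.density_field[sink]
    )


def test_unknown_event_kind_rejected(scene):
    tl = make_timeline(scene, _times(), D=1.4)
    ev = PerturbationEvent(time=0.0, kind="sorcery", center=(60, 60), radius=1.0)
    with pytest.raises(ValueError, match="unknown event kind"):
        apply_perturbation(tl, ev)


def test_core_retraction_shrinks_truth_radius(scene):
    tl = make_timeline(scene, _times(), D=1.4)
    pod = scene.podosome_truth[0]
    ev = PerturbationEvent(time=0.0, kind="photocleave", center=pod.centroid,
                           radius=1.5, residual=0.0, core_response_factor=0.75)
    tl2 = apply_perturbation(tl, ev)
    post = tl2.frames[-1]
    assert post.podosome_truth[0].core_radius == pytest.approx(0.75 * pod.core_radius)
    # the other podosome is untouched
    assert post.podosome_truth[1].core_radius == pytest.approx(
        scene.podosome_truth[1].core_radius
    )
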