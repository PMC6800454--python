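"""Modulation fitting, tilt inversion, anisotropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtflim.mfm import (
    anisotropy,
    fit_modulation,
    g_factor,
    orientation_from_stack,
    podosome_tilt_summary,
    tilt_angle,
)
from mtflim.polarization import (
    PolarizationStack,
    default_sweep_angles,
    render_polarization_stack,
)
from mtflim.probes import AcquisitionContext

from conftest import make_uniform_scene


def _noiseless_stack(tilt, azimuth, shape=(4, 4)):
    angles = default_sweep_angles()
    from mtflim.polarization import dipole_ring_intensity

    frames = np.empty((len(angles),) + shape)
    for k, a in enumerate(angles):
        frames[k] = 1000.0 * 2.0 * dipole_ring_intensity(a, tilt, azimuth)
    acq = AcquisitionContext()
    return PolarizationStack(images=frames, angles_deg=angles, acq=acq)


def test_constant_sweep_has_zero_amplitude_and_undefined_phase():
    acq = AcquisitionContext()
    angles = default_sweep_angles()
    stack = PolarizationStack(
        images=np.full((len(angles), 3, 3), 500.0), angles_deg=angles, acq=acq
    )
    omap = fit_modulation(stack)
    assert np.allclose(omap.amplitude, 0.0, atol=1e-9)
    assert np.all(np.isnan(omap.phase_deg))


def test_noiseless_phase_recovery():
    omap = fit_modulation(_noiseless_stack(60.0, 30.0))
    assert np.allclose(omap.phase_deg, 30.0, atol=0.5)


def test_phase_equivariance_under_azimuth_rotation():
    """Rotating the scene azimuth by delta rotates the fitted phase by delta
    (mod 180), exactly in the noiseless case."""
    base = fit_modulation(_noiseless_stack(60.0, 20.0)).phase_deg[0, 0]
    for delta in (30.0, 90.0, 140.0):
        rot = fit_modulation(_noiseless_stack(60.0, 20.0 + delta)).phase_deg[0, 0]
        assert ((rot - base - delta + 90) % 180 - 90) == pytest.approx(0.0, abs=1e-6)


def test_tilt_mapping_reference_points():
    theta, cone, sat = tilt_angle(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 1.0 / 3.0]))
    assert theta[0] == pytest.approx(0.0) and cone[0]
    assert theta[1] == pytest.approx(90.0)
    assert theta[2] == pytest.approx(45.0, abs=1e-9)
    assert not sat.any()


def test_tilt_saturation_clip():
    theta, cone, sat = tilt_angle(np.array([1.0]), np.array([1.2]))
    assert theta[0] == pytest.approx(90.0)
    assert sat[0]


@settings(deadline=None, max_examples=30)
@given(st.floats(1.0, 89.0))
def test_tilt_round_trip(theta_true):
    """m(theta) -> theta inversion is exact on the closed form."""
    s2 = np.sin(np.radians(theta_true)) ** 2
    m = s2 / (2.0 - s2)
    theta, _, _ = tilt_angle(np.array([1.0]), np.array([m]))
    assert theta[0] == pytest.approx(theta_true, abs=1e-9)


@pytest.mark.parametrize("tilt", [30.0, 45.0, 60.0, 90.0])
def test_noiseless_tilt_recovery_within_one_degree(probe, tilt):
    scene = make_uniform_scene(shape=(6, 6), fraction_open=1.0, tilt_deg=tilt,
                               azimuth_deg=70.0)
    acq = AcquisitionContext(exposure_scale=2e6, psf_sigma=0.0)
    stack = render_polarization_stack(scene, probe, acq, seed=2, closed_residual=0.0)
    omap = orientation_from_stack(stack)
    assert abs(float(np.mean(omap.tilt_deg)) - tilt) <= 1.0


def test_podosome_tilt_summary_mean_and_cone(probe):
    from mtflim.podosomes import PodosomeRecord

    shape = (10, 10)
    tilt = np.full(shape, 21.0)
    omap_like = orientation_map_stub(tilt)
    ring = np.zeros(shape, bool)
    ring[2:5, 2:5] = True
    rec = PodosomeRecord(id=0, frame=0, centroid=(3, 3), core_radius=0.3,
                         depletion_pct=80.0, core_mask=np.zeros(shape, bool),
                         ring_mask=ring)
    df, summary = podosome_tilt_summary([rec], omap_like)
    assert summary["cell_mean_tilt_deg"] == pytest.approx(21.0)
    # inside-cone truth propagates the flag
    omap_cone = orientation_map_stub(np.full(shape, 10.0))
    _, s2 = podosome_tilt_summary([rec], omap_cone)
    assert s2["vertical_cone_fraction"] == pytest.approx(1.0)


def orientation_map_stub(tilt):
    from mtflim.mfm import OrientationMap

    shape = tilt.shape
    return OrientationMap(
        offset=np.ones(shape),
        amplitude=np.zeros(shape),
        phase_deg=np.zeros(shape),
        tilt_deg=tilt,
        vertical_cone=tilt < 20.0,
        saturated=np.zeros(shape, bool),
        residual=np.zeros(shape),
    )


def test_g_factor_and_anisotropy_reference_values():
    rng = np.random.default_rng(0)
    ref_par = rng.poisson(1100, size=10000)
    ref_perp = rng.poisson(1000, size=10000)
    G = g_factor(ref_par, ref_perp)
    assert G == pytest.approx(1.1, rel=0.02)
    r = anisotropy(np.array([2.0]), np.array([1.0]), 1.0)
    assert r[0] == pytest.approx(0.25)
    assert anisotropy(np.array([5.0]), np.array([0.0]), 1.3)[0] == pytest.approx(1.0)
    # isotropic field: r = 0 +/- 0.005
    i_perp = rng.poisson(20000, size=(50, 50))
    i_par = rng.poisson(20000 * 1.1, size=(50, 50))
    r_iso = anisotropy(i_par, i_perp, 1.1)
    assert abs(np.nanmean(r_iso)) < 0.005
    # masked where denominator vanishes
    assert np.isnan(anisotropy(np.array([0.0]), np.array([0.0]), 1.0)[0])
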