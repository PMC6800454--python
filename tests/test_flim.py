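"""Barycenter lifetimes, calibration, percent-open and density equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtflim.flim import (
    build_calibration,
    density_map,
    fast_flim,
    forward_mixture_intensity,
    forward_mixture_lifetime,
    lifetime_precision,
    percent_open_map,
    quenching_efficiency,
    state_barycenter,
    validity_mask,
)
from mtflim.probes import AcquisitionContext, ProbeSpecies
from mtflim.tcspc import TCSPCImage


def _cube_from_hist(hist, acq):
    return TCSPCImage(histogram=np.asarray(hist, dtype=np.uint32), acq=acq)


def test_barycenter_point_mass():
    """All photons of a pixel in the bin at 2.0 ns past the pulse peak."""
    acq = AcquisitionContext()
    dt = acq.bin_width
    hist = np.zeros((1, 2, acq.n_time_bins))
    hist[0, 0, 0] = 1000  # bright first bin fixes the pooled peak at t=dt/2
    i = int(round(2.0 / dt))  # bin centre at 2.0 + dt/2
    hist[0, 1, i] = 50
    fmap = fast_flim(_cube_from_hist(hist, acq))
    assert fmap.t_peak == pytest.approx(dt / 2)
    assert fmap.avg_lifetime[0, 1] == pytest.approx(2.0, abs=1e-9)


def test_barycenter_two_point_masses_weighted_mean():
    """Masses at 1 and 3 ns with counts 1:3 average to 2.5 ns."""
    acq = AcquisitionContext()
    dt = acq.bin_width
    hist = np.zeros((1, 2, acq.n_time_bins))
    hist[0, 0, 0] = 10000
    hist[0, 1, int(round(1.0 / dt))] = 100
    hist[0, 1, int(round(3.0 / dt))] = 300
    fmap = fast_flim(_cube_from_hist(hist, acq))
    assert fmap.avg_lifetime[0, 1] == pytest.approx(2.5, abs=1e-9)


def test_truncated_mono_exponential_closed_form():
    """Gated mono-exponential barycenter: tau - T e^(-T/tau)/(1 - e^(-T/tau))."""
    assert state_barycenter(((1.0, 1.5),), 12.5) == pytest.approx(1.49700, abs=1e-4)
    # numerical-integration oracle
    from scipy.integrate import quad

    tau, T = 1.5, 12.5
    num = quad(lambda t: t * np.exp(-t / tau), 0, T)[0]
    den = quad(lambda t: np.exp(-t / tau), 0, T)[0]
    assert state_barycenter(((1.0, tau),), T) == pytest.approx(num / den, rel=1e-9)


def test_empty_cube_raises():
    acq = AcquisitionContext(n_time_bins=8)
    with pytest.raises(ValueError, match="empty"):
        fast_flim(_cube_from_hist(np.zeros((2, 2, 8)), acq))


def test_validity_mask_boundaries():
    """Exclusion is '<25 photons or tau > 2.97 ns', so both boundaries are
    inclusive on the valid side."""
    acq = AcquisitionContext()
    from mtflim.flim import FastFLIMMap

    counts = np.array([[24, 25, 10000]])
    tau = np.array([[1.0, 2.97, 3.1]])
    m = FastFLIMMap(
        photon_counts=counts, avg_lifetime=tau,
        valid_mask=counts > 0, acq=acq,
    )
    mask = validity_mask(m)
    assert mask.tolist() == [[False, True, False]]


def test_quenching_efficiency_examples():
    assert quenching_efficiency(1000.0, 220.0) == pytest.approx(0.78)
    assert quenching_efficiency(5.0, 5.0) == 0.0
    assert quenching_efficiency(7.0, 0.0) == 1.0
    with pytest.warns(UserWarning):
        assert quenching_efficiency(100.0, 120.0) < 0


def test_forward_mixture_endpoints_and_arithmetic():
    probe = ProbeSpecies(
        name="t", f_half=4.7, brightness_closed=0.22,
        decay_open=((1.0, 2.8),), decay_closed=((1.0, 0.9),),
    )
    T = 1e4  # effectively ungated
    assert forward_mixture_lifetime(probe, 0.0, T) == pytest.approx(0.9, rel=1e-6)
    assert forward_mixture_lifetime(probe, 1.0, T) == pytest.approx(2.8, rel=1e-6)
    # (0.5*2.8 + 0.5*0.22*0.9) / (0.5 + 0.11) = 1.499 / 0.61
    assert forward_mixture_lifetime(probe, 0.5, T) == pytest.approx(
        1.499 / 0.61, rel=1e-6
    )


@settings(deadline=None, max_examples=25)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_forward_mixture_monotone_in_f(f1, f2):
    from mtflim.probes import default_hairpin_probe

    probe = default_hairpin_probe()
    lo, hi = sorted((f1, f2))
    assert forward_mixture_lifetime(probe, lo) <= forward_mixture_lifetime(probe, hi) + 1e-12


def _calibration_samples(probe, n=11):
    fr = np.linspace(0.0, 1.0, n)
    return [
        (f, forward_mixture_lifetime(probe, f), forward_mixture_intensity(probe, f))
        for f in fr
    ]


def test_calibration_round_trip_and_quality():
    from mtflim.probes import default_hairpin_probe

    probe = default_hairpin_probe()
    samples = _calibration_samples(probe)
    cal = build_calibration(samples)
    fr = np.array([s[0] for s in samples])
    tau = np.array([s[1] for s in samples])
    assert np.max(np.abs(cal.tau_of_f(fr) - tau) / tau) < 0.01
    assert cal.r_squared_intensity >= 0.999
    assert cal.quenching_efficiency == pytest.approx(
        probe.quenching_efficiency, abs=1e-9
    )
    # fitted curve strictly increasing
    grid = cal.tau_of_f(np.linspace(0, 1, 500))
    assert np.all(np.diff(grid) > 0)


def test_calibration_rejects_non_monotone():
    bad = [(0.0, 1.0, 0.2), (0.3, 2.0, 0.4), (0.6, 1.8, 0.6), (1.0, 2.5, 1.0)]
    with pytest.raises(ValueError, match="non-monotone"):
        build_calibration(bad)


def test_calibration_requires_endpoints():
    probe_samples = [(0.1, 1.0, 0.3), (0.4, 1.5, 0.5), (0.7, 2.0, 0.7), (0.9, 2.2, 0.9)]
    with pytest.raises(ValueError, match="endpoint"):
        build_calibration(probe_samples)


def test_percent_open_endpoints_and_clamping():
    from mtflim.flim import FastFLIMMap
    from mtflim.probes import default_hairpin_probe

    probe = default_hairpin_probe()
    cal = build_calibration(_calibration_samples(probe))
    acq = AcquisitionContext()
    tau = np.array([[cal.tau_min, cal.tau_max, cal.tau_min - 0.5, cal.tau_max + 0.5]])
    counts = np.full(tau.shape, 1000)
    m = FastFLIMMap(photon_counts=counts, avg_lifetime=tau,
                    valid_mask=np.ones(tau.shape, bool), acq=acq)
    F, oor = percent_open_map(m, cal)
    assert F[0, 0] == pytest.approx(0.0, abs=1e-6)
    assert F[0, 1] == pytest.approx(1.0, abs=1e-6)
    assert F[0, 2] == 0.0 and F[0, 3] == 1.0
    assert oor.tolist() == [[False, False, True, True]]


def test_density_equation_reference_cases():
    # background pixel
    assert density_map(np.array([100.0]), np.array([0.0]), 100.0, 0.0, 0.78)[
        0
    ] == pytest.approx(1.0)
    # fully open unit density: I - D = (I0 - D)/(1 - QE)
    qe = 0.78
    i = 100.0 / (1 - qe)
    assert density_map(np.array([i]), np.array([1.0]), 100.0, 0.0, qe)[
        0
    ] == pytest.approx(1.0)
    # direct substitution
    val = density_map(np.array([200.0]), np.array([0.5]), 100.0, 0.0, 0.78)[0]
    assert val == pytest.approx(200.0 / (100.0 / 0.22 * 0.5 + 100.0 * 0.5), rel=1e-12)
    assert val == pytest.approx(0.721, abs=5e-4)
    with pytest.raises(ValueError):
        density_map(np.array([1.0]), np.array([0.0]), 1.0, 2.0, 0.78)


def test_linear_probe_forces_f_zero():
    out = density_map(np.array([150.0]), np.array([0.9]), 100.0, 0.0, 0.78,
                      linear_probe=True)
    assert out[0] == pytest.approx(1.5)


def test_lifetime_precision_scaling_and_monte_carlo():
    assert lifetime_precision(400, 2.0) == pytest.approx(0.1)
    assert lifetime_precision(1e12, 2.0) < 1e-5
    rng = np.random.default_rng(5)
    stds = [
        rng.exponential(2.0, size=100).mean() for _ in range(4000)
    ]
    assert abs(np.std(stds) - 0.2) / 0.2 < 0.2
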