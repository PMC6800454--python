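"""Bilayer diffusion stepping and FRAP recovery fitting."""

import numpy as np
import pytest

from mtflim.diffusion import diffuse, disk_mask, render_frap_movie
from mtflim.frap import (
    RecoveryFitError,
    diffusion_coefficient,
    fit_recovery,
    frap_halftime,
    FRAPSeries,
    roi_timeseries,
)
from mtflim.probes import AcquisitionContext


def test_frozen_field_when_d_zero():
    acq = AcquisitionContext(exposure_scale=500.0)
    times = np.concatenate([[-1.0], np.arange(0.0, 5.0, 0.5)])
    movie, roi, tt = render_frap_movie(0.0, 1.0, acq, times, photon_noise=False)
    y = roi_timeseries(movie, roi)
    assert np.allclose(y[1:], y[1])  # constant after bleach


def test_mass_conservation_outside_bleach():
    acq = AcquisitionContext(exposure_scale=100.0)
    times = np.concatenate([[-1.0], np.arange(0.0, 8.0, 0.5)])
    movie, roi, tt = render_frap_movie(1.4, 1.0, acq, times, photon_noise=False)
    totals = movie.sum(axis=(1, 2))
    # post-bleach frames conserve total intensity to 1e-6 relative
    assert np.max(np.abs(totals[1:] - totals[1]) / totals[1]) < 1e-6


def test_diffuse_stability_error_for_subpixel_kernel():
    field = np.ones((32, 32))
    with pytest.raises(ValueError, match="kernel"):
        diffuse(field, D=0.001, dt=0.01, pixel_size=0.1)


def test_margin_requirement():
    acq = AcquisitionContext()
    with pytest.raises(ValueError, match="margin"):
        render_frap_movie(1.0, 2.0, acq, [0.0, 1.0], shape=(60, 60))


def test_exact_exponential_halftime():
    """A recovery with rate ln 2 per second has a 1 s half-time."""
    t = np.concatenate([[-1.0], np.linspace(0.0, 10.0, 60)])
    y = np.where(t < 0, 1.0, 0.3 + 0.7 * (1 - np.exp(-np.log(2.0) * np.maximum(t, 0))))
    series = fit_recovery(t, y)
    assert series.t_half == pytest.approx(1.0, rel=1e-6)


def test_halftime_invariant_to_intensity_scaling():
    t = np.concatenate([[-1.0], np.linspace(0.0, 10.0, 40)])
    y = np.where(t < 0, 1.0, 0.2 + 0.8 * (1 - np.exp(-0.9 * np.maximum(t, 0))))
    a = fit_recovery(t, y).t_half
    b = fit_recovery(t, 137.0 * y).t_half
    assert a == pytest.approx(b, rel=1e-9)


def test_flat_series_raises():
    t = np.concatenate([[-1.0], np.linspace(0.0, 5.0, 20)])
    y = np.where(t < 0, 1.0, 0.3 * np.ones_like(t))
    with pytest.raises(RecoveryFitError, match="amplitude"):
        fit_recovery(t, y)


def test_diffusion_coefficient_substitutions():
    assert diffusion_coefficient(2.0, 1.0) == pytest.approx(1.0)
    assert diffusion_coefficient(2.0, 0.709) == pytest.approx(1.41, abs=0.005)
    assert diffusion_coefficient(4.0, 1.0) == 4 * diffusion_coefficient(2.0, 1.0)
    with pytest.raises(ValueError):
        diffusion_coefficient(-1.0, 1.0)


def test_round_trip_d_recovery_single_case():
    """Grid-diffusion round trip at the bilayer's measured diffusivity."""
    acq = AcquisitionContext(exposure_scale=1000.0)
    D, w = 1.4, 2.0
    T = w**2 / (4 * D)
    times = np.concatenate([[-1.0, -0.5], np.arange(0.0, 10.001, 0.05)]) * T
    movie, roi, tt = render_frap_movie(D, w, acq, times, seed=9)
    series = fit_recovery(tt, roi_timeseries(movie, roi), 0.0, bleach_radius=w)
    assert abs(series.D - D) / D <= 0.25
    # recovery curve monotone non-decreasing in the noiseless rendering
    quiet, _, _ = render_frap_movie(D, w, acq, times, photon_noise=False)
    yq = roi_timeseries(quiet, roi)
    post = tt >= 0
    assert np.all(np.diff(yq[post]) >= -1e-12)


def test_frap_halftime_accessor():
    t = np.concatenate([[-1.0], np.linspace(0.0, 10.0, 40)])
    y = np.where(t < 0, 1.0, 0.2 + 0.8 * (1 - np.exp(-0.5 * np.maximum(t, 0))))
    series = FRAPSeries(times=t, roi_mean=y, bleach_radius=2.0)
    th = frap_halftime(series)
    assert th == pytest.approx(np.log(2) / 0.5, rel=1e-6)
    assert series.D == pytest.approx(diffusion_coefficient(2.0, th))
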