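"""Probe photophysics and acquisition settings.

A DNA-hairpin tension probe is a two-state emitter: *closed* (FRET-quenched,
dim, short-lived) and *open* (unquenched, bright, long-lived).  Each state is
described by a multi-exponential fluorescence decay and a relative brightness;
the ratio of closed to open brightness fixes the quenching efficiency
``QE = 1 - brightness_closed / brightness_open``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeSpecies",
    "AcquisitionContext",
    "default_hairpin_probe",
    "default_acquisition",
]

_AMP_TOL = 1e-9


def _validate_decay(decay: tuple[tuple[float, float], ...], label: str) -> None:
    amps = np.array([a for a, _ in decay], dtype=float)
    taus = np.array([t for _, t in decay], dtype=float)
    if abs(amps.sum() - 1.0) > _AMP_TOL:
        raise ValueError(f"{label} decay amplitudes sum to {amps.sum()}, not 1")
    if np.any(taus <= 0):
        raise ValueError(f"{label} decay lifetimes must be positive")
    if np.any(amps < 0):
        raise ValueError(f"{label} decay amplitudes must be non-negative")


@dataclass(frozen=True)
class ProbeSpecies:
    """Two-state DNA tension probe.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"hairpin-4.7pN"``.
    f_half:
        Force at which half the hairpins are open at equilibrium (pN).
    brightness_open, brightness_closed:
        Relative photon rates of the two states; open state is the
        reference (1.0).
    decay_open, decay_closed:
        Multi-exponential decays as ``((amplitude, lifetime_ns), ...)``;
        amplitudes are photon fractions and sum to one.
    t_tol:
        Rupture tolerance (pN) for tension-gauge-tether mode; ``None`` for
        reversible hairpins.
    """

    name: str
    f_half: float
    brightness_open: float = 1.0
    brightness_closed: float = 0.22
    decay_open: tuple[tuple[float, float], ...] = ((1.0, 2.85),)
    decay_closed: tuple[tuple[float, float], ...] = ((0.7, 0.35), (0.3, 1.6))
    t_tol: float | None = None

    def __post_init__(self) -> None:
        _validate_decay(tuple(self.decay_open), "open")
        _validate_decay(tuple(self.decay_closed), "closed")
        if not (0 < self.brightness_closed <= self.brightness_open):
            raise ValueError("require 0 < brightness_closed <= brightness_open")

    @property
    def quenching_efficiency(self) -> float:
        """Fractional intensity loss of the closed relative to the open state."""
        return 1.0 - self.brightness_closed / self.brightness_open


@dataclass(frozen=True)
class AcquisitionContext:
    """TCSPC / camera acquisition geometry and photon budget.

    ``exposure_scale`` is the expected photon count per pixel for a fully
    open, unit-density probe field under flat illumination; ``dark_counts``
    is the expected background count per pixel (the ``D`` of the density
    equation).
    """

    pixel_size: float = 0.1  # um
    n_time_bins: int = 400
    time_window: float = 12.5  # ns
    pulse_period: float = 50.0  # ns (20 MHz)
    exposure_scale: float = 500.0  # photons / pixel / unit density, open state
    dark_counts: float = 0.0
    psf_sigma: float = 0.1  # um
    illumination_profile: np.ndarray | None = None  # per-pixel, strictly > 0

    def __post_init__(self) -> None:
        if self.n_time_bins < 2:
            raise ValueError("n_time_bins must be >= 2")
        if self.time_window > self.pulse_period:
            raise ValueError("time_window cannot exceed pulse_period")
        if self.exposure_scale <= 0:
            raise ValueError("exposure_scale must be positive")
        if self.illumination_profile is not None and np.any(
            np.asarray(self.illumination_profile) <= 0
        ):
            raise ValueError("illumination_profile must be strictly positive")

    @property
    def bin_width(self) -> float:
        return self.time_window / self.n_time_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_time_bins + 1) * self.bin_width

    def illumination(self, shape: tuple[int, int]) -> np.ndarray:
        if self.illumination_profile is None:
            return np.ones(shape)
        prof = np.asarray(self.illumination_profile, dtype=float)
        if prof.shape != shape:
            raise ValueError("illumination profile shape mismatch")
        return prof


def default_hairpin_probe(f_half: float = 4.7) -> ProbeSpecies:
    """Default hairpin probe: 78% quenched when folded, open-state barycenter
    ~2.7 ns inside the 12.5 ns gate."""
    return ProbeSpecies(name=f"hairpin-{f_half}pN", f_half=f_half)


def default_acquisition(**overrides) -> AcquisitionContext:
    """Default TCSPC settings: 400 bins over 0-12.5 ns at 20 MHz pulsing."""
    return AcquisitionContext(**overrides)
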