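"""Self-contained recovery experiments on synthetic data.

Each function builds its own inputs with the scene generator, runs the
corresponding analysis stage and returns the recovered quantities next to
the ground truth.  The analysis drivers, the validation tests and the
acceptance script all call these, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .diffusion import disk_mask, render_frap_movie
from .flim import (
    build_calibration,
    density_map,
    fast_flim,
    forward_mixture_intensity,
    forward_mixture_lifetime,
    measure_calibration_samples,
    percent_open_map,
    validity_mask,
)
from .force import ForceModelParams, podosome_force
from .frap import fit_recovery, recovery_after_cleavage, roi_timeseries
from .mfm import orientation_from_stack
from .podosomes import detect_clusters, detect_podosomes, link_tracks, \
    perturbation_response, ring_tension_stats
from .polarization import (
    default_sweep_angles,
    dipole_ring_intensity,
    monte_carlo_ring_intensity,
    render_polarization_stack,
)
from .probes import AcquisitionContext, default_hairpin_probe
from .scene import SceneConfig, build_scene
from .tcspc import render_tcspc
from .timeline import (
    PerturbationEvent,
    apply_perturbation,
    make_timeline,
    render_timeline_intensity,
    render_timeline_tension,
)

RING_TRUTH_F = 0.10  # modeled fraction of open probes in the podosome ring


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def calibration_roundtrip(n_fractions: int = 11) -> dict:
    """Fit the calibration to noiseless forward-model samples and measure the
    worst-case relative error of the fitted curve at the sample fractions."""
    probe = default_hairpin_probe()
    fr = np.linspace(0.0, 1.0, n_fractions)
    samples = [
        (f, forward_mixture_lifetime(probe, f), forward_mixture_intensity(probe, f))
        for f in fr
    ]
    cal = build_calibration(samples)
    tau = np.array([s[1] for s in samples])
    max_rel = float(np.max(np.abs(cal.tau_of_f(fr) - tau) / tau))
    return {
        "max_rel_err_pct": 100.0 * max_rel,
        "intensity_r2": float(cal.r_squared_intensity),
        "quenching_efficiency": float(cal.quenching_efficiency),
        "n_fractions": n_fractions,
    }


def ring_percent_open_recovery(
    seed: int,
    n_podosomes: int = 20,
    photons_per_pixel: float = 500.0,
    shape: tuple[int, int] = (320, 320),
) -> dict:
    """Full image pipeline on a podosome field with 10% open ring probes."""
    s_scene, s_render, s_cal = _spawn_seeds(seed, 3)
    probe = default_hairpin_probe()
    acq = AcquisitionContext(exposure_scale=photons_per_pixel)
    scene = build_scene(
        SceneConfig(shape=shape, n_podosomes=n_podosomes,
                    ring_fraction_open=RING_TRUTH_F),
        seed=s_scene,
    )
    cube = render_tcspc(scene, probe, acq, seed=s_render)
    fmap = fast_flim(cube)
    vmask = validity_mask(fmap)
    cal = build_calibration(
        measure_calibration_samples(probe, acq, np.linspace(0, 1, 11), seed=s_cal)
    )
    F, _ = percent_open_map(fmap, cal, vmask)
    bilayer = vmask & (scene.fraction_open_field == 0) & (scene.density_field == 1)
    i0 = float(cube.photon_counts[bilayer].mean())
    rho = density_map(cube.photon_counts.astype(float), F, i0, 0.0,
                      cal.quenching_efficiency)
    records = detect_podosomes(cube.photon_counts.astype(float), i0,
                               pixel_size=acq.pixel_size)
    _, summary = ring_tension_stats(records, F, rho, vmask)
    return {
        "cell_mean_F": summary["cell_mean_F"],
        "truth_F": RING_TRUTH_F,
        "n_podosomes": summary["n_podosomes"],
        "photons_per_pixel": photons_per_pixel,
    }


def density_recovery(
    seed: int,
    photons_per_pixel: float = 300.0,
    shape: tuple[int, int] = (240, 240),
) -> dict:
    """Cluster (rho = 2, F = 0) and bare-bilayer (rho = 1) density recovery."""
    s_scene, s_render, s_cal = _spawn_seeds(seed, 3)
    probe = default_hairpin_probe()
    acq = AcquisitionContext(exposure_scale=photons_per_pixel)
    scene = build_scene(
        SceneConfig(shape=shape, n_podosomes=3, n_clusters=4,
                    cluster_density=2.0, cluster_radius=0.6),
        seed=s_scene,
    )
    cube = render_tcspc(scene, probe, acq, seed=s_render)
    fmap = fast_flim(cube)
    vmask = validity_mask(fmap)
    cal = build_calibration(
        measure_calibration_samples(probe, acq, np.linspace(0, 1, 11), seed=s_cal)
    )
    F, _ = percent_open_map(fmap, cal, vmask)
    from scipy.ndimage import binary_erosion

    bilayer = vmask & (scene.fraction_open_field == 0) & (scene.density_field == 1)
    bilayer = binary_erosion(bilayer, iterations=4)
    i0 = float(cube.photon_counts[bilayer].mean())
    rho = density_map(cube.photon_counts.astype(float), F, i0, 0.0,
                      cal.quenching_efficiency)
    records = detect_podosomes(cube.photon_counts.astype(float), i0,
                               pixel_size=acq.pixel_size)
    clusters = detect_clusters(
        cube.photon_counts.astype(float) / i0, records, background=1.0,
        pixel_size=acq.pixel_size, F_map=F, rho_map=rho,
    )
    return {
        "bare_bilayer_rho": float(np.nanmean(rho[bilayer])),
        "cluster_rho": float(np.mean([c.mean_density for c in clusters])),
        "cluster_F": float(np.mean([c.mean_F for c in clusters])),
        "truth_cluster_rho": 2.0,
        "n_clusters": len(clusters),
    }


def lifetime_photon_scaling(
    seed: int,
    photon_levels: tuple[float, ...] = (25.0, 100.0, 400.0, 1600.0),
    shape: tuple[int, int] = (48, 48),
) -> dict:
    """Scaling of the per-pixel barycenter-lifetime spread with photon count.

    Uniform closed-probe fields are rendered at increasing photon budget; the
    empirical standard deviation across valid pixels should fall as
    N^(-1/2).  Also verifies the validity mask equals the stated photon /
    lifetime cutoffs exactly.
    """
    from .scene import Scene

    probe = default_hairpin_probe()
    seeds = _spawn_seeds(seed, len(photon_levels))
    log_n, log_std = [], []
    mask_exact = True
    for photons, s in zip(photon_levels, seeds):
        scale = photons / probe.brightness_closed
        acq = AcquisitionContext(exposure_scale=scale)
        scene = Scene(
            shape=shape, pixel_size=acq.pixel_size,
            density_field=np.ones(shape), fraction_open_field=np.zeros(shape),
            tilt_field=np.zeros(shape), azimuth_field=np.zeros(shape),
            podosome_truth=[], cluster_truth=[], cell_mask=np.ones(shape, bool),
            seed=s,
        )
        cube = render_tcspc(scene, probe, acq, seed=s)
        fmap = fast_flim(cube)
        vmask = validity_mask(fmap)
        expected_mask = (cube.photon_counts >= 25) & (fmap.avg_lifetime <= 2.97)
        mask_exact &= bool(np.array_equal(vmask, expected_mask & fmap.valid_mask))
        n_eff = float(cube.photon_counts[vmask].mean())
        log_n.append(np.log(n_eff))
        log_std.append(np.log(float(np.std(fmap.avg_lifetime[vmask], ddof=1))))
    slope = float(np.polyfit(log_n, log_std, 1)[0])
    return {"slope": slope, "mask_exact": mask_exact,
            "photon_levels": list(photon_levels)}


def mfm_tilt_recovery(
    seed: int,
    tilts: tuple[float, ...] = (30.0, 45.0, 60.0, 90.0),
    photons_per_sweep: float = 5e3,
) -> dict:
    """Noiseless and Poisson-noise tilt recovery on uniform oriented fields."""
    from .scene import Scene

    probe = default_hairpin_probe()
    seeds = _spawn_seeds(seed, 2 * len(tilts))
    noiseless_err, noisy_err = [], []
    for i, tilt in enumerate(tilts):
        for noisy in (False, True):
            shape = (24, 24) if noisy else (6, 6)
            scene = Scene(
                shape=shape, pixel_size=0.1,
                density_field=np.ones(shape),
                fraction_open_field=np.ones(shape),
                tilt_field=np.full(shape, tilt),
                azimuth_field=np.full(shape, 37.0),
                podosome_truth=[], cluster_truth=[],
                cell_mask=np.ones(shape, bool), seed=0,
            )
            per_frame = photons_per_sweep / 73.0 if noisy else 1e7
            acq = AcquisitionContext(exposure_scale=per_frame, psf_sigma=0.0)
            stack = render_polarization_stack(
                scene, probe, acq, seed=seeds[2 * i + int(noisy)],
                closed_residual=0.0,
            )
            omap = orientation_from_stack(stack)
            err = abs(float(np.mean(omap.tilt_deg)) - tilt)
            (noisy_err if noisy else noiseless_err).append(err)
    return {
        "max_err_noiseless_deg": float(max(noiseless_err)),
        "max_err_noisy_deg": float(max(noisy_err)),
        "tilts": list(tilts),
        "photons_per_sweep": photons_per_sweep,
    }


def vertical_cone_flag_rate(
    seed: int,
    n_trials: int = 40,
    photons_per_sweep: float = 5e3,
    cone_angle: float = 20.0,
) -> dict:
    """Fraction of near-vertical podosomes flagged inside the sensitivity cone.

    Each trial is one podosome-scale patch with a true tilt drawn uniformly
    inside the cone; the per-podosome mean tilt must be flagged vertical.
    """
    from .scene import Scene

    probe = default_hairpin_probe()
    rng = np.random.default_rng(seed)
    seeds = _spawn_seeds(seed + 1, n_trials)
    flagged = 0
    for t in range(n_trials):
        tilt = rng.uniform(0.0, cone_angle)
        shape = (8, 8)
        scene = Scene(
            shape=shape, pixel_size=0.1,
            density_field=np.ones(shape), fraction_open_field=np.ones(shape),
            tilt_field=np.full(shape, tilt),
            azimuth_field=np.full(shape, rng.uniform(0, 180)),
            podosome_truth=[], cluster_truth=[],
            cell_mask=np.ones(shape, bool), seed=0,
        )
        acq = AcquisitionContext(exposure_scale=photons_per_sweep / 73.0,
                                 psf_sigma=0.0)
        stack = render_polarization_stack(scene, probe, acq, seed=seeds[t],
                                          closed_residual=0.0)
        omap = orientation_from_stack(stack, cone_angle=cone_angle)
        if float(np.mean(omap.tilt_deg)) < cone_angle:
            flagged += 1
    return {"flag_rate": flagged / n_trials, "n_trials": n_trials}


def modulation_oracle_agreement(
    seed: int, tilts: tuple[float, ...] = (0.0, 30.0, 45.0, 60.0, 90.0)
) -> dict:
    """Closed-form dipole-ring modulation vs brute-force Monte-Carlo dipoles."""
    angles = default_sweep_angles()
    max_dev = 0.0
    for tilt in tilts:
        cf = dipole_ring_intensity(angles, tilt, 40.0)
        mc = monte_carlo_ring_intensity(angles, tilt, 40.0, n_dipoles=100_000,
                                        seed=seed)
        max_dev = max(max_dev, float(np.max(np.abs(mc - cf) / np.maximum(cf, 0.05))))
    return {"max_dev_pct": 100.0 * max_dev, "tilts": list(tilts)}


def frap_d_recovery(
    seed: int, d_values: tuple[float, ...] = (0.5, 1.4, 3.0), w: float = 2.0
) -> dict:
    """Round-trip D estimation on grid-diffusion FRAP simulations.

    The frame schedule scales with the nominal recovery time w^2/(4 D), as an
    experimenter matches the frame rate to the recovery speed.
    """
    acq = AcquisitionContext(exposure_scale=1000.0)
    base = np.concatenate([[-1.0, -0.5], np.arange(0.0, 10.001, 0.05)])
    seeds = _spawn_seeds(seed, len(d_values))
    out = {}
    rel_errs = []
    for D, s in zip(d_values, seeds):
        times = base * w**2 / (4.0 * D)
        movie, roi, tt = render_frap_movie(D, w, acq, times, seed=s)
        series = fit_recovery(tt, roi_timeseries(movie, roi), 0.0, bleach_radius=w)
        out[D] = series.D
        rel_errs.append(abs(series.D - D) / D)
    # conservation in the absence of bleaching
    quiet, _, _ = render_frap_movie(1.4, w, acq, base[2:] + 1.0, bleach_time=-10.0,
                                    bleach_residual=1.0, photon_noise=False)
    totals = quiet.sum(axis=(1, 2))
    conservation = float(np.max(np.abs(totals - totals[0]) / totals[0]))
    return {
        "estimates": out,
        "max_rel_err": float(max(rel_errs)),
        "mass_conservation": conservation,
    }


def perturbation_locality(
    seed: int,
    D: float = 1.4,
    roi_radius: float = 1.5,
    response_factor: float = 0.75,
) -> dict:
    """Photocleavage under one podosome: local retraction, distal silence and
    diffusive tension recovery compared with the FRAP of the same ROI."""
    s_scene, s_frap = _spawn_seeds(seed, 2)
    probe = default_hairpin_probe()
    acq = AcquisitionContext(exposure_scale=500.0)
    scene = build_scene(
        SceneConfig(shape=(240, 240), n_podosomes=6, min_separation=2.0),
        seed=s_scene,
    )
    times = np.concatenate([[-1.0, -0.5], np.arange(0.0, 10.0, 0.25)])
    tl = make_timeline(scene, times, D=D)
    target = scene.podosome_truth[0]
    event = PerturbationEvent(
        time=0.0, kind="photocleave", center=target.centroid, radius=roi_radius,
        residual=0.0, core_response_factor=response_factor,
    )
    tl2 = apply_perturbation(tl, event)
    roi = disk_mask(scene.shape, target.centroid, roi_radius / scene.pixel_size)

    # podosome radii from the density channel: one pre-event frame and one
    # after the cleaved region has replenished enough for the retracted core
    # boundary to re-sharpen
    density = render_timeline_intensity(tl2, probe, acq)
    i0 = float(np.median(density[0]))
    k_post = len(times) - 1
    frames = [
        detect_podosomes(density[k], i0, pixel_size=scene.pixel_size, frame=f)
        for f, k in enumerate((1, k_post))
    ]
    tracks = link_tracks(frames, gating_radius=0.5, pixel_size=scene.pixel_size)
    df, groups = perturbation_response(tracks, roi, t_event=0.5,
                                       frame_times=[0.0, 1.0])

    # tension recovery vs FRAP of an equivalent ROI on the same schedule
    tension = render_timeline_tension(tl2, probe, acq)
    rec = recovery_after_cleavage(times, tension, roi, 0.0)
    movie, roi2, tt = render_frap_movie(D, roi_radius, acq, times, seed=s_frap,
                                        photon_noise=False)
    frap_fit = fit_recovery(tt, roi_timeseries(movie, roi2), 0.0)
    return {
        "proximal_pct": groups.get("proximal", np.nan),
        "distal_pct": groups.get("distal", np.nan),
        "recovery_t_half": rec.t_half,
        "frap_t_half": frap_fit.t_half,
        "t_half_ratio": rec.t_half / frap_fit.t_half,
        "n_tracks": len(df),
    }


def force_model_reference() -> dict:
    """Ring force model at the modeled podosome parameterization, checked
    against an independent hand evaluation."""
    params = ForceModelParams(R=1.0, r=0.3, biotin_mol_fraction=0.001, d=1.0,
                              rho=1.0, O=0.1, F_int=19.0)
    f_pod, band = podosome_force(params, d_band=(0.5, 2.0))
    hand = np.pi * (1.0 - 0.09) * (1e6 * 0.001 / 0.72) * 1.0 * 1.0 * 19.0 * 0.1
    return {
        "F_pod_pN": f_pod,
        "F_pod_nN": f_pod / 1000.0,
        "hand_value_pN": float(hand),
        "rel_dev": abs(f_pod - hand) / hand,
        "band_nN": [band[0] / 1000.0, band[1] / 1000.0],
    }
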