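# Methods

`mtflim` implements the quantitative analysis chain for DNA-hairpin FRET
tension probes on fluid supported lipid bilayers (SLBs), together with a
photon-realistic simulator that generates every input the analysis consumes.
This note records the models, the defaults and why they were chosen, and what
the synthetic validation does and does not demonstrate.

## Probe photophysics and the fast-FLIM estimator

A hairpin tension probe is modeled as a two-state emitter. The closed
(FRET-quenched) state has relative brightness `B_c` and a multi-exponential
decay; the open state has brightness `B_o = 1` and a longer-lived decay. The
quenching efficiency is `QE = 1 - B_c / B_o`. Default states:

- closed: biexponential, amplitudes (0.7, 0.3), lifetimes (0.35, 1.6) ns,
  `B_c = 0.22` (78% quenched when folded);
- open: mono-exponential, 2.85 ns.

These defaults are free parameters of the simulator: they were chosen so the
closed/open brightness ratio matches the measured quenching efficiency of
this probe class and so the open-state average lifetime (~2.7 ns after
gating) sits below the 2.97 ns validity cutoff. Every decay constant is
config-overridable.

The per-pixel average lifetime is the **barycenter of photon arrival time**
(fit-free FLIM): the count-weighted mean of the bin centres minus the arrival
time of the pooled-histogram peak, which proxies the excitation pulse. The
origin convention (subtracting the pooled peak) is a package choice; with the
delta instrument response of the simulator the peak is the first bin. For a
mono-exponential decay gated to a window `T` the barycenter is
`tau - T e^(-T/tau) / (1 - e^(-T/tau))`; mixtures combine states weighted by
brightness times within-gate detected fraction. Because of the
multi-exponential decays, the barycenter is strongly *non*-linear in the open
fraction; it is steepest at low open fractions, which is what makes the
method sensitive in the physiologically relevant few-percent-open regime.

Acquisition defaults follow time-correlated single-photon counting at 20 MHz
pulsing: 400 time bins over 0–12.5 ns, 0.1 µm pixels. The instrument response
is treated as a delta at the window origin and photons arriving after the
gate are discarded; no wrap-around tail from the 50 ns pulse period is
modeled. Pixels with fewer than 25 photons or barycenter lifetime above
2.97 ns are invalid (both boundaries inclusive on the valid side, since the
exclusion rule is stated as strict `<25` / `>2.97`).

## Calibration and inversion

The calibration curve `tau(f)` is fitted to lifetime measurements of
surfaces presenting known open:closed probe ratios with the saturating
double exponential

    tau(f) = c0 + a1 (1 - e^(-f/s1)) + a2 (1 - e^(-f/s2)),

a monotone five-parameter form whose two rise scales capture the steep low-f
rise of the brightness-weighted mixture. The fit must reproduce the endpoint
lifetimes within 1% and be strictly increasing; inversion is numerical on a
dense grid with linear interpolation, out-of-range lifetimes clamp to 0 or 1
and are flagged. Intensity is fitted affine in `f`; its endpoints yield the
quenching efficiency.

In the image pipeline the calibration samples are produced by *rendering*
uniform mixed-fraction surfaces at high photon budget (default 4000
photons/pixel over a 48 × 48 patch) and measuring them with the same pooled
barycenter estimator applied to cell data. This keeps estimator conventions
(binning, gating, peak subtraction) identical between calibration and
measurement, which is what makes sub-0.01 recovery of the open fraction
possible at 500 photons/pixel.

## Relative probe density

On a fluid bilayer, receptor clustering and hairpin opening both raise
intensity; once the open fraction `F` is known from lifetime, the relative
probe density per pixel is

    rho = (I - D) / [ (I0 - D)/(1 - QE) * F + (I0 - D) (1 - F) ]

with `I` the illumination-corrected photon count, `D` dark counts and `I0`
the cell-free bilayer reference. For linear (hairpin-free) probes `F` is
forced to zero. The shot-noise floor of the barycenter is `tau/sqrt(N)` for
an untruncated mono-exponential — a lower-bound heuristic for the gated
multi-exponential case; the empirical spread follows the `N^(-1/2)` law with
log-log slope −0.5 within ±0.02 in the validation runs.

## Podosome morphometrics

Podosome cores are depletion zones: connected pixels below
`0.7 × background` (the threshold fraction is a free parameter; the source
analysis used intensity-based thresholding without stating a value).
Touching cores are split by a marker-based watershed seeded at
distance-transform maxima, with the separating line realized as a
2-pixel-wide barrier. Depletion percent is measured in the centroid dilated
by 2 pixels; core radius is the effective radius `sqrt(area/pi)` of the
segmented core. The ring is the annulus from the core radius out to
`core + 0.5 µm`, capped at 1 µm (ring width is undefined in the source and
exposed as a parameter). Per-cell statistics are unweighted means of
per-podosome means. Clusters are bright components (default > 1.5 ×
background) with no podosome within 1.2 µm; channel means are taken over the
footprint eroded by 2 pixels to avoid diffraction-softened edges. Tracking
is greedy nearest-centroid linking with a gating radius, no gap closing, and
a `split` lineage tag for tracks born next to a live track.

For perturbation responses, per-track radius changes use the nearest frames
before/after the event; outliers beyond median ± 3 median absolute
deviations are excluded per group — the only place the MAD rule is applied,
mirroring where the original analysis used it.

## Force orientation (excitation-resolved polarization)

An open, force-aligned probe carries its cyanine dipole uniformly
distributed on the circle perpendicular to the duplex axis. With a purely
in-plane excitation field at polarization angle `alpha`, the ring-averaged
absorption is

    I(alpha) ∝ (1/2) (1 - sin^2(theta) cos^2(alpha - phi)),

re-derived here both analytically (the dipole-ring covariance is
`(I - n n^T)/2`) and by brute-force Monte-Carlo dipole sampling, which agrees
within 0.5% at every sweep angle. The per-pixel sweep (default 73 frames at
2.5° steps) is fitted closed-form as `C + A cos(2(alpha - phi))` via linear
least squares; `phi` is reported at the intensity **minimum**, mod 180° (the
opposite convention is equally defensible — stated here once and used
everywhere). The modulation ratio `m = A/C` inverts to the tilt from the
substrate normal via `theta = arcsin(sqrt(2m/(1+m)))`.

The excitation field is modeled purely in-plane (epi-illumination); no
large-NA z-field or emission-polarization scrambling corrections are
applied. Consequently the modulation vanishes quadratically as `theta -> 0`
and tilts below ~20° are indistinguishable from vertical at realistic photon
budgets; such pixels carry a `vertical_cone` flag rather than a trusted
angle. Closed probes contribute an unmodulated residual (default 2% of open
brightness, the static-quench mechano-selection residual). Emission
anisotropy uses the standard G-factor correction
`r = (I_par - G I_perp)/(I_par + 2 G I_perp)` with `G` from an isotropic
reference dye.

## Membrane dynamics

Free 2-D diffusion is integrated exactly by Gaussian-kernel composition
(variance `2 D dt` per step, periodic boundaries, mass conserved to machine
precision); kernels narrower than 0.5 px raise a stability error. FRAP
recoveries are fitted with a single exponential
`I_b + A (1 - e^(-k t))` (the recovery order is not specified in the source;
bleach depth and plateau are free) and `t_half = ln 2 / k` feeds
`D = w^2 / (4 t_half)` with `w` the nominal bleach radius. This relation is
an approximation to exact disk-recovery theory; with frame schedules scaled
to the nominal recovery time `w^2/(4D)` — the way an experimenter matches
frame rate to recovery speed — it carries a uniform ~14% systematic
underestimate, documented here and well inside the 25% validation band. The
fitted half-time does depend on how much plateau the schedule records, which
is why the round-trip uses a recovery-scaled schedule rather than a fixed
one.

## Perturbation timelines

The maintained scene pattern (cores, rings, clusters) is treated as a
quasi-steady state actively held by the cell. Photocleavage multiplies
density and open fraction inside the ROI by a residual (default 0); the
resulting density *deviation* then relaxes by free diffusion while the
maintained pattern persists, so the tension channel (density × open
fraction) recovers on the diffusive timescale of the ROI — in the
simulations its recovery half-time tracks the FRAP half-time of the same
region within ~15%. Cleaved podosomes retract: their truth core radius
shrinks by a response factor (default 0.75). Tension-gauge tethers rupture
only when the simulated per-receptor force reaches the tether tolerance
`T_tol`; below tolerance the timeline is unchanged.

## Podosome force model

The net vertical tensile force per podosome integrates per-receptor forces
over the ring:

    F_pod = pi (R^2 - r^2) · (l d) · (rho F_int O)

with defaults `R = 1 µm`, `r = 0.3 µm`, anchor density
`l = leaflet_factor × biotin_mol_fraction / area_per_lipid` (0.1 mol%
biotinylated lipid over a 0.72 nm² DOPC footprint, one accessible leaflet:
`l ≈ 1.39 × 10^3 µm^-2`), `d = 1` probe per biotinylated lipid (band 0.5–2),
ring density `rho = 1`, open fraction `O = 0.1` and per-receptor force
`F_int`. At `F_int = 19 pN` this gives ~7.5 nN per podosome. The
`leaflet_factor` is exposed because the published arithmetic is ambiguous
about one- versus two-leaflet partitioning (0.5 is defensible if the mole
fraction spreads over both leaflets but streptavidin reaches only the
upper). A two-population option replaces `F_int` by a weight-averaged force;
the weights are left to the user because the printed pairing of forces and
open percentages admits two readings.

## What the synthetic validation shows — and does not

The scene generator emulates: Poisson photon statistics per (pixel, time
bin); two-state multi-exponential decays with gating; Gaussian
diffraction blur of intensity fields (default sigma 0.1 µm); podosome
geometry (0.3 µm depleted core, ring to 1 µm, 10% open probes, clusters of
doubled density without tension); polarization sweeps under the dipole-ring
model; lateral diffusion at `D ≈ 1.4 µm² s^-1`; photocleavage and TGT
rupture events. It does **not** emulate: instrument response broadening or
afterpulsing, detector dead time, vectorial/TIRF excitation, camera read
noise or EMCCD gain, bilayer defects, cell-shape heterogeneity, or motion
during the 60 s FLIM accumulation. Passing recovery tests therefore
demonstrates correctness and statistical calibration of the *analysis* under
the stated imaging physics, not robustness to every instrumental artifact of
real data. Problem sizes in the validation runs (320² px tension fields at
500 photons/pixel, 48² calibration patches, 24² polarization fields, 161²
FRAP grids) were chosen so each experiment completes in seconds while
leaving estimator noise well below the tolerance being tested.

## Numerical conventions

- Coordinates are 0-based row-major pixel indices; radii in µm are converted
  through the pixel size.
- All randomness flows from `numpy` `SeedSequence` spawning; every renderer
  is bitwise reproducible under a fixed seed.
- Validity boundaries are inclusive; out-of-range inversions clamp and are
  flagged rather than erroring; degenerate references (`I0 <= D`,
  non-positive backgrounds) raise.
- Per-pixel modulation fits use one shared normal-equation solve per stack;
  amplitudes indistinguishable from zero get a NaN (undefined) phase.
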