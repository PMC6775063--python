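# Methods

This note records the models, conventions and numerical choices behind
`sheetscan`, in the spirit of a methods section: what each component
assumes, which defaults matter and why, and what the synthetic-data tests
do and do not demonstrate about real data.

## Optics

**Gaussian axial PSF.** All axial widths use the Gaussian-beam
convention: a beam whose marginal ray angle is θ = arcsin(NA/n) has
Rayleigh range z_R = λ / (2π n (1 − cos θ)) — the exact-angle form of the
paraxial n λ / (π NA²) — and the on-axis intensity of such a beam falls
to half at one Rayleigh range, so the axial FWHM is 2 z_R =
λ / (π n (1 − cos θ)). The test suite checks this convention against an
independent scalar-diffraction oracle (a Debye integral over a
Gaussian-apodised pupil whose intensity reaches 1/e² at the aperture
edge); the two agree within ~9% at NA 0.5, comfortably inside the ±20%
band we consider meaningful for a Gaussian approximation. The lateral
width uses the common Gaussian fit to the Airy core,
σ_lat = 0.21 λ / NA. Defaults: λ = 0.525 μm (centre of a 500–550 nm
green-emission band), n = 1.333 (water).

**Light-sheet system PSF.** The system axial response is the product of
two Gaussians — the detection axial PSF and the sheet thickness profile
at the illumination waist (waist 1/e² radius w₀ = λ/(π NA_ill), so
intensity σ = w₀/2) — hence 1/σ² adds. For NA_det = 0.5 with
NA_ill = 0.11 this gives a combined axial FWHM of ≈1.24 μm, sharper than
either factor alone.

**Remote-focus aberration model.** For an objective obeying the Abbe
sine condition, imaging a plane displaced by z from the native focal
plane (by refocusing on the low-NA image side) leaves a residual
spherical wavefront: marginal rays cross the axis z (1 − cos θ) away
from the paraxial focus. At best focus the caustic spreads over
±z(1 − cos θ)/2, and we take that half-spread as the geometric axial
spot size, on the same half-width footing as the diffraction FWHM. The
reported spot is max(diffraction FWHM, aberration spread), and the
diffraction-limited defocus range is the |z| at which the two cross,
bisected to 0.1 μm. For the 10×/0.3, 20×/0.5 and 40×/0.8 water-immersion
objectives this yields 381, 47 and 6.3 μm. Magnification enters the
model only through its covariation with NA in commercial objective
families; the model itself depends on NA and n.

**Throughput arithmetic.** Photon-collection ratios use solid angles
2π(1 − cos(arcsin NA)) with n = 1 by default (an `immersion_index`
keyword gives medium-aware angles). The camera-splitting (DPI) tree is
modelled as a balanced binary tree of depth log₂(n_cameras); each photon
traverses one relay/mirror pair per level, so transmission is
(η_relay·η_mirror)^depth while frame rate scales with camera count. The
mirror efficiency defaults to 1.0 and is configurable; which loss
surfaces to count is a system-specific budget. Equal read-noise-limited
SNR between two cameras requires N_b/N_a = (QE_a/QE_b)(σ_b/σ_a); for a
(50%, 23 e⁻) burst camera vs an (82%, 1.4 e⁻) scientific camera that is
≈27× more light.

## Scan control

**Command smoothing.** Triangle commands are low-passed with a 4th-order
Butterworth at 3.25× the cycle frequency, applied forward-and-backward
over three concatenated periods keeping the middle one — zero phase, no
edge transients, strictly periodic output. Filtering erodes the
vertices, so the underlying triangle amplitude is re-expanded and
re-filtered until the output peak-to-peak matches the target within
0.1 μm (typically 2 iterations).

**Range tuning.** The tuning loop commands a range 10% smaller than the
target (overshoot guard), measures one steady-state sensor cycle, and
moves each limit independently by 90% of its error, regenerating the
smoothed command each iteration, until both limits are within 0.1 μm.
On a unity-gain plant the error contracts by exactly 10× per iteration;
on any linear plant with gain in [0.5, 1.5] convergence is monotone
after the first iteration. The default simulated plant converges in 4
iterations for a 700 μm / 20 Hz scan.

**Slice timing.** Plane depths are centred in their spacing bins,
z_min + (k + ½)Δz, so every plane is interior to the tuned range (the
extremes themselves are touched only instantaneously). Crossing times
are linearly interpolated between sensor samples, separately for the
rising and falling sweeps, which must be monotonic; times are reported
in the waveform's own clock over one cycle starting at the sensor
minimum. The frame budget defines idle fraction as
1 − min_interval/uniform_interval. A smoothed command therefore shows a
nonzero idle fraction whose exact value depends on the plant and
smoothing; the interval distribution, not only its minimum, would be
needed to reproduce any particular measured idle figure.

## Timing calibration

"Similarity" is the sum of squared differences normalised by the
reference energy over the overlap — 0 for identical images, lower is
better — so the best offset is the score minimum; ties break toward the
earliest offset. Registration is an exhaustive integer search within the
lateral budget (2 μm by default), optionally refined by a separable
parabolic fit of the score surface; alignment for scoring uses cubic
interpolation. The offset grid is 0–1.2 ms in 50 μs steps (25
candidates). If no offset beats the naive timing by more than a small
tolerance the naive timing is kept.

The simulated calibration scenario gives the plant an
acceleration-proportional focus error (≈2 μm worst case at
700 μm / 20 Hz), an acceleration-proportional lateral wobble (≤1.2 μm),
and a fixed 0.6 ms acquisition-chain latency so that the correct offsets
are positive and interior to the one-sided grid. Under those conditions
calibration recovers every slice's injected offset within one grid step
and the corrected dynamic images match the static ground truth at
normalised SSD ≤ 0.02.

## Dual-camera stitching

The reflected frame is mirrored about its row axis in software before
any transform. The session transform is estimated from three bead-field
views: rigid between the reflected camera's knife-edge (small) and
beamsplitter (full) views — near identity by construction — then affine
from the reflected camera into the unreflected camera's frame, composed
rigid-first-affine-second. With the beamsplitter in place both cameras
see the whole field, so the unreflected reference is full-field and the
affine is constrained by beads everywhere rather than in one half only.
Bead centres come from 2-D Gaussian fits (free offset); the affine is
fit by RANSAC with a least-squares refit on the inliers, because beads
inside the knife-edge intensity ramp are partially vignetted and their
centroids biased by several tenths of a pixel — outliers that trimmed
least squares handles poorly. An affine scale more than 1% from identity
triggers a warning.

Stitching flips, bias-subtracts, warps (quintic spline) and **adds** the
two frames: the mirror apex divides the light between the cameras with
complementary ramps, so summation conserves intensity across the seam.
(An intensity-weighted average would darken the strip.) The simulator's
ramp runs between 0.75 and 0.25 of full intensity rather than to zero,
reflecting the defocused mirror edge spreading light so that beads in
the redundant strip are visible on both cameras. On simulated pairs with
small random misalignments (≤0.3° rotation, ≤0.5% anisotropic scale,
≤2 px translation) the estimated transform matches the injected one
within 0.05 px RMS and reconstruction is within 1% of dynamic range off
the seam. Warp fidelity is only defined for adequately sampled images;
the round-trip fixtures use band-limited bead fields (σ ≈ 2 px).

## Image analysis

**Destriping** log-transforms the slice (stripes are multiplicative),
attenuates an angular wedge (±2° by default) perpendicular to the stripe
orientation beyond 4 cycles/image, and exponentiates back. Removing a
zero-mean multiplicative sinusoid biases the log-domain mean by −d²/4,
so the output is rescaled to the input's mean intensity. Defaults
(attenuation 0.1, wedge ±2°, radial floor 4) are configurable.

**Stack registration** is an exhaustive integer search over the shift
window scoring overlap-normalised cross-correlation; on small stacks it
is therefore its own oracle, and a peak correlation below 0.2 flags a
low-confidence (noise-dominated) result.

**PSF estimation.** Beads are local maxima above median + 5 robust σ;
each ROI (9 px lateral, a few expected widths axial) gets an axial
Gaussian fit with free centre (sub-voxel) and offset. Fits wider than 5×
the diffraction limit are flagged as clusters and excluded. Only
isolated, interior beads are used downstream: any detected peak inside a
bead's resampling window (≈±4.5 μm axial, ±2 μm lateral) disqualifies
it, since a neighbour would contaminate both its fitted width and the
averaged profile. The waist is the minimum of the 10 μm sliding median
of fitted widths along the propagation axis, located by fitting a
parabola to the median curve — the curve is shallow near the waist, so
the raw argmin jitters with per-bead noise while the vertex is stable.
The 20 isolated beads nearest the waist are aligned on their fitted
centres, resampled trilinearly at 0.1 μm isotropic spacing, and
averaged; the reported axial FWHM comes from a Gaussian fit of the
averaged profile. On seeded phantoms the waist is localised within 2 μm
and, for a uniform width profile, the averaged FWHM matches the
generator within 5%.

## Trace analysis

ΔF/F uses a centred 60 s moving-average baseline; the first and last
30 s, where the window is undefined, are dropped. Welch spectra use a
rectangular window, 2048-sample segments and 50% overlap by default,
with no detrending (inputs are baseline-subtracted), so Parseval's
relation holds. Heartbeat detection scores every candidate fundamental
in the search band by the summed prominence of the median-across-neurons
PSD at the candidate and its harmonics (3 by default, below Nyquist) and
requires the winner to clear the local noise floor by 4 robust σ —
otherwise an empty model is returned and scrubbing is a no-op. Stopbands
are ±0.25 Hz around each harmonic; scrubbing applies an order-5
Butterworth bandstop per band, forward and backward (zero phase).
Correlation deltas are Pearson correlations of 1 Hz-highpassed traces
before and after scrubbing. ROI traces are sums (not means) of voxel
intensities, which matters for noise scaling.

## Synthetic data

The simulators define the conditions under which everything above is
tested. The piezo plant is a linear second-order system (ωₙ = 150 Hz,
ζ = 0.7, unity DC gain) computed in periodic steady state — exactly the
post-initialisation limit, so cycles repeat to machine precision; creep
and hysteresis are not modelled because closed-loop operation is the
intended regime. Underdamped variants (ζ ≈ 0.25) reproduce the ringing
that raw triangle commands excite in an unoptimised system. The focal
plane differs from the sensor by k_a × acceleration with
k_a = 2.3×10⁻⁷ μm/(μm s⁻²), scaled to ≈2 μm worst case at
700 μm / 20 Hz.

Bead phantoms place ~4 beads per 1000 μm³ in a (24, 120, 24) μm volume
with an axial width profile σ(y) = σ₀√(1 + ((y−y*)/R)²), σ₀ = 1.26 μm
(the combined 10×/0.3 detection × 5.3 μm sheet waist) and R = 30 μm (the
effective width-growth length of a focused sheet tempered by the
constant detection width); beads are bright (5000 photons at the centre)
as calibration preparations are, with Poisson shot noise and 2 e⁻ read
noise. Heartbeat traces are Poisson events convolved with a
difference-of-exponentials indicator kernel (50 ms rise, 400 ms decay),
plus a shared periodic artifact (2.5 Hz fundamental, harmonic amplitudes
1 : 0.45 : 0.3) coupled per neuron with a random sign; the coupling
magnitude is solved so the artifact-induced pairwise correlation —
measured, as in the analysis pipeline, on 1 Hz-highpassed traces — is
≈0.1. Defaults: 24 neurons, 20 Hz, 20 min (24,000 samples).

What passing these tests shows: the algorithms recover known ground
truth under realistic noise, rates and magnitudes. What they do not
show: robustness to specimen motion beyond rigid drift, non-Gaussian or
spatially structured noise, scattering-induced stripe dynamics, heart-
rate drift within a recording (the bandstop is static; regression on
motion vectors would be the robust alternative), or plant
nonlinearities.

## Interfaces

Stacks travel as multi-page TIFF with a JSON sidecar or HDF5 with
attributes; axis order is normalised to (t, z, y, x). Waveforms and
slice plans are CSV with units in the headers; configuration is YAML.
The CLI is a thin veneer over the library and adds no behaviour.
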