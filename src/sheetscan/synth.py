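"""Simulators that give every analysis module a ground truth.

Desk-scale stand-ins for the hardware and specimens the toolkit operates
on: a second-order piezo plant whose *focal* position differs from its
*sensor* reading by an acceleration-proportional error, a rolling-shutter
camera with pulsed illumination imaging a 3-D bead phantom, a two-camera
split-image pair related by a known transform, multiplicative stripe
fields, and neuron calcium traces contaminated by a shared periodic
heartbeat artifact with harmonics.  Every generator is deterministic under
a fixed seed and returns its ground truth alongside the observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .scan import PulseSchedule, SlicePlan, Waveform
from .traces import TraceMatrix

__all__ = [
    "PlantModel",
    "PhantomSpec",
    "ArtifactTraceSpec",
    "BeadPhantom",
    "simulate_piezo",
    "simulate_camera",
    "make_bead_phantom",
    "make_split_pair",
    "make_dpi_calibration_set",
    "make_heartbeat_traces",
    "make_striped_image",
]


# --------------------------------------------------------------------------
# piezo plant
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantModel:
    """Linear second-order model of a closed-loop piezo positioner.

    The closed loop behaves like a damped harmonic oscillator with
    transfer function ``H(s) = g * wn^2 / (s^2 + 2*zeta*wn*s + wn^2)``.
    The built-in sensor reports the mechanical response delayed by
    ``sensor_lag``; the *optical* focal plane additionally differs from
    the response by an acceleration-proportional error with coefficient
    ``accel_coupling`` (um per um/s^2), emulating dynamic forces flexing
    the scan assembly.  The default coupling produces a worst-case
    sensor-vs-focus error of roughly 2 um when scanning 700 um at 20 Hz.
    """

    natural_frequency: float = 150.0  # Hz
    damping_ratio: float = 0.7
    dc_gain: float = 1.0
    sensor_lag: float = 0.0  # s
    accel_coupling: float = 2.3e-7  # um per (um/s^2): ~2 um worst case at 20 Hz/700 um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if not 0.0 < self.damping_ratio < 2.0:
            raise ValueError("damping_ratio must be in (0, 2)")
        if self.dc_gain <= 0:
            raise ValueError("dc_gain must be positive")

    def check_stable_for(self, cycle_frequency: float) -> None:
        if self.natural_frequency <= 5.0 * cycle_frequency:
            raise ValueError(
                "plant natural frequency must exceed 5x the commanded cycle "
                f"frequency ({cycle_frequency} Hz) for stable tests"
            )


def simulate_piezo(
    plant: PlantModel, command: Waveform, n_init_cycles: int = 5
) -> tuple[Waveform, Waveform]:
    """Periodic steady-state response of the plant to a cyclic command.

    Returns ``(sensor, focal)`` waveforms covering the same samples as the
    command.  The response is computed per frequency bin of one command
    period, which is exactly the limit reached after the initialisation
    transient has decayed (``n_init_cycles`` documents the discarded
    cycles; the transient of a damped second-order system at the default
    parameters is below machine precision after a handful of cycles, so
    post-transient cycles are identical by construction).
    """
    plant.check_stable_for(1.0 / command.period)
    period = command.one_period()
    n = period.size
    freqs = np.fft.rfftfreq(n, d=1.0 / command.sample_rate)
    w = 2.0 * np.pi * freqs
    wn = 2.0 * np.pi * plant.natural_frequency
    s = 1j * w
    h = plant.dc_gain * wn**2 / (s**2 + 2.0 * plant.damping_ratio * wn * s + wn**2)
    u = np.fft.rfft(period)
    resp_f = h * u
    response = np.fft.irfft(resp_f, n)
    sensor = np.fft.irfft(resp_f * np.exp(-s * plant.sensor_lag), n)
    accel = np.fft.irfft(resp_f * (s**2), n)
    focal = response + plant.accel_coupling * accel
    if not (np.all(np.isfinite(response)) and np.ptp(response) < 10 * np.ptp(period)):
        raise RuntimeError("plant response unstable")
    n_rep = command.samples.size // n
    mk = lambda x: Waveform(np.tile(x, n_rep), command.sample_rate, n)
    return mk(sensor), mk(focal)


# --------------------------------------------------------------------------
# bead phantom and rolling-shutter camera
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """3-D fluorescent bead phantom description.

    ``shape_um`` is the (z, y, x) extent.  The axial Gaussian width of a
    bead image depends on its position ``y`` along the sheet propagation
    axis: ``sigma(y) = sigma_waist * sqrt(1 + ((y - waist_y)/rayleigh_y)^2)``,
    with a unique minimum at the sheet waist.  Intensities carry Poisson
    shot noise plus Gaussian read noise.
    """

    shape_um: tuple = (24.0, 120.0, 24.0)
    bead_density_per_1000um3: float = 4.0
    # combined detection x sheet axial sigma at the waist for the 10x/NA 0.3
    # objective with a 5.3 um-waist sheet (1/e^2 radius 2.65 um)
    sigma_waist: float = 1.26  # um
    waist_y: float = 60.0  # um along propagation axis
    # effective width-growth length of the combined detection x sheet
    # profile (the sheet's own Rayleigh range, tempered by the constant
    # detection width)
    rayleigh_y: float = 30.0  # um
    sigma_lateral: float = 0.3  # um
    amplitude: float = 5000.0  # photons at bead centre (bright calibration beads)
    background: float = 20.0  # photons per voxel
    read_noise: float = 2.0  # rms counts
    fused_fraction: float = 0.0  # fraction of beads doubled into close pairs
    seed: int = 0

    def __post_init__(self) -> None:
        n_beads = self.bead_density_per_1000um3 * np.prod(self.shape_um) / 1000.0
        if n_beads < 30:
            raise ValueError("spec yields fewer than 30 beads; raise the density")


class BeadPhantom:
    """Continuous bead field rendered on demand.

    ``positions`` are (z, y, x) bead centres in um; intensity at a point is
    a sum of anisotropic Gaussians with the position-dependent axial width
    from the spec.
    """

    def __init__(self, spec: PhantomSpec, positions: np.ndarray, fused_mask: np.ndarray):
        self.spec = spec
        self.positions = positions
        self.fused_mask = fused_mask

    def sigma_axial(self, y: np.ndarray) -> np.ndarray:
        s = self.spec
        return s.sigma_waist * np.sqrt(1.0 + ((y - s.waist_y) / s.rayleigh_y) ** 2)

    def render_volume(
        self, voxel_size: tuple, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Sample the phantom on a (z, y, x) voxel grid, with noise if ``rng``."""
        dz, dy, dx = voxel_size
        nz = int(round(self.spec.shape_um[0] / dz))
        ny = int(round(self.spec.shape_um[1] / dy))
        nx = int(round(self.spec.shape_um[2] / dx))
        vol = np.full((nz, ny, nx), float(self.spec.background))
        zg = (np.arange(nz) + 0.5) * dz
        yg = (np.arange(ny) + 0.5) * dy
        xg = (np.arange(nx) + 0.5) * dx
        for (bz, by, bx) in self.positions:
            sz = float(self.sigma_axial(np.array(by)))
            sl = self.spec.sigma_lateral
            iz = np.flatnonzero(np.abs(zg - bz) < 5 * sz)
            iy = np.flatnonzero(np.abs(yg - by) < 6 * sl)
            ix = np.flatnonzero(np.abs(xg - bx) < 6 * sl)
            if not (iz.size and iy.size and ix.size):
                continue
            gz = np.exp(-0.5 * ((zg[iz] - bz) / sz) ** 2)
            gy = np.exp(-0.5 * ((yg[iy] - by) / sl) ** 2)
            gx = np.exp(-0.5 * ((xg[ix] - bx) / sl) ** 2)
            vol[np.ix_(iz, iy, ix)] += self.spec.amplitude * (
                gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            )
        if rng is not None:
            vol = rng.poisson(vol).astype(float) + rng.normal(
                0.0, self.spec.read_noise, vol.shape
            )
        return vol

    def section(
        self,
        z: float,
        pixel_size: float,
        shape_px: tuple,
        lateral_shift_um: tuple = (0.0, 0.0),
    ) -> np.ndarray:
        """Noise-free optical section at focal depth ``z`` (y, x image)."""
        ny, nx = shape_px
        yg = (np.arange(ny) + 0.5) * pixel_size + lateral_shift_um[0]
        xg = (np.arange(nx) + 0.5) * pixel_size + lateral_shift_um[1]
        img = np.full((ny, nx), float(self.spec.background))
        for (bz, by, bx) in self.positions:
            sz = float(self.sigma_axial(np.array(by)))
            az = math.exp(-0.5 * ((z - bz) / sz) ** 2)
            if az < 1e-4:
                continue
            sl = self.spec.sigma_lateral
            iy = np.flatnonzero(np.abs(yg - by) < 6 * sl)
            ix = np.flatnonzero(np.abs(xg - bx) < 6 * sl)
            if not (iy.size and ix.size):
                continue
            gy = np.exp(-0.5 * ((yg[iy] - by) / sl) ** 2)
            gx = np.exp(-0.5 * ((xg[ix] - bx) / sl) ** 2)
            img[np.ix_(iy, ix)] += self.spec.amplitude * az * np.outer(gy, gx)
        return img


def make_bead_phantom(spec: PhantomSpec) -> BeadPhantom:
    """Draw bead positions for ``spec`` (deterministic under its seed)."""
    rng = np.random.default_rng(spec.seed)
    volume = float(np.prod(spec.shape_um))
    n = rng.poisson(spec.bead_density_per_1000um3 * volume / 1000.0)
    n = max(n, 30)
    lo = np.array([2.0, 2.0, 2.0])
    hi = np.array(spec.shape_um) - 2.0
    pos = lo + rng.random((n, 3)) * (hi - lo)
    fused = np.zeros(n, dtype=bool)
    if spec.fused_fraction > 0:
        n_fuse = int(round(spec.fused_fraction * n))
        idx = rng.choice(n, size=n_fuse, replace=False)
        partners = pos[idx] + rng.normal(0.0, 0.4, (n_fuse, 3)) + np.array([2.5, 0, 0])
        pos = np.vstack([pos, partners])
        fused = np.concatenate([fused, np.ones(n_fuse, dtype=bool)])
        fused[idx] = True
    return BeadPhantom(spec, pos, fused)


@dataclass(frozen=True)
class RollingShutterResult:
    """Output of the rolling-shutter camera model."""

    image: np.ndarray
    row_planes: np.ndarray  # focal position sampled by each row, um
    plane_spread: float  # max - min of row_planes, um
    flagged_rows: np.ndarray  # rows whose illumination fell outside their window


def simulate_camera(
    phantom: BeadPhantom,
    focal: Waveform,
    exposure_start: float,
    pulses: PulseSchedule | None,
    shape_px: tuple,
    pixel_size: float,
    line_time: float = 9.76e-6,
    bias: float = 100.0,
    rng: np.random.Generator | None = None,
) -> RollingShutterResult:
    """Expose one rolling-shutter frame while the focus moves.

    Rows start exposing at ``exposure_start + row * line_time`` and expose
    for the schedule's exposure time.  With a pulse inside the global
    window every row samples the focal position at the pulse centre
    (plane spread zero); with continuous illumination (``pulses=None``)
    each row samples the focal position at the midpoint of its own
    exposure window, reproducing the multi-plane contamination that
    pulsing prevents.
    """
    ny, nx = shape_px
    t = focal.times
    pos = focal.samples
    interp = lambda tt: np.interp(tt % focal.period, t[: focal.period_samples], pos[: focal.period_samples])
    rows = np.arange(ny)
    starts = exposure_start + rows * line_time
    if pulses is not None:
        exposure = pulses.exposure_time
        pulse_t0 = exposure_start + pulses.pulse_offset_in_exposure
        pulse_mid = pulse_t0 + 0.5 * pulses.pulse_duration
        # rows are globally exposed when the pulse lies inside their window
        ok = (starts <= pulse_t0 + 1e-15) & (
            starts + exposure >= pulse_t0 + pulses.pulse_duration - 1e-15
        )
        row_times = np.where(ok, pulse_mid, np.clip(pulse_mid, starts, starts + exposure))
        flagged = rows[~ok]
    else:
        exposure = ny * line_time  # effective: sample mid-window per row
        row_times = starts + 0.5 * exposure
        flagged = np.array([], dtype=int)
    row_planes = interp(row_times)
    if np.allclose(row_planes, row_planes[0]):
        image = phantom.section(float(row_planes[0]), pixel_size, shape_px)
    else:
        image = np.empty(shape_px)
        # render per group of rows sharing (nearly) one plane
        for r in rows:
            image[r] = phantom.section(float(row_planes[r]), pixel_size, (1, nx))[0]
    image = image + bias
    if rng is not None:
        image = rng.poisson(np.clip(image, 0, None)).astype(float) + rng.normal(
            0.0, phantom.spec.read_noise, image.shape
        )
    return RollingShutterResult(
        image=image,
        row_planes=row_planes,
        plane_spread=float(np.ptp(row_planes)),
        flagged_rows=flagged,
    )


# --------------------------------------------------------------------------
# timing-calibration scenario
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationScenario:
    """Everything the image-guided timing calibration needs, plus truth.

    ``ground_truth`` is the quasi-static reference stack (one image per
    plane), ``acquire(slice, direction, offset)`` emulates a dynamic
    acquisition at a timing offset from the naive sensor-based time, and
    ``true_offsets`` maps ``(slice_index, direction)`` to the offset that
    places the focus exactly in the intended plane.
    """

    ground_truth: np.ndarray
    acquire: object
    true_offsets: dict
    true_shifts_um: dict
    plan: SlicePlan
    pixel_size: float


def make_calibration_scenario(
    plant: PlantModel,
    spec,
    phantom: BeadPhantom | None = None,
    shape_px: tuple = (48, 48),
    pixel_size: float = 0.65,
    trigger_latency: float = 6.0e-4,
    lateral_coupling: tuple = (5.0e-7, 2.5e-7),
    noise_rng: np.random.Generator | None = None,
) -> CalibrationScenario:
    """Build a simulated acquisition for exercising timing calibration.

    The plant is range-tuned and run at the requested scan; naive slice
    times come from its *sensor* waveform while images are formed at the
    *focal* position, which leads/lags the sensor by the acceleration-
    coupled error.  The acquisition chain additionally fires
    ``trigger_latency`` seconds early (emulating the unexplained timing
    error that motivates image-guided calibration), so the correct
    offsets are positive and sit inside the default 0-1.2 ms grid.
    Dynamic frames are also shifted laterally in proportion to the
    instantaneous acceleration (``lateral_coupling`` um per um/s^2 in y
    and x), bounded well under 2 um at the default scan.
    """
    from .scan import slice_times_from_sensor, tune_range

    if phantom is None:
        phantom = make_bead_phantom(
            PhantomSpec(
                shape_um=(
                    spec.z_max - spec.z_min + 8.0,
                    shape_px[0] * pixel_size,
                    shape_px[1] * pixel_size,
                ),
                bead_density_per_1000um3=2.0,
                sigma_lateral=0.6,  # realistic lateral blur; well sampled at 0.65 um px
                seed=plant.seed,
            )
        )
    tuned = tune_range(lambda c: simulate_piezo(plant, c)[0], spec)
    sensor, focal = simulate_piezo(plant, tuned.command)
    plan = slice_times_from_sensor(sensor, spec)
    focal_plan = slice_times_from_sensor(focal, spec)

    period = sensor.period
    p = sensor.period_samples
    t_grid = np.arange(p) / sensor.sample_rate
    focal_cycle = focal.one_period()
    # acceleration of the mechanical response, for the lateral wobble
    freqs = np.fft.rfftfreq(p, d=1.0 / sensor.sample_rate)
    accel_cycle = np.fft.irfft(
        np.fft.rfft(focal_cycle) * (2j * np.pi * freqs) ** 2, p
    )

    def z_at(t: float) -> float:
        return float(np.interp(t % period, t_grid, focal_cycle, period=period))

    def accel_at(t: float) -> float:
        return float(np.interp(t % period, t_grid, accel_cycle, period=period))

    naive, true_offsets, true_shifts = {}, {}, {}
    for _, row in plan.records.iterrows():
        key = (int(row["slice_index"]), row["direction"])
        naive[key] = float(row["crossing_time_s"])
    for _, row in focal_plan.records.iterrows():
        key = (int(row["slice_index"]), row["direction"])
        t_true = float(row["crossing_time_s"])
        # exposure happens at (naive + offset - latency); it lands on the
        # true focal crossing when offset = latency + (t_true - t_naive)
        true_offsets[key] = trigger_latency + (t_true - naive[key])
        a = accel_at(t_true)
        true_shifts[key] = (lateral_coupling[0] * a, lateral_coupling[1] * a)

    planes = plan.planes
    ground_truth = np.stack(
        [phantom.section(z, pixel_size, shape_px) for z in planes]
    )

    def acquire(slice_index: int, direction: str, offset: float) -> np.ndarray:
        t = naive[(slice_index, direction)] + offset - trigger_latency
        a = accel_at(t)
        shift = (lateral_coupling[0] * a, lateral_coupling[1] * a)
        img = phantom.section(z_at(t), pixel_size, shape_px, lateral_shift_um=shift)
        if noise_rng is not None:
            img = noise_rng.poisson(np.clip(img, 0, None)).astype(float)
        return img

    return CalibrationScenario(
        ground_truth=ground_truth,
        acquire=acquire,
        true_offsets=true_offsets,
        true_shifts_um=true_shifts,
        plan=plan,
        pixel_size=pixel_size,
    )


# --------------------------------------------------------------------------
# split-camera (DPI) pairs
# --------------------------------------------------------------------------


def _observe_reflected(field: np.ndarray, transform) -> np.ndarray:
    """Record ``field`` (common-frame intensities) on the reflected camera.

    ``transform`` is the *forward* map from flipped-reflected-camera pixel
    coordinates to the common frame, so the camera frame (before the
    mirror flip) is the field pulled back through it, and the physical
    mirror flip is applied last.
    """
    if transform is not None:
        field = sktransform.warp(
            field, transform, order=5, mode="constant", cval=0.0, preserve_range=True
        )
    return np.flipud(field)


def split_weights(height: int, overlap_rows: int) -> tuple[np.ndarray, np.ndarray]:
    """Complementary per-row intensity weights of the two cameras.

    The knife edge sits at the mid-row; the reflected camera sees the top
    half at full intensity, the unreflected camera the bottom half, and a
    shared strip of ``overlap_rows`` rows just above the edge carries
    complementary linear ramps summing to unity (light divided at the
    mirror apex conserves the original).  Because the slightly defocused
    mirror edge spreads light, both cameras receive an appreciable
    fraction throughout the strip — the ramps run between 0.75 and 0.25
    rather than to zero, matching the observation that beads in the
    redundant region are visible on *both* cameras.
    """
    half = height // 2
    if overlap_rows < 0 or overlap_rows > half:
        raise ValueError("overlap cannot exceed half the image height")
    w_refl = np.zeros(height)
    w_refl[: half - overlap_rows] = 1.0
    if overlap_rows:
        ramp = 0.75 - 0.5 * (np.arange(overlap_rows) + 0.5) / overlap_rows
        w_refl[half - overlap_rows : half] = ramp
    return w_refl, 1.0 - w_refl


def make_split_pair(
    truth: np.ndarray,
    transform=None,
    overlap_rows: int = 0,
    bias: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Split ``truth`` into an unreflected/reflected camera pair.

    Both camera frames share the truth's canvas size.  The unreflected
    camera records the bottom half (plus its share of the overlap ramp)
    in place; the reflected camera records the top half mirrored about
    the row axis and, if ``transform`` (a skimage ``GeometryTransform``
    mapping flipped-reflected pixel coordinates to the common frame) is
    given, misaligned by its inverse.  Camera bias and Gaussian noise are
    added last.  Returns a dict with the observed frames, the
    ground-truth transform and the split geometry.
    """
    truth = np.asarray(truth, dtype=float)
    h, _ = truth.shape
    rng = np.random.default_rng(seed)
    w_refl, w_unrefl = split_weights(h, overlap_rows)

    unreflected = truth * w_unrefl[:, None]
    reflected = _observe_reflected(truth * w_refl[:, None], transform)

    def finish(img):
        img = img + bias
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        return img

    return {
        "unreflected": finish(unreflected),
        "reflected": finish(reflected),
        "transform": transform,
        "overlap_rows": overlap_rows,
        "bias": bias,
        "split_row": h // 2,
        "truth": truth,
    }


def make_dpi_calibration_set(
    truth: np.ndarray,
    transform=None,
    overlap_rows: int = 0,
    bias: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Bead-field calibration triplet for estimating the stitch transform.

    Emulates the alignment session: with the knife-edge mirror in place
    the reflected camera records its *small* half image; with the mirror
    swapped for a 50/50 beamsplitter both cameras see the whole field,
    and the reflected camera's *full* view plus the unreflected camera's
    full-field *reference* view are recorded.  All three views share one
    stationary bead field, so the cross-camera transform is constrained
    by beads everywhere in the frame rather than in one half only.
    """
    pair = make_split_pair(truth, transform, overlap_rows, bias, noise_sigma, seed)
    rng = np.random.default_rng(seed + 1)

    def snapshot(img):
        img = img + bias
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        return img

    full_reflected = snapshot(_observe_reflected(np.asarray(truth, dtype=float), transform))
    reference_unreflected = snapshot(np.asarray(truth, dtype=float))
    return {
        "small_reflected": pair["reflected"],
        "full_reflected": full_reflected,
        "reference_unreflected": reference_unreflected,
        "transform": transform,
        "pair": pair,
    }


# --------------------------------------------------------------------------
# heartbeat-contaminated calcium traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactTraceSpec:
    """Synthetic calcium-trace recording with a shared periodic artifact.

    Clean activity is a Poisson event train convolved with a
    difference-of-exponentials indicator kernel (50 ms rise, 400 ms decay,
    GCaMP6f-like).  The artifact is a periodic waveform at ``fundamental``
    Hz with the given relative ``harmonic_amplitudes``, coupled into each
    neuron with a random signed coefficient scaled so the worst-case
    spurious pairwise correlation is approximately
    ``target_spurious_corr``.
    """

    n_neurons: int = 24
    fs: float = 20.0  # Hz
    duration: float = 1200.0  # s
    event_rate: float = 0.25  # Hz
    rise_time: float = 0.05  # s
    decay_time: float = 0.4  # s
    event_amplitude: float = 1.0
    fundamental: float = 2.5  # Hz
    harmonic_amplitudes: tuple = (1.0, 0.45, 0.3)
    target_spurious_corr: float = 0.1
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.decay_time <= self.rise_time:
            raise ValueError("kernel times must satisfy 0 < rise < decay")
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")


def _indicator_kernel(spec: ArtifactTraceSpec) -> np.ndarray:
    t = np.arange(0.0, 5.0 * spec.decay_time, 1.0 / spec.fs)
    k = np.exp(-t / spec.decay_time) - np.exp(-t / spec.rise_time)
    return k / k.max()


def make_heartbeat_traces(
    spec: ArtifactTraceSpec,
) -> tuple[TraceMatrix, TraceMatrix, TraceMatrix]:
    """Generate ``(observed, clean, artifact)`` trace matrices.

    ``observed = clean + artifact + white noise``; the clean and artifact
    components are returned separately for ground-truth tests.  Coupling
    coefficients are solved from the target spurious correlation *as it
    is measured*: pairwise correlations of heartbeat-contaminated traces
    are computed on 1 Hz-highpassed signals, so the calibration uses the
    highpassed variances of the background (clean + noise) and of the
    artifact waveform: ``corr = c^2 var_hp(w) / (var_hp(bg) + c^2
    var_hp(w))``, solved for ``c``.
    """
    from scipy import signal as _signal

    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration * spec.fs))
    t = np.arange(n_t) / spec.fs

    kernel = _indicator_kernel(spec)
    events = rng.random((spec.n_neurons, n_t)) < spec.event_rate / spec.fs
    amps = events * rng.exponential(spec.event_amplitude, (spec.n_neurons, n_t))
    clean = np.apply_along_axis(
        lambda row: np.convolve(row, kernel)[:n_t], 1, amps
    )

    waveform = np.zeros(n_t)
    phases = rng.uniform(0, 2 * np.pi, len(spec.harmonic_amplitudes))
    for k, (amp, ph) in enumerate(zip(spec.harmonic_amplitudes, phases), start=1):
        f = k * spec.fundamental
        if f >= spec.fs / 2:
            break
        waveform += amp * np.sin(2 * np.pi * f * t + ph)

    signs = rng.choice([-1.0, 1.0], spec.n_neurons)
    noise = rng.normal(0.0, spec.noise_sigma, (spec.n_neurons, n_t))
    var_wave = float(np.var(waveform))
    if var_wave > 0 and spec.target_spurious_corr > 0:
        hp_cut = min(1.0, 0.4 * spec.fs / 2)
        sos = _signal.butter(5, hp_cut / (spec.fs / 2), btype="highpass", output="sos")
        bg_hp = _signal.sosfiltfilt(sos, clean + noise, axis=-1)
        wave_hp = _signal.sosfiltfilt(sos, waveform)
        v_bg = float(bg_hp.var(axis=1).mean())
        v_w = float(np.var(wave_hp))
        target = spec.target_spurious_corr
        c0 = math.sqrt(target * v_bg / ((1.0 - target) * v_w))
    else:
        c0 = 0.0
    coupling = signs * c0
    artifact = coupling[:, None] * waveform[None, :]
    observed = clean + artifact + noise

    mk = lambda v, kind: TraceMatrix(values=v, fs=spec.fs, kind=kind)
    return (
        mk(observed, "raw_F"),
        mk(clean, "raw_F"),
        mk(artifact, "raw_F"),
    )


# --------------------------------------------------------------------------
# stripes
# --------------------------------------------------------------------------


def make_striped_image(
    base: np.ndarray, angle: float, period: float, depth: float
) -> np.ndarray:
    """Multiply ``base`` by a sinusoidal stripe pattern.

    ``angle`` is the orientation of the stripe *lines* in degrees CCW
    from the x (column) axis; intensity varies perpendicular to them with
    the given ``period`` in pixels.  ``depth`` in [0, 1) is the
    modulation depth: ``out = base * (1 + depth * pattern)``.
    """
    if not 0.0 <= depth < 1.0:
        raise ValueError("depth must be in [0, 1)")
    base = np.asarray(base, dtype=float)
    h, w = base.shape
    yy, xx = np.mgrid[0:h, 0:w]
    phi = math.radians(angle + 90.0)  # variation direction, perpendicular to lines
    u = xx * math.cos(phi) + yy * math.sin(phi)
    pattern = np.sin(2.0 * np.pi * u / period)
    return base * (1.0 + depth * pattern)
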