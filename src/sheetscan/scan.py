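"""Piezo scan command generation, range tuning, slice timing and frame budgets.

A volume is scanned by translating the imaging optics with a piezo
positioner driven by a periodic command.  Raw triangle waves contain
accelerations at their vertices that a closed-loop (PID) piezo cannot
follow, so commands are low-pass filtered and the lost peak-to-peak range
is restored iteratively.  The commanded range is then tuned against the
positioner's own sensor, slice acquisition times are read off the measured
sensor waveform by interpolation, and simple arithmetic summarises how well
the camera's frame budget is used.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ScanSpec",
    "Waveform",
    "SlicePlan",
    "PulseSchedule",
    "SmoothResult",
    "TuneResult",
    "FrameBudget",
    "make_triangle",
    "smooth_command",
    "tune_range",
    "slice_times_from_sensor",
    "interpolate_stack_pairs",
    "plan_pulses",
    "frame_budget",
]


@dataclass(frozen=True)
class ScanSpec:
    """Scan geometry and rates.

    ``z_min``/``z_max`` are the target sensor-measured extremes in um,
    ``cycle_frequency`` the triangle repetition rate in Hz, ``sample_rate``
    the waveform sampling rate in samples/s and ``slice_spacing`` the axial
    distance between acquired planes in um.
    """

    z_min: float
    z_max: float
    cycle_frequency: float
    sample_rate: float
    slice_spacing: float

    def __post_init__(self) -> None:
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")
        if self.cycle_frequency <= 0:
            raise ValueError("cycle_frequency must be positive")
        if self.sample_rate < 100 * self.cycle_frequency:
            raise ValueError("sample_rate must be >= 100x cycle_frequency")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        n = self.scan_range / self.slice_spacing
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("scan range must be an integer number of slice spacings")
        p = self.sample_rate / self.cycle_frequency
        if abs(p - round(p)) > 1e-9:
            raise ValueError("sample_rate must be an integer multiple of cycle_frequency")

    @property
    def scan_range(self) -> float:
        return self.z_max - self.z_min

    @property
    def n_planes(self) -> int:
        """Number of slice planes per sweep."""
        return int(round(self.scan_range / self.slice_spacing))

    @property
    def period_samples(self) -> int:
        return int(round(self.sample_rate / self.cycle_frequency))


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled position-versus-time signal (um vs s)."""

    samples: np.ndarray
    sample_rate: float
    period_samples: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite values")
        if self.period_samples <= 0 or samples.size % self.period_samples:
            raise ValueError("period must divide the waveform length")
        if np.ptp(samples) <= 0:
            raise ValueError("waveform peak-to-peak must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def period(self) -> float:
        """Cycle duration in seconds."""
        return self.period_samples / self.sample_rate

    @property
    def peak_to_peak(self) -> float:
        return float(np.ptp(self.samples))

    def one_period(self) -> np.ndarray:
        return self.samples[: self.period_samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "position_um": self.samples})


class SlicePlan:
    """Per-slice acquisition records for one scan cycle.

    Wraps a DataFrame with columns ``slice_index``, ``plane_depth_um``,
    ``direction`` (``forward``/``reverse``), ``crossing_time_s``,
    ``timing_offset_s`` and ``shift_x_um``/``shift_y_um``.  Within each
    direction crossing times are strictly increasing and every plane
    appears exactly once.
    """

    COLUMNS = (
        "slice_index",
        "plane_depth_um",
        "direction",
        "crossing_time_s",
        "timing_offset_s",
        "shift_x_um",
        "shift_y_um",
    )

    def __init__(self, records: pd.DataFrame, cycle_period: float):
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"slice plan missing columns: {sorted(missing)}")
        self.records = records.reset_index(drop=True)
        self.cycle_period = float(cycle_period)
        for direction in ("forward", "reverse"):
            sub = self.direction(direction)
            times = sub["crossing_time_s"].to_numpy()
            if times.size and not np.all(np.diff(times) > 0):
                raise ValueError(f"{direction} crossing times not strictly increasing")
            if sub["plane_depth_um"].duplicated().any():
                raise ValueError(f"duplicate plane in {direction} sweep")

    def direction(self, direction: str) -> pd.DataFrame:
        return self.records[self.records["direction"] == direction].sort_values(
            "crossing_time_s"
        )

    @property
    def planes(self) -> np.ndarray:
        return np.sort(self.records["plane_depth_um"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cycle_period: float) -> "SlicePlan":
        return cls(pd.read_csv(path), cycle_period)


@dataclass(frozen=True)
class PulseSchedule:
    """Illumination pulse placement inside a rolling-shutter exposure (s)."""

    exposure_time: float
    frame_period: float
    pulse_duration: float
    pulse_offset_in_exposure: float
    global_window: float

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")
        end = self.pulse_offset_in_exposure + self.pulse_duration
        if self.pulse_offset_in_exposure < self.exposure_time - self.global_window - 1e-15:
            raise ValueError("pulse starts before the global exposure window")
        if end > self.exposure_time + 1e-15:
            raise ValueError("pulse extends past the exposure")


@dataclass(frozen=True)
class SmoothResult:
    waveform: Waveform
    iterations: int
    final_scale: float


@dataclass(frozen=True)
class TuneResult:
    command: Waveform
    iterations: int
    history: pd.DataFrame  # per-iteration limits and errors


@dataclass(frozen=True)
class FrameBudget:
    min_interval: float
    uniform_interval: float
    idle_fraction: float
    avg_scan_speed: float  # mm/s


def make_triangle(
    spec: ScanSpec, n_periods: int = 1, z_min: float | None = None, z_max: float | None = None
) -> Waveform:
    """Symmetric triangle command between ``z_min`` and ``z_max``.

    The first sample sits at the lower extreme, the mid-period sample at
    the upper extreme.  ``z_min``/``z_max`` override the spec's limits
    (used by the range-tuning loop, which commands a different range from
    the one it targets).
    """
    lo = spec.z_min if z_min is None else z_min
    hi = spec.z_max if z_max is None else z_max
    if hi <= lo:
        raise ValueError("z_max must exceed z_min")
    p = spec.period_samples
    k = np.arange(p)
    tri = lo + (hi - lo) * (1.0 - np.abs(2.0 * k / p - 1.0))
    samples = np.tile(tri, n_periods)
    return Waveform(samples, spec.sample_rate, p)


def _lowpass_periodic(samples: np.ndarray, sample_rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of one waveform period.

    Filters three concatenated periods forward and backward and keeps the
    middle one, so the result is periodic with no edge transients.
    """
    nyq = 0.5 * sample_rate
    if cutoff >= 0.99 * nyq:
        return samples.copy()
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    tiled = np.tile(samples, 3)
    filtered = signal.sosfiltfilt(sos, tiled)
    n = samples.size
    return filtered[n : 2 * n]


def smooth_command(
    tri: Waveform,
    cutoff_factor: float = 3.25,
    range_tolerance: float = 0.1,
    max_iter: int = 50,
) -> SmoothResult:
    """Low-pass a triangle command and restore its peak-to-peak range.

    The filter cutoff is ``cutoff_factor`` times the triangle frequency
    (32.5 Hz for a 10 Hz triangle with the default factor).  Filtering
    erodes the triangle vertices and shrinks the range, so the underlying
    triangle amplitude is expanded and re-filtered until the filtered
    peak-to-peak matches the original within ``range_tolerance`` um.
    """
    if cutoff_factor <= 1:
        raise ValueError("cutoff_factor must exceed 1")
    base = tri.one_period()
    target_ptp = float(np.ptp(base))
    center = 0.5 * (base.max() + base.min())
    cutoff = cutoff_factor / tri.period
    scale = 1.0
    for iteration in range(1, max_iter + 1):
        expanded = center + scale * (base - center)
        filtered = _lowpass_periodic(expanded, tri.sample_rate, cutoff)
        ptp = float(np.ptp(filtered))
        if abs(ptp - target_ptp) <= range_tolerance:
            n_rep = tri.samples.size // tri.period_samples
            wf = Waveform(np.tile(filtered, n_rep), tri.sample_rate, tri.period_samples)
            return SmoothResult(wf, iteration, scale)
        scale *= target_ptp / ptp
    raise RuntimeError(f"range not restored within {max_iter} iterations")


def tune_range(
    plant,
    spec: ScanSpec,
    correction: float = 0.9,
    tolerance: float = 0.1,
    max_iter: int = 50,
    cutoff_factor: float = 3.25,
) -> TuneResult:
    """Iteratively tune command limits until the measured range matches.

    ``plant`` maps a command :class:`Waveform` to a measured (sensor)
    :class:`Waveform`; it must be deterministic after its initialisation
    period (the simulator discards initial cycles for this reason).  The
    initial command range is 10% smaller than the target to guard against
    overshoot.  Each iteration the lower and upper limits are updated
    independently by ``correction`` (default 90%) of the respective error
    ``target - measured``, and a fresh smoothed command is generated.
    Stops when both limits are within ``tolerance`` um of the targets.
    """
    shrink = 0.05 * spec.scan_range
    lo_cmd, hi_cmd = spec.z_min + shrink, spec.z_max - shrink
    rows = []
    prev_err = None
    growth_streak = 0
    for iteration in range(1, max_iter + 1):
        tri = make_triangle(spec, z_min=lo_cmd, z_max=hi_cmd)
        command = smooth_command(tri, cutoff_factor=cutoff_factor).waveform
        measured = plant(command)
        m_lo = float(measured.samples.min())
        m_hi = float(measured.samples.max())
        e_lo = spec.z_min - m_lo
        e_hi = spec.z_max - m_hi
        rows.append(
            {
                "iteration": iteration,
                "command_lo_um": lo_cmd,
                "command_hi_um": hi_cmd,
                "measured_lo_um": m_lo,
                "measured_hi_um": m_hi,
                "error_lo_um": e_lo,
                "error_hi_um": e_hi,
            }
        )
        worst = max(abs(e_lo), abs(e_hi))
        if worst <= tolerance:
            return TuneResult(command, iteration, pd.DataFrame(rows))
        if prev_err is not None and worst > prev_err:
            growth_streak += 1
            if growth_streak >= 2:
                raise RuntimeError(
                    "range tuning diverging: error grew two consecutive iterations"
                )
        else:
            growth_streak = 0
        prev_err = worst
        lo_cmd += correction * e_lo
        hi_cmd += correction * e_hi
    raise RuntimeError(f"range tuning did not converge in {max_iter} iterations")


def slice_times_from_sensor(sensor: Waveform, spec: ScanSpec) -> SlicePlan:
    """Derive per-plane crossing times from a measured sensor cycle.

    Plane depths are centred in their spacing bins,
    ``z_min + (k + 1/2) * slice_spacing``, so all planes are interior to
    the tuned range.  For each plane the forward (rising) and reverse
    (falling) crossing times are found by linear interpolation between
    sensor samples; both sweeps must be monotonic between the extrema.
    Intervals between crossings are naturally longer near the extrema
    where the scanner moves slowly.
    """
    cycle = sensor.one_period()
    p = cycle.size
    i_min = int(np.argmin(cycle))
    # analyse one cycle starting at the waveform minimum, but keep times in
    # the waveform's own clock (they may extend past one nominal period)
    vals = np.roll(cycle, -i_min)
    t = (i_min + np.arange(p)) / sensor.sample_rate
    j_max = int(np.argmax(vals))
    rising_v, rising_t = vals[: j_max + 1], t[: j_max + 1]
    falling_v, falling_t = vals[j_max:], t[j_max:]
    if np.any(np.diff(rising_v) < -1e-9) or np.any(np.diff(falling_v) > 1e-9):
        raise ValueError("sweeps are not monotonic between extrema (ringing?)")

    planes = spec.z_min + (np.arange(spec.n_planes) + 0.5) * spec.slice_spacing
    lo, hi = float(vals.min()), float(vals.max())
    if planes.min() < lo or planes.max() > hi:
        raise ValueError(
            f"planes [{planes.min():.3f}, {planes.max():.3f}] um outside the "
            f"measured range [{lo:.3f}, {hi:.3f}] um"
        )
    t_fwd = np.interp(planes, rising_v, rising_t)
    t_rev = np.interp(planes, falling_v[::-1], falling_t[::-1])

    rows = []
    for k, (z, tc) in enumerate(zip(planes, t_fwd)):
        rows.append((k, z, "forward", tc))
    for k in range(len(planes) - 1, -1, -1):
        rows.append((k, planes[k], "reverse", t_rev[k]))
    records = pd.DataFrame(
        rows, columns=["slice_index", "plane_depth_um", "direction", "crossing_time_s"]
    )
    records["timing_offset_s"] = 0.0
    records["shift_x_um"] = 0.0
    records["shift_y_um"] = 0.0
    return SlicePlan(records, sensor.period)


def interpolate_stack_pairs(stacks, timestamps=None):
    """Average consecutive bidirectional stacks into virtual mid-time stacks.

    ``stacks`` is a time-ordered sequence of alternating forward/reverse
    stacks of identical shape.  Each adjacent pair yields one virtual
    stack equal to the voxelwise mean, timestamped midway between the
    sweeps (the sweep transition).  ``n`` inputs produce ``n - 1``
    outputs, doubling the average sampling rate of bidirectional imaging.
    Returns the list of stacks, or ``(stacks, times)`` when timestamps
    are given.
    """
    stacks = [np.asarray(s, dtype=float) for s in stacks]
    if len(stacks) < 2:
        raise ValueError("need at least two stacks to interpolate")
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("stacks must share one shape")
    virtual = [0.5 * (a + b) for a, b in zip(stacks[:-1], stacks[1:])]
    if timestamps is None:
        return virtual
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size != len(stacks):
        raise ValueError("one timestamp per stack required")
    return virtual, 0.5 * (timestamps[:-1] + timestamps[1:])


def plan_pulses(
    exposure_time: float,
    frame_period: float,
    min_exposure: float,
    pulse_fraction: float = 0.05,
) -> PulseSchedule:
    """Place a laser pulse in the global window at the end of an exposure.

    With a rolling shutter only the tail of the exposure is globally
    simultaneous across rows; its duration is ``exposure_time -
    min_exposure`` where ``min_exposure`` is the shortest exposure the
    camera can sustain (one line time at maximum rate).  The pulse lasts
    ``pulse_fraction`` of the exposure and ends with it; it must fit
    inside the global window, which requires running the camera slightly
    below its maximum rate.
    """
    if pulse_fraction <= 0:
        raise ValueError("pulse_fraction must be positive")
    if exposure_time <= min_exposure:
        raise ValueError("exposure must exceed the camera's minimum exposure")
    if frame_period < exposure_time:
        raise ValueError("frame period cannot be shorter than the exposure")
    global_window = exposure_time - min_exposure
    pulse_duration = pulse_fraction * exposure_time
    if pulse_duration > global_window:
        raise ValueError(
            f"pulse of {pulse_duration:.3g} s does not fit the global window "
            f"of {global_window:.3g} s; reduce frame rate or pulse fraction"
        )
    return PulseSchedule(
        exposure_time=exposure_time,
        frame_period=frame_period,
        pulse_duration=pulse_duration,
        pulse_offset_in_exposure=exposure_time - pulse_duration,
        global_window=global_window,
    )


def frame_budget(plan: SlicePlan, spec: ScanSpec) -> FrameBudget:
    """Camera utilisation summary for a slice plan.

    ``min_interval`` is the smallest gap between consecutive acquisitions
    anywhere in the cycle (wrapping across the cycle boundary);
    ``uniform_interval`` is the gap a perfect triangle would allow
    (sweep duration / planes per sweep); ``idle_fraction`` is
    ``1 - min/uniform``; ``avg_scan_speed`` is ``2 * range * frequency``
    in mm/s, counting both sweeps.
    """
    times = np.sort(plan.records["crossing_time_s"].to_numpy())
    if times.size < 4:
        raise ValueError("need at least two slices per direction")
    gaps = np.diff(times)
    wrap = plan.cycle_period - (times[-1] - times[0])
    min_interval = float(min(gaps.min(), wrap))
    sweep_duration = 0.5 * plan.cycle_period
    uniform = sweep_duration / spec.n_planes
    return FrameBudget(
        min_interval=min_interval,
        uniform_interval=uniform,
        idle_fraction=1.0 - min_interval / uniform,
        avg_scan_speed=2.0 * spec.scan_range * 1e-3 * spec.cycle_frequency,
    )
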