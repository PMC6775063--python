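"""Destriping, stack registration and bead-based PSF estimation.

Light-sheet images carry multiplicative stripe artifacts along the sheet
propagation axis (shadowing/interference), slow specimen drift between
stacks, and the axial resolution of the system is characterised by
imaging sub-diffraction fluorescent beads throughout a volume: each bead's
axial profile is fit with a Gaussian, clustered beads are rejected, the
sheet waist is localised with a sliding median of fitted widths, and the
beads nearest the waist are aligned and averaged into one empirical PSF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "BeadFit",
    "PSFEstimate",
    "Shift3D",
    "destripe",
    "register_stack_translation",
    "fit_axial_gaussian",
    "estimate_psf",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class BeadFit:
    """Axial Gaussian fit of one bead.

    ``center`` is (z, y, x) in micrometres (z sub-voxel from the fit);
    ``ok`` is cleared when the fitted axial FWHM exceeds 5x the
    diffraction limit, the signature of fused bead clusters.
    """

    center: tuple
    axial_sigma: float
    amplitude: float
    offset: float
    ok: bool

    def __post_init__(self) -> None:
        if self.axial_sigma <= 0:
            raise ValueError("axial sigma must be positive")

    @property
    def axial_fwhm(self) -> float:
        return _FWHM_PER_SIGMA * self.axial_sigma


@dataclass(frozen=True)
class PSFEstimate:
    """Averaged empirical PSF and its axial summary."""

    average_bead: np.ndarray  # 3-D, 0.1 um isotropic
    spacing: float  # um, always 0.1
    axial_profile: np.ndarray
    axial_fwhm: float
    waist_position: float  # um along the propagation axis
    n_beads: int


class Shift3D(tuple):
    """Integer (dz, dy, dx) shift with a confidence flag."""

    def __new__(cls, dz, dy, dx, confident=True, score=0.0):
        obj = super().__new__(cls, (dz, dy, dx))
        obj.confident = confident
        obj.score = score
        return obj

    @property
    def dz(self):
        return self[0]

    @property
    def dy(self):
        return self[1]

    @property
    def dx(self):
        return self[2]


def destripe(
    image: np.ndarray,
    stripe_angle: float,
    attenuation: float = 0.1,
    radial_min: float = 4.0,
    wedge_halfwidth: float = 2.0,
) -> np.ndarray:
    """Attenuate multiplicative stripes in the Fourier domain.

    The image is log-transformed (stripes are multiplicative), Fourier
    transformed, and the bins in the angular wedge perpendicular to the
    stripe *lines* (``stripe_angle`` degrees CCW from the column axis,
    wedge half-width ``wedge_halfwidth`` degrees) are multiplied by
    ``attenuation``.  Bins within ``radial_min`` cycles/image of DC are
    left untouched to preserve slow background, and the result is mapped
    back through an inverse FFT and exponentiation.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("destripe expects a non-negative image")
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must be in [0, 1]")
    if radial_min < 1.0:
        raise ValueError("radial_min below 1 cycle/image would touch DC")
    eps = 1.0
    spectrum = np.fft.fft2(np.log(image + eps))
    h, w = image.shape
    fy = np.fft.fftfreq(h)[:, None] * h  # cycles per image
    fx = np.fft.fftfreq(w)[None, :] * w
    radius = np.hypot(fy, fx)
    theta = np.degrees(np.arctan2(fy, fx))  # -180..180
    target = (stripe_angle + 90.0) % 180.0
    delta = np.abs((theta - target + 90.0) % 180.0 - 90.0)
    wedge = (delta <= wedge_halfwidth) & (radius >= radial_min)
    gain = np.ones_like(radius)
    gain[wedge] = attenuation
    out = np.clip(np.exp(np.fft.ifft2(spectrum * gain).real) - eps, 0.0, None)
    # a zero-mean multiplicative stripe has a negative mean in log space
    # (E[log(1 + d*p)] = -d^2/4 for a sinusoid), so notching it biases the
    # overall gain; restore the input's mean intensity
    if attenuation < 1.0 and out.mean() > 0:
        out *= image.mean() / out.mean()
    return out


def register_stack_translation(
    moving: np.ndarray,
    reference: np.ndarray,
    max_shift: int = 4,
    confidence_threshold: float = 0.2,
) -> Shift3D:
    """Integer 3-D shift of ``moving`` that best overlaps ``reference``.

    Exhaustive search over all shifts within ``max_shift`` voxels,
    scoring each by the normalised cross-correlation of the overlapping
    region (the simple-translation registration used between stacks of a
    timeseries).  A peak correlation below ``confidence_threshold``
    flags the result as low-confidence (e.g. pure-noise inputs).
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("stacks must share a shape")
    if moving.std() == 0 or reference.std() == 0:
        raise ValueError("blank stack: registration undefined")

    def overlap(arr, shift, other):
        sl_a, sl_b = [], []
        for s, n in zip(shift, arr.shape):
            sl_a.append(slice(max(0, s), min(n, n + s)))
            sl_b.append(slice(max(0, -s), min(n, n - s)))
        return arr[tuple(sl_a)], other[tuple(sl_b)]

    best = None
    rng = range(-max_shift, max_shift + 1)
    for dz in rng:
        for dy in rng:
            for dx in rng:
                ref_part, mov_part = overlap(reference, (dz, dy, dx), moving)
                if ref_part.size < 8:
                    continue
                a = ref_part - ref_part.mean()
                b = mov_part - mov_part.mean()
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                score = float((a * b).sum() / denom) if denom > 0 else -1.0
                key = (score, -(dz * dz + dy * dy + dx * dx))
                if best is None or key > best[0]:
                    best = (key, (dz, dy, dx))
    (score, _), (dz, dy, dx) = best
    return Shift3D(dz, dy, dx, confident=score >= confidence_threshold, score=score)


def _gauss(z, amplitude, z0, sigma, offset):
    return amplitude * np.exp(-0.5 * ((z - z0) / sigma) ** 2) + offset


def fit_axial_gaussian(
    roi: np.ndarray,
    voxel_size: tuple,
    diffraction_limit: float | None = None,
    cluster_factor: float = 5.0,
) -> BeadFit:
    """Least-squares Gaussian fit of a bead ROI's axial profile.

    The axial profile is the lateral sum of the (z, y, x) ROI; the
    Gaussian centre is a free parameter, giving sub-voxel axial
    localisation.  Lateral centre comes from intensity-weighted
    centroiding.  When ``diffraction_limit`` (an axial FWHM in um) is
    given, fits broader than ``cluster_factor`` times it are marked not
    ok — such beads are clusters/clumps and excluded from averaging.
    """
    roi = np.asarray(roi, dtype=float)
    dz, dy, dx = voxel_size
    profile = roi.sum(axis=(1, 2))
    if np.ptp(profile) <= 0:
        raise ValueError("flat ROI: no axial peak to fit")
    z = (np.arange(roi.shape[0]) + 0.5) * dz
    offset0 = float(profile.min())
    amp0 = float(profile.max() - offset0)
    z00 = float(z[np.argmax(profile)])
    sigma0 = max(dz, 0.3 * np.ptp(z) / 4)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            z,
            profile,
            p0=(amp0, z00, sigma0, offset0),
            bounds=(
                (0.0, z[0] - dz, dz * 0.05, -np.inf),
                (np.inf, z[-1] + dz, np.ptp(z) * 5, np.inf),
            ),
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise ValueError(f"axial Gaussian fit did not converge: {exc}") from None
    amplitude, z0, sigma, offset = (float(v) for v in popt)
    if amplitude <= 0:
        raise ValueError("no axial peak (non-positive fitted amplitude)")

    # lateral centroid in the slices nearest the fitted centre
    k = int(np.clip(round(z0 / dz - 0.5), 0, roi.shape[0] - 1))
    plane = np.clip(roi[k] - np.median(roi[k]), 0, None)
    total = plane.sum()
    if total > 0:
        yy, xx = np.mgrid[0 : roi.shape[1], 0 : roi.shape[2]]
        cy = float((plane * yy).sum() / total + 0.5) * dy
        cx = float((plane * xx).sum() / total + 0.5) * dx
    else:
        cy = roi.shape[1] * dy / 2
        cx = roi.shape[2] * dx / 2

    ok = True
    if diffraction_limit is not None:
        ok = _FWHM_PER_SIGMA * sigma <= cluster_factor * diffraction_limit
    return BeadFit((z0, cy, cx), sigma, amplitude, offset, ok)


def _detect_peaks_3d(stack: np.ndarray, min_distance: int, threshold: float):
    footprint = np.ones((2 * min_distance + 1,) * 3, dtype=bool)
    is_max = (stack == ndimage.maximum_filter(stack, footprint=footprint)) & (
        stack > threshold
    )
    return np.argwhere(is_max)


def estimate_psf(
    stack: np.ndarray,
    voxel_size: tuple,
    diffraction_limit: float,
    propagation_axis: int = 1,
    n_average: int = 20,
    window: float = 10.0,
    roi_lateral: int = 9,
    spacing: float = 0.1,
) -> PSFEstimate:
    """Bead-based empirical PSF of a light-sheet system.

    Beads are detected as local maxima above median + 5 robust sigma,
    each ROI (``roi_lateral`` px square, axial span covering several
    expected widths) is fit with :func:`fit_axial_gaussian`, cluster fits
    are excluded, and the median fitted FWHM within a ``window``-um
    sliding window along the ``propagation_axis`` localises the sheet
    waist at its minimum.  The ``n_average`` valid beads nearest the
    waist are aligned on their fitted centres, resampled at ``spacing``
    um isotropic spacing (trilinear), and averaged; the axial FWHM of the
    averaged bead is reported from a Gaussian fit of its axial profile.
    """
    stack = np.asarray(stack, dtype=float)
    dz, dy, dx = voxel_size
    med = np.median(stack)
    mad = np.median(np.abs(stack - med)) + 1e-12
    peaks = _detect_peaks_3d(stack, min_distance=2, threshold=med + 5 * 1.4826 * mad)

    half_lat = roi_lateral // 2
    # axial ROI half-span: a few expected widths, so that broadened
    # (clustered) beads are still measurably wide rather than truncated
    sigma_expect = diffraction_limit / _FWHM_PER_SIGMA
    half_ax = max(4, int(math.ceil(4.0 * sigma_expect / dz)) + 2)
    fits, centers = [], []
    for pz, py, px in peaks:
        if not (
            half_ax <= pz < stack.shape[0] - half_ax
            and half_lat <= py < stack.shape[1] - half_lat
            and half_lat <= px < stack.shape[2] - half_lat
        ):
            continue
        roi = stack[
            pz - half_ax : pz + half_ax + 1,
            py - half_lat : py + half_lat + 1,
            px - half_lat : px + half_lat + 1,
        ]
        try:
            fit = fit_axial_gaussian(roi, voxel_size, diffraction_limit)
        except ValueError:
            continue
        z0 = (pz - half_ax) * dz + fit.center[0]
        y0 = (py - half_lat) * dy + fit.center[1]
        x0 = (px - half_lat) * dx + fit.center[2]
        fits.append(fit)
        centers.append((z0, y0, x0))
    valid = [(f, c) for f, c in zip(fits, centers) if f.ok]
    if len(valid) < n_average:
        raise ValueError(
            f"only {len(valid)} valid bead fits; need at least {n_average}"
        )

    centers_v = np.array([c for _, c in valid])

    # keep only isolated, interior beads: a neighbour inside the
    # resampling window contaminates both the per-bead width (biasing the
    # sliding median) and the averaged profile.  Conflict candidates are
    # every detected peak, including those whose own fit was skipped.
    half_um = max(1.5 * diffraction_limit, 8 * spacing)
    half_lat_um = max(6 * spacing, half_lat * min(dy, dx) * 0.8)
    all_centers = (peaks + 0.5) * np.array(voxel_size)
    iso_scale = np.array([half_um + 2.0, 2.0, 2.0])
    extent = np.array(stack.shape) * np.array(voxel_size)
    margin = np.array([half_um, half_lat_um, half_lat_um])
    isolated = []
    for i in range(len(valid)):
        c = centers_v[i]
        if np.any(c < margin) or np.any(c > extent - margin):
            continue  # resampling window would leave the volume
        d = np.abs(all_centers - c) / iso_scale
        conflict = np.max(d, axis=1) < 1.0
        if np.count_nonzero(conflict) <= 1:  # itself only
            isolated.append(i)
    isolated = np.array(isolated, dtype=int)
    if isolated.size < n_average:
        raise ValueError(
            f"only {isolated.size} isolated bead fits; need at least {n_average}"
        )

    fwhms = np.array([valid[i][0].axial_fwhm for i in isolated])
    prop = centers_v[isolated, propagation_axis]

    # sliding-window median of fitted widths along the propagation axis
    grid = np.linspace(prop.min(), prop.max(), 101)
    medians = np.full(grid.size, np.nan)
    for i, g in enumerate(grid):
        sel = np.abs(prop - g) <= window / 2
        if np.count_nonzero(sel) >= 3:
            medians[i] = np.median(fwhms[sel])
    if np.all(np.isnan(medians)):
        raise ValueError("no window contains enough beads")
    waist = float(grid[int(np.nanargmin(medians))])
    # locate the minimum by fitting a parabola to the whole median curve:
    # the curve is shallow near the waist, so the raw argmin jitters with
    # per-bead fit noise while the parabola vertex is stable
    ok_bins = ~np.isnan(medians)
    if np.count_nonzero(ok_bins) >= 5:
        coef = np.polyfit(grid[ok_bins], medians[ok_bins], 2)
        if coef[0] > 0:
            vertex = -coef[1] / (2 * coef[0])
            if grid[0] <= vertex <= grid[-1]:
                waist = float(vertex)

    order = isolated[np.argsort(np.abs(prop - waist))][:n_average]
    nz = int(round(2 * half_um / spacing)) + 1
    nl = int(round(2 * half_lat_um / spacing)) + 1
    zg = np.linspace(-half_um, half_um, nz)
    lg = np.linspace(-half_lat_um, half_lat_um, nl)
    acc = np.zeros((nz, nl, nl))
    for idx in order:
        cz, cy, cx = centers_v[idx]
        zz = (cz + zg) / dz - 0.5
        yy = (cy + lg) / dy - 0.5
        xx = (cx + lg) / dx - 0.5
        coords = np.meshgrid(zz, yy, xx, indexing="ij")
        sub = ndimage.map_coordinates(stack, coords, order=1, mode="nearest")
        # scale beads to comparable brightness; the final Gaussian fit has a
        # free offset, so background need not be removed here
        acc += sub / max(valid[idx][0].amplitude, 1e-12)
    avg = acc / len(order)

    profile = avg.sum(axis=(1, 2))
    fit = fit_axial_gaussian(avg, (spacing, spacing, spacing))
    return PSFEstimate(
        average_bead=avg,
        spacing=spacing,
        axial_profile=profile,
        axial_fwhm=fit.axial_fwhm,
        waist_position=waist,
        n_beads=len(order),
    )
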