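"""Closed-form optics calculators for scanned light-sheet microscopes.

This module collects the small amount of optical theory needed to reason
about a light-sheet system's resolution and throughput:

* Gaussian-beam approximations of the detection and light-sheet axial PSF.
* The spherical-aberration penalty paid by *remote focusing* systems that
  image planes away from the objective's native focal plane, and the defocus
  range over which such a system stays diffraction limited.
* Photon-collection solid angles, the transmission of a binary camera-
  splitting (DPI) relay tree, and the extra light a noisy burst camera needs
  relative to a scientific CMOS camera.

Conventions
-----------
All lengths are in micrometres, object space unless stated otherwise.  The
Gaussian axial PSF uses the Gaussian-beam convention: a beam whose marginal
ray angle is ``theta = arcsin(NA / n)`` has Rayleigh range
``z_R = lambda / (pi * n * (1 - cos(theta)))`` (the exact-angle form of the
paraxial ``n * lambda / (pi * NA**2)`` with an effective beam factor of 2),
and the axial full width at half maximum of its on-axis intensity is
``2 * z_R``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ObjectiveSpec",
    "GaussianPSF",
    "AberrationCurve",
    "axial_psf_extent",
    "lightsheet_axial_psf",
    "remote_focus_spot",
    "diffraction_limited_defocus_range",
    "collection_solid_angle_ratio",
    "dpi_chain_throughput",
    "photon_requirement_ratio",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Largest defocus considered physically plausible for a piezo-scanned system.
MAX_DEFOCUS_UM = 1000.0


@dataclass(frozen=True)
class ObjectiveSpec:
    """Detection objective description.

    Parameters
    ----------
    na:
        Numerical aperture (dimensionless), ``0 < na < immersion_index``.
    magnification:
        Nominal magnification of the objective.
    immersion_index:
        Refractive index of the immersion/sample medium (1.333 for water).
    wavelength:
        Emission wavelength in micrometres.  Defaults to 0.525 um, the
        centre of a typical 500-550 nm green-emission band.
    """

    na: float
    magnification: float
    immersion_index: float = 1.333
    wavelength: float = 0.525

    def __post_init__(self) -> None:
        if not 0.0 < self.na < self.immersion_index:
            raise ValueError(
                f"need 0 < NA < immersion index, got NA={self.na}, "
                f"n={self.immersion_index}"
            )
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if not 0.3 <= self.wavelength <= 0.8:
            warnings.warn(
                f"wavelength {self.wavelength} um outside the typical "
                "0.3-0.8 um visible/near-IR band; check units (um expected)",
                stacklevel=3,
            )

    @property
    def half_angle(self) -> float:
        """Marginal ray angle ``arcsin(NA / n)`` in radians."""
        return math.asin(self.na / self.immersion_index)


@dataclass(frozen=True)
class GaussianPSF:
    """Gaussian PSF widths (micrometres, object space)."""

    sigma_lateral: float
    sigma_axial: float
    fwhm_axial: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sigma_lateral <= 0 or self.sigma_axial <= 0:
            raise ValueError("PSF widths must be positive")
        expected = _FWHM_PER_SIGMA * self.sigma_axial
        if self.fwhm_axial == 0.0:
            object.__setattr__(self, "fwhm_axial", expected)
        elif not math.isclose(self.fwhm_axial, expected, rel_tol=1e-9):
            raise ValueError("fwhm_axial inconsistent with sigma_axial")


@dataclass(frozen=True)
class AberrationCurve:
    """Axial spot size versus defocus for a remote-focusing system."""

    defocus: tuple
    spot_size: tuple
    diffraction_floor: float


def _one_minus_cos(obj: ObjectiveSpec, na: float | None = None) -> float:
    na = obj.na if na is None else na
    s = na / obj.immersion_index
    return 1.0 - math.sqrt(1.0 - s * s)


def _axial_fwhm(obj: ObjectiveSpec, na: float | None = None) -> float:
    """Gaussian-beam axial FWHM: two Rayleigh ranges, exact-angle form.

    ``z_R = lambda / (2 * pi * n * (1 - cos(theta)))`` reduces to the
    paraxial ``n * lambda / (pi * NA**2)`` since ``1 - cos(theta) ~
    theta**2 / 2``; the on-axis intensity of a Gaussian beam falls to
    half at one Rayleigh range, so the FWHM is ``2 * z_R``.  Checked
    against a scalar-diffraction (Gaussian-apodised Debye) oracle in the
    test suite.
    """
    omc = _one_minus_cos(obj, na)
    return obj.wavelength / (math.pi * obj.immersion_index * omc)


def axial_psf_extent(obj: ObjectiveSpec) -> GaussianPSF:
    """Gaussian approximation of the detection PSF of ``obj``.

    The axial width follows the Gaussian-beam convention documented in the
    module docstring; the lateral width uses the common Gaussian fit to the
    in-focus Airy core, ``sigma_lateral = 0.21 * lambda / NA``.
    """
    fwhm_ax = _axial_fwhm(obj)
    sigma_ax = fwhm_ax / _FWHM_PER_SIGMA
    sigma_lat = 0.21 * obj.wavelength / obj.na
    return GaussianPSF(sigma_lateral=sigma_lat, sigma_axial=sigma_ax)


def lightsheet_axial_psf(
    na_det: float, na_illum: float, obj: ObjectiveSpec
) -> GaussianPSF:
    """Combined axial PSF of detection objective and light sheet.

    The system axial response is the product of two Gaussians: the axial
    detection PSF (set by ``na_det``) and the sheet thickness profile at
    the illumination waist — a Gaussian-beam waist of 1/e^2 radius
    ``w0 = lambda / (pi * na_illum)``, i.e. intensity sigma ``w0 / 2`` —
    hence ``1/sigma**2`` adds.  An illumination NA of zero means a flat
    (non-focused) sheet and returns the detection-only PSF.
    """
    if na_illum < 0 or na_illum >= obj.immersion_index:
        raise ValueError("invalid illumination NA")
    det = axial_psf_extent(
        ObjectiveSpec(na_det, obj.magnification, obj.immersion_index, obj.wavelength)
    )
    if na_illum == 0.0:
        return det
    sigma_ill = obj.wavelength / (2.0 * math.pi * na_illum)
    sigma = 1.0 / math.sqrt(det.sigma_axial**-2 + sigma_ill**-2)
    return GaussianPSF(sigma_lateral=det.sigma_lateral, sigma_axial=sigma)


def _aberration_extent(obj: ObjectiveSpec, z: float) -> float:
    """Object-space longitudinal spherical aberration at defocus ``z``.

    For an objective obeying the Abbe sine condition, refocusing on the
    image side for an object plane displaced by ``z`` leaves marginal
    rays crossing the axis ``z * (1 - cos(theta))`` away from the
    paraxial focus, with ``theta`` the marginal ray angle.  At best
    focus (midway through the caustic) the rays spread over
    ``+- z * (1 - cos(theta)) / 2``; that half-spread is the axial spot
    size attributable to the aberration, on the same (half-width-like)
    footing as the diffraction FWHM it is compared against.
    """
    return 0.5 * abs(z) * _one_minus_cos(obj)


def remote_focus_spot(obj: ObjectiveSpec, z: float) -> float:
    """Axial spot size (um, object space) when imaging at defocus ``z``.

    The spot is the larger of the diffraction floor (Gaussian axial FWHM)
    and the geometric longitudinal aberration; it is even in ``z`` and
    non-decreasing in ``|z|``.
    """
    if abs(z) > MAX_DEFOCUS_UM:
        raise ValueError(
            f"|z|={abs(z)} um exceeds the plausible actuator range "
            f"({MAX_DEFOCUS_UM} um)"
        )
    return max(_axial_fwhm(obj), _aberration_extent(obj, z))


def aberration_curve(obj: ObjectiveSpec, z_max: float = 500.0, n: int = 201) -> AberrationCurve:
    """Sampled spot-size-versus-defocus curve for plotting/tabulation."""
    zs = [z_max * (2 * i / (n - 1) - 1.0) for i in range(n)]
    return AberrationCurve(
        defocus=tuple(zs),
        spot_size=tuple(remote_focus_spot(obj, z) for z in zs),
        diffraction_floor=_axial_fwhm(obj),
    )


def diffraction_limited_defocus_range(
    obj: ObjectiveSpec, tol: float = 0.1
) -> float:
    """Largest ``|z|`` at which remote focusing stays diffraction limited.

    Bisects for the defocus at which the longitudinal aberration first
    exceeds the diffraction floor, to ``tol`` micrometres.  Returns
    ``math.inf`` if the spot never exceeds the floor within the plausible
    actuator range.
    """
    floor = _axial_fwhm(obj)

    def excess(z: float) -> float:
        return _aberration_extent(obj, z) - floor

    lo, hi = 0.0, MAX_DEFOCUS_UM
    if excess(hi) <= 0.0:
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excess(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def collection_solid_angle_ratio(
    na_a: float, na_b: float, immersion_index: float = 1.0
) -> float:
    """Ratio of photon-collection solid angles of two apertures.

    The solid angle of a cone of half-angle ``arcsin(NA / n)`` is
    ``2 * pi * (1 - cos(arcsin(NA / n)))``.  By default ``n = 1`` so the
    NA is interpreted directly as the sine of the half angle; pass the
    immersion index to get medium-aware angles.
    """
    for na in (na_a, na_b):
        if not 0.0 < na < immersion_index:
            raise ValueError(f"NA {na} incompatible with n={immersion_index}")

    def omega(na: float) -> float:
        return 2.0 * math.pi * (1.0 - math.sqrt(1.0 - (na / immersion_index) ** 2))

    return omega(na_a) / omega(na_b)


def dpi_chain_throughput(
    n_cameras: int, relay_efficiency: float, mirror_efficiency: float = 1.0
) -> tuple[float, int]:
    """Transmission and speedup of a balanced camera-splitting tree.

    A knife-edge-mirror splitting stage halves the image and sends each
    half through one relay; chaining stages forms a balanced binary tree
    of depth ``log2(n_cameras)``.  Every photon traverses ``depth``
    relay/mirror pairs, so total transmission is
    ``(relay_efficiency * mirror_efficiency) ** depth`` while frame rate
    scales linearly with the camera count.

    Returns ``(throughput, speedup)`` with ``speedup = n_cameras``.
    """
    if n_cameras < 2 or (n_cameras & (n_cameras - 1)) != 0:
        raise ValueError("camera count must be a power of two >= 2")
    for eff in (relay_efficiency, mirror_efficiency):
        if not 0.0 < eff <= 1.0:
            raise ValueError("efficiencies must be in (0, 1]")
    depth = int(math.log2(n_cameras))
    return (relay_efficiency * mirror_efficiency) ** depth, n_cameras


def photon_requirement_ratio(
    qe_a: float, read_noise_a: float, qe_b: float, read_noise_b: float
) -> float:
    """Extra light camera *b* needs to match camera *a*'s read-noise SNR.

    In the read-noise-limited regime SNR = QE * N / sigma_read, so equal
    SNR requires ``N_b / N_a = (qe_a / qe_b) * (read_noise_b / read_noise_a)``.
    """
    for qe in (qe_a, qe_b):
        if not 0.0 < qe <= 1.0:
            raise ValueError("quantum efficiencies must be in (0, 1]")
    if read_noise_a <= 0 or read_noise_b <= 0:
        raise ValueError("read noises must be positive")
    return (qe_a / qe_b) * (read_noise_b / read_noise_a)
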