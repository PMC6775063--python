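"""Image-guided refinement of per-slice exposure timing and lateral shift.

Sensor-guided slice timing assumes the piezo's sensor reading equals the
true focal-plane position, but during fast scanning dynamic forces make
the focus lead or lag the sensor (the error tracks the command's
acceleration) and flex the assembly laterally by a micron or two.  The fix
is empirical: acquire each slice at a grid of timing offsets around the
naive sensor-based time, register each trial image laterally to a static
ground-truth stack, score the registered image by normalised
sum-of-squared differences, and keep the offset and shift that score best
— separately for forward and reverse sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CalibrationGrid",
    "CalibrationResult",
    "Shift2D",
    "register_translation_2d",
    "similarity_score",
    "calibrate_offsets",
]


@dataclass(frozen=True)
class CalibrationGrid:
    """Timing-offset search grid and lateral-shift budget.

    Defaults follow the acquisition protocol: offsets from 0 to 1.2 ms in
    50 us steps (25 candidates) and at most 2 um of lateral shift.
    """

    offsets: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 1.2e-3 + 25e-6, 50e-6)
    )
    max_lateral_shift: float = 2.0  # um

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        if offsets.size < 2 or np.any(np.diff(offsets) <= 0):
            raise ValueError("offsets must be sorted with at least two entries")
        if self.max_lateral_shift < 0:
            raise ValueError("max_lateral_shift must be non-negative")


class Shift2D(tuple):
    """Integer (dy, dx) shift with an at-boundary flag."""

    def __new__(cls, dy, dx, at_boundary=False):
        obj = super().__new__(cls, (dy, dx))
        obj.at_boundary = at_boundary
        return obj

    @property
    def dy(self):
        return self[0]

    @property
    def dx(self):
        return self[1]


@dataclass
class CalibrationResult:
    """Best offset/shift/score per (slice, direction), with score curves."""

    records: pd.DataFrame  # slice_index, direction, best_offset_s, dy_px, dx_px, best_score
    score_curves: dict  # (slice_index, direction) -> DataFrame(offset_s, score)

    def best_offset(self, slice_index: int, direction: str) -> float:
        sel = self.records[
            (self.records["slice_index"] == slice_index)
            & (self.records["direction"] == direction)
        ]
        return float(sel["best_offset_s"].iloc[0])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def register_translation_2d(
    moving: np.ndarray, fixed: np.ndarray, max_shift: int, subpixel: bool = False
) -> Shift2D:
    """Shift of ``moving`` that best matches ``fixed``.

    Exhaustive search over all integer (dy, dx) within ``max_shift``
    pixels, minimising the overlap-normalised SSD; the small window makes
    brute force both fast and exactly optimal.  With ``subpixel`` the
    integer optimum is refined by a separable parabolic fit through the
    neighbouring scores.  Results on the search boundary are flagged
    (the true shift may lie outside the budget).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must share a shape")
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("blank image: registration undefined")
    max_shift = int(max_shift)
    n = 2 * max_shift + 1
    scores = np.full((n, n), np.inf)
    h, w = fixed.shape
    for i, dy in enumerate(range(-max_shift, max_shift + 1)):
        for j, dx in enumerate(range(-max_shift, max_shift + 1)):
            f = fixed[max(0, dy) : min(h, h + dy), max(0, dx) : min(w, w + dx)]
            m = moving[max(0, -dy) : min(h, h - dy), max(0, -dx) : min(w, w - dx)]
            denom = float((f**2).sum())
            if denom <= 0 or f.size < 16:
                continue
            scores[i, j] = float(((m - f) ** 2).sum()) / denom
    i0, j0 = np.unravel_index(np.argmin(scores), scores.shape)
    dy, dx = i0 - max_shift, j0 - max_shift
    at_boundary = max(abs(dy), abs(dx)) == max_shift and max_shift > 0

    def parabolic(s_m, s_0, s_p):
        denom = s_m - 2 * s_0 + s_p
        if not np.isfinite(denom) or denom <= 0:
            return 0.0
        return float(np.clip(0.5 * (s_m - s_p) / denom, -0.5, 0.5))

    fy = fx = 0.0
    if subpixel and not at_boundary and max_shift > 0:
        if 0 < i0 < n - 1:
            fy = parabolic(scores[i0 - 1, j0], scores[i0, j0], scores[i0 + 1, j0])
        if 0 < j0 < n - 1:
            fx = parabolic(scores[i0, j0 - 1], scores[i0, j0], scores[i0, j0 + 1])
    return Shift2D(dy + fy, dx + fx, at_boundary)


def similarity_score(
    trial: np.ndarray, reference: np.ndarray, overlap_mask: np.ndarray | None = None
) -> float:
    """Normalised SSD between registered images over their overlap.

    ``sum((trial - reference)^2) / sum(reference^2)`` over the overlap
    region: 0 for identical images, 1 when the trial carries none of the
    reference energy.  Lower is more similar — the "highest similarity"
    in the acquisition protocol corresponds to the lowest score.
    """
    trial = np.asarray(trial, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trial.shape != reference.shape:
        raise ValueError("images must share a shape")
    if overlap_mask is not None:
        trial = trial[overlap_mask]
        reference = reference[overlap_mask]
    if trial.size == 0:
        raise ValueError("empty overlap region")
    denom = float((reference**2).sum())
    if denom == 0:
        raise ValueError("reference has no energy in the overlap")
    return float(((trial - reference) ** 2).sum()) / denom


def calibrate_offsets(
    ground_truth: np.ndarray,
    acquire,
    grid: CalibrationGrid,
    directions: tuple = ("forward", "reverse"),
    pixel_size: float = 0.65,
    improvement_tolerance: float = 1e-3,
) -> CalibrationResult:
    """Choose the best timing offset and lateral shift per slice.

    ``ground_truth`` is a (slices, y, x) stack acquired quasi-statically
    (slow scan), ``acquire(slice_index, direction, offset)`` returns the
    dynamic trial image for a timing offset (s) added to the naive
    sensor-based timing.  For each slice and direction every offset on
    the grid is tried; the trial image is first registered laterally
    (within ``max_lateral_shift`` um, converted to pixels by
    ``pixel_size``), then scored with :func:`similarity_score`.  The
    lowest score wins; ties break toward the earliest offset.  If no
    offset improves on the naive timing by more than
    ``improvement_tolerance``, the naive timing is kept and a warning is
    recorded in the result.
    """
    ground_truth = np.asarray(ground_truth, dtype=float)
    max_shift_px = int(round(grid.max_lateral_shift / pixel_size))
    rows = []
    curves = {}
    for direction in directions:
        for k in range(ground_truth.shape[0]):
            ref = ground_truth[k]
            scores = np.empty(grid.offsets.size)
            shifts = []
            for i, offset in enumerate(grid.offsets):
                trial = np.asarray(acquire(k, direction, float(offset)), dtype=float)
                shift = register_translation_2d(trial, ref, max_shift_px, subpixel=True)
                aligned = ndimage.shift(
                    trial, (shift.dy, shift.dx), order=3, mode="nearest"
                )
                scores[i] = similarity_score(aligned, ref)
                shifts.append(shift)
            best = int(np.argmin(scores))  # argmin takes the earliest on ties
            naive = scores[0] if grid.offsets[0] == 0.0 else None
            kept_naive = False
            if naive is not None and naive - scores[best] <= improvement_tolerance:
                best, kept_naive = 0, True
            rows.append(
                {
                    "slice_index": k,
                    "direction": direction,
                    "best_offset_s": float(grid.offsets[best]),
                    "dy_px": shifts[best].dy,
                    "dx_px": shifts[best].dx,
                    "best_score": float(scores[best]),
                    "kept_naive": kept_naive,
                }
            )
            curves[(k, direction)] = pd.DataFrame(
                {"offset_s": grid.offsets, "score": scores}
            )
    return CalibrationResult(pd.DataFrame(rows), curves)
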