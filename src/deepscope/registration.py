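"""Rigid (translation-only) 2-D frame alignment.

Two estimators are provided: subpixel cross-correlation (for the motility
projections) and an iterative translation-only Lucas-Kanade solver (for
calcium-movie and spine-stack stabilization).  A shift ``(dy, dx)`` is the
displacement of the moving frame relative to the reference:
``moving(y, x) ≈ reference(y − dy, x − dx)``.  ``apply_shift`` undoes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


class RegistrationError(RuntimeError):
    pass


@dataclass
class Shift:
    dy: float
    dx: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dy) and np.isfinite(self.dx)):
            raise RegistrationError("shift components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dy, self.dx))


def _check_pair(reference: np.ndarray, moving: np.ndarray) -> None:
    if reference.shape != moving.shape:
        raise RegistrationError(
            f"shape mismatch: reference {reference.shape} vs moving {moving.shape}"
        )
    if reference.ndim != 2:
        raise RegistrationError("registration operates on 2-D frames")


def estimate_shift_xcorr(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample: int = 10,
    max_shift: float = 20.0,
    normalization: Optional[str] = None,
) -> Shift:
    """Translation maximizing cross-correlation, refined to 1/upsample px.

    ``normalization=None`` (plain cross-correlation on mean-subtracted
    images) is the most precise choice when the two frames differ only by
    noise; ``"phase"`` whitens the cross-power spectrum, trading a little
    subpixel precision for robustness when the scene itself changes
    between frames (as consecutive motility timepoints do).
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    _check_pair(reference, moving)
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if reference.std() == 0 or moving.std() == 0:
        raise RegistrationError("correlation undefined for constant images")
    (reg_dy, reg_dx), error, _ = phase_cross_correlation(
        reference - reference.mean(),
        moving - moving.mean(),
        upsample_factor=upsample,
        normalization=normalization,
    )
    # phase_cross_correlation returns the shift that registers moving onto
    # the reference; the displacement of moving itself is its negation.
    shift = Shift(dy=float(-reg_dy), dx=float(-reg_dx), score=float(1.0 - error))
    if shift.magnitude > max_shift:
        raise RegistrationError(
            f"estimated shift {shift.magnitude:.1f} px exceeds max_shift={max_shift}"
        )
    return shift


def apply_shift(image: np.ndarray, shift: Shift, fill: float = 0.0) -> np.ndarray:
    """Translate by (−dy, −dx) with bilinear interpolation, filling borders.

    Composing with the estimated shift aligns the moving frame back onto
    its reference; integer shifts reduce to pure index shifts.
    """
    image = np.asarray(image, dtype=np.float64)
    return ndimage.shift(
        image, (-shift.dy, -shift.dx), order=1, mode="constant", cval=fill, prefilter=False
    )


def estimate_shift_lk(
    reference: np.ndarray,
    moving: np.ndarray,
    max_iter: int = 50,
    tol: float = 0.01,
    max_shift: float = 20.0,
) -> Shift:
    """Translation-only Lucas-Kanade: iterate the 2×2 normal equations.

    At each step the moving frame is warped by the current estimate, the
    residual against the reference is projected onto the reference
    gradients, and the resulting 2-vector update is accumulated until it
    falls below ``tol`` pixels or ``max_iter`` is reached.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    _check_pair(reference, moving)
    gy, gx = np.gradient(reference)
    # interior only: border gradients are one-sided and warping fills borders
    m = np.zeros(reference.shape, dtype=bool)
    m[2:-2, 2:-2] = True
    H = np.array(
        [
            [np.sum(gy[m] * gy[m]), np.sum(gy[m] * gx[m])],
            [np.sum(gx[m] * gy[m]), np.sum(gx[m] * gx[m])],
        ]
    )
    if np.linalg.cond(H) > 1e12 or not np.all(np.isfinite(H)):
        raise RegistrationError("singular normal matrix: image has no usable gradients")
    Hinv = np.linalg.inv(H)
    dy, dx = 0.0, 0.0
    for _ in range(max_iter):
        warped = ndimage.shift(
            moving, (dy, dx), order=1, mode="constant", cval=0.0, prefilter=False
        )
        err = (reference - warped)[m]
        b = np.array([np.sum(gy[m] * err), np.sum(gx[m] * err)])
        step_y, step_x = Hinv @ b
        # residual r ≈ −(δy·gy + δx·gx) for remaining displacement δ of the
        # warped frame, so the solved step moves the estimate toward −δ.
        dy -= step_y
        dx -= step_x
        if float(np.hypot(step_y, step_x)) < tol:
            break
    shift = Shift(dy=-dy, dx=-dx, score=float("nan"))
    if shift.magnitude > max_shift:
        raise RegistrationError(
            f"estimated shift {shift.magnitude:.1f} px exceeds max_shift={max_shift}"
        )
    return shift


def valid_region(shifts: Sequence[Shift], shape: Tuple[int, int]) -> Tuple[slice, slice]:
    """Maximal rectangle covered by every aligned frame (no fill pixels)."""
    H, W = shape
    y0, x0 = 0.0, 0.0
    y1, x1 = float(H), float(W)
    for s in shifts:
        y0 = max(y0, -s.dy)
        y1 = min(y1, H - s.dy)
        x0 = max(x0, -s.dx)
        x1 = min(x1, W - s.dx)
    ys = slice(int(np.ceil(y0)), int(np.floor(y1)))
    xs = slice(int(np.ceil(x0)), int(np.floor(x1)))
    if ys.start >= ys.stop or xs.start >= xs.stop:
        raise RegistrationError("shifts leave no common valid region")
    return ys, xs


def register_series(
    frames: Sequence[np.ndarray],
    reference: Literal["first", "previous"] = "first",
    upsample: int = 10,
    max_shift: float = 20.0,
    normalization: Optional[str] = "phase",
) -> Tuple[List[np.ndarray], List[Shift], Tuple[slice, slice]]:
    """Align a time series of frames by cross-correlation.

    With ``reference="first"`` every frame is registered directly to frame
    0 (no drift accumulation); with ``"previous"`` pairwise shifts are
    chained.  Returns aligned frames, per-frame shifts and the common valid
    rectangle free of fill pixels — downstream pixel classification must be
    restricted to it.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) < 2:
        raise RegistrationError("need at least 2 frames")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise RegistrationError("all frames must share one shape")
    shifts: List[Shift] = [Shift(0.0, 0.0, score=1.0)]
    for i in range(1, len(frames)):
        ref = frames[0] if reference == "first" else frames[i - 1]
        s = estimate_shift_xcorr(
            ref, frames[i], upsample=upsample, max_shift=max_shift,
            normalization=normalization,
        )
        if reference == "previous":
            prev = shifts[i - 1]
            s = Shift(dy=s.dy + prev.dy, dx=s.dx + prev.dx, score=s.score)
        shifts.append(s)
    aligned = [frames[0]] + [apply_shift(f, s) for f, s in zip(frames[1:], shifts[1:])]
    region = valid_region(shifts, shape)
    return aligned, shifts, region
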