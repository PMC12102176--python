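"""Microglial fine-process motility: binarization chain, ΔB map, turnover rate.

Each registered z-projection is binarized (CLAHE → Otsu → small-blob
removal).  For consecutive binarized frames B(t_i), B(t_{i+1}) the
temporal-variation map is

    ΔB(t_i) = 2·B(t_i) − B(t_{i+1})

whose values classify every pixel: 1 = stable (on → on), −1 = gained
(off → on), 2 = lost (on → off), 0 = background.  The per-interval
turnover rate is

    TOR(t_i) = (N_g + N_l) / (N_s + N_g + N_l)

and the session statistic is the mean of TOR over the N−1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .config import MotilityConfig
from .io import ImageStack, RoiLabelMask
from .preprocess import (
    BinaryMap,
    clahe,
    max_project_z,
    median_filter_xy,
    otsu_threshold,
    remove_small_blobs,
)
from .registration import register_series

STABLE, GAINED, LOST, BACKGROUND = 1, -1, 2, 0


@dataclass
class DeltaMap:
    """Per-pixel fate map over {−1, 0, 1, 2} for one interval (t_i, t_{i+1})."""

    values: np.ndarray
    interval: Tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        bad = ~np.isin(self.values, (STABLE, GAINED, LOST, BACKGROUND))
        if bad.any():
            raise ValueError("DeltaMap values must lie in {-1, 0, 1, 2}")


@dataclass
class MotilityInterval:
    t_index: int
    n_stable: int
    n_gained: int
    n_lost: int
    frac_stable: float = float("nan")
    frac_gained: float = float("nan")
    frac_lost: float = float("nan")
    tor: float = float("nan")
    valid: bool = True
    dt_s: Optional[float] = None


@dataclass
class MotilityResult:
    intervals: List[MotilityInterval]
    mean_tor: float
    mean_frac_stable: float = float("nan")
    mean_frac_gained: float = float("nan")
    mean_frac_lost: float = float("nan")
    shifts: List = field(default_factory=list)
    region: Optional[Tuple[slice, slice]] = None


def binarize_projection(projection: np.ndarray, cfg: Optional[MotilityConfig] = None) -> BinaryMap:
    """CLAHE → Otsu → remove_small_blobs, in that order.

    Otsu always produces a split, even on a frame containing nothing but
    noise (where it halves the noise distribution and the resulting
    half-density mask percolates into blobs too large for the size
    filter).  The mask is therefore accepted only if the candidate
    foreground is separated from the background by at least
    ``cfg.snr_floor`` robust background spreads on the raw projection;
    otherwise the frame is declared structureless and the mask is empty.
    """
    cfg = cfg or MotilityConfig()
    eq = clahe(projection, clip_limit=cfg.clahe_clip_limit, tiles=cfg.clahe_tiles)
    _, bmap = otsu_threshold(eq, n_bins=cfg.otsu_bins)
    fg = np.asarray(projection, dtype=np.float64)[bmap.mask]
    bg = np.asarray(projection, dtype=np.float64)[~bmap.mask]
    if fg.size and bg.size:
        spread = 1.4826 * np.median(np.abs(bg - np.median(bg)))
        if spread > 0 and (np.median(fg) - np.median(bg)) / spread < cfg.snr_floor:
            return BinaryMap(mask=np.zeros_like(bmap.mask), t_index=bmap.t_index)
    return remove_small_blobs(bmap, min_size=cfg.min_blob_px, connectivity=cfg.connectivity)


def delta_map(b_i: BinaryMap, b_i1: BinaryMap) -> DeltaMap:
    """ΔB = 2·B(t_i) − B(t_{i+1}), elementwise with true=1/false=0."""
    if b_i.mask.shape != b_i1.mask.shape:
        raise ValueError("binary maps must share one shape")
    values = 2 * b_i.mask.astype(np.int8) - b_i1.mask.astype(np.int8)
    return DeltaMap(values=values, interval=(b_i.t_index, b_i1.t_index))


def classify_counts(delta: DeltaMap, roi: Optional[np.ndarray] = None) -> Tuple[int, int, int]:
    """Counts of stable (1), gained (−1) and lost (2) pixels; 0 is ignored.

    An optional boolean ROI restricts the counts to one cell's pixels.
    """
    v = delta.values
    if roi is not None:
        if roi.shape != v.shape:
            raise ValueError("ROI shape must match the delta map")
        v = v[roi]
    return (
        int(np.count_nonzero(v == STABLE)),
        int(np.count_nonzero(v == GAINED)),
        int(np.count_nonzero(v == LOST)),
    )


def interval_metrics(
    counts: Tuple[int, int, int], t_index: int = 0, dt_s: Optional[float] = None
) -> MotilityInterval:
    """Fractions and turnover rate from (N_s, N_g, N_l).

    An all-zero interval (no process pixels at either timepoint) has an
    undefined TOR; it is flagged invalid and excluded from averaging rather
    than silently counted as zero.
    """
    n_s, n_g, n_l = counts
    if min(counts) < 0:
        raise ValueError("counts must be nonnegative")
    total = n_s + n_g + n_l
    iv = MotilityInterval(t_index=t_index, n_stable=n_s, n_gained=n_g, n_lost=n_l, dt_s=dt_s)
    if total == 0:
        iv.valid = False
        return iv
    iv.frac_stable = n_s / total
    iv.frac_gained = n_g / total
    iv.frac_lost = n_l / total
    iv.tor = (n_g + n_l) / total
    return iv


def summarize_intervals(intervals: List[MotilityInterval], pooled: bool = False) -> MotilityResult:
    valid = [iv for iv in intervals if iv.valid]
    if not valid:
        return MotilityResult(intervals=intervals, mean_tor=float("nan"))
    if pooled:
        tot = interval_metrics(
            (
                sum(iv.n_stable for iv in valid),
                sum(iv.n_gained for iv in valid),
                sum(iv.n_lost for iv in valid),
            )
        )
        return MotilityResult(
            intervals=intervals,
            mean_tor=tot.tor,
            mean_frac_stable=tot.frac_stable,
            mean_frac_gained=tot.frac_gained,
            mean_frac_lost=tot.frac_lost,
        )
    return MotilityResult(
        intervals=intervals,
        mean_tor=float(np.mean([iv.tor for iv in valid])),
        mean_frac_stable=float(np.mean([iv.frac_stable for iv in valid])),
        mean_frac_gained=float(np.mean([iv.frac_gained for iv in valid])),
        mean_frac_lost=float(np.mean([iv.frac_lost for iv in valid])),
    )


def motility_pipeline(
    stack: ImageStack,
    cfg: Optional[MotilityConfig] = None,
    roi_mask: Optional[RoiLabelMask] = None,
) -> MotilityResult:
    """Full pipeline: median filter → z-projection → registration →
    binarization → ΔB classification → TOR per interval → session mean.

    Classification is restricted to the registration's common valid region
    so border fill can never be scored as gained or lost; a ROI label mask
    further restricts counting to one cell.
    """
    cfg = cfg or MotilityConfig()
    T = stack.n_timepoints
    if T < 2:
        raise ValueError("motility needs at least 2 timepoints")
    filtered = median_filter_xy(stack, kernel=cfg.median_kernel)
    projections = [max_project_z(filtered, t, cfg.channel) for t in range(T)]
    if cfg.register_frames:
        aligned, shifts, region = register_series(
            projections, reference=cfg.reference, upsample=cfg.upsample, max_shift=cfg.max_shift
        )
    else:
        aligned, shifts, region = projections, [], (
            slice(0, projections[0].shape[0]),
            slice(0, projections[0].shape[1]),
        )
    ys, xs = region
    roi = None
    if roi_mask is not None:
        if roi_mask.labels.shape != projections[0].shape:
            raise ValueError("ROI mask shape must match the projection")
        roi = roi_mask.labels[ys, xs] > 0
    bmaps = []
    for t, frame in enumerate(aligned):
        bm = binarize_projection(frame[ys, xs], cfg)
        bm.t_index = t
        bmaps.append(bm)
    dt = stack.frame_interval
    intervals = [
        interval_metrics(
            classify_counts(delta_map(bmaps[i], bmaps[i + 1]), roi=roi), t_index=i, dt_s=dt
        )
        for i in range(T - 1)
    ]
    result = summarize_intervals(intervals, pooled=cfg.pooled)
    result.shifts = shifts
    result.region = region
    return result
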