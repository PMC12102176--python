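"""Calcium-event detection for astrocyte microdomains and neuronal ΔF/F.

Astrocyte branch: each ROI trace is normalized by a robust z-score
(median/MAD with the normal-consistency constant 1.4826), smoothed with a
Gaussian, and local maxima above a hard threshold become peak candidates;
each candidate gets an amplitude (peak − local baseline) and a full
duration at half-maximum (FDHM) from linearly interpolated half-level
crossings.

Neuronal branch: ΔF/F = (F − F0)/F0 with F0 the 8th percentile of a
rolling 200-frame window, then peak amplitude and half-width of decay
(time from peak to the half-amplitude crossing on the falling side).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from .config import AstroConfig
from .io import RoiLabelMask

MAD_SCALE = 1.4826  # makes MAD consistent with the SD of a normal sample


@dataclass
class Trace:
    """A single ROI's fluorescence time series at sampling rate ``fs`` Hz."""

    values: np.ndarray
    fs: float
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Trace values must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass
class CalciumEvent:
    roi_id: int
    peak_index: int
    peak_time: float
    amplitude: float
    fdhm: Optional[float] = None
    half_width_decay: Optional[float] = None
    baseline: float = 0.0
    flags: List[str] = field(default_factory=list)


@dataclass
class EventSummary:
    roi_id: int
    n_events: int
    frequency_per_min: float
    amplitudes: List[float]
    fdhms: List[float]


def propose_microdomain_rois(movie: np.ndarray, cfg: Optional[AstroConfig] = None) -> RoiLabelMask:
    """Activity-based ROI proposal for a (T, Y, X) movie.

    The per-pixel temporal standard deviation is Gaussian-smoothed and
    Otsu-thresholded; connected components within the configured area
    bounds become labeled ROIs.  A transparent stand-in for manual/macro
    microdomain selection — externally supplied label masks bypass it.
    """
    cfg = cfg or AstroConfig()
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, Y, X)")
    sd = movie.std(axis=0)
    if cfg.roi_smooth_sigma_px > 0:
        sd = ndimage.gaussian_filter(sd, cfg.roi_smooth_sigma_px)
    if sd.max() == sd.min():
        return RoiLabelMask(labels=np.zeros(sd.shape, dtype=np.int32))
    mask = sd > _skfilters.threshold_otsu(sd)
    labeled = _skmeasure.label(mask, connectivity=2)
    out = np.zeros_like(labeled, dtype=np.int32)
    next_id = 1
    for region in _skmeasure.regionprops(labeled):
        if cfg.roi_min_area <= region.area <= cfg.roi_max_area:
            out[labeled == region.label] = next_id
            next_id += 1
    return RoiLabelMask(labels=out)


def extract_roi_traces(movie: np.ndarray, rois: RoiLabelMask, fs: float) -> List[Trace]:
    """Per-frame mean intensity over each ROI's pixels."""
    movie = np.asarray(movie, dtype=np.float64)
    if movie.shape[1:] != rois.labels.shape:
        raise ValueError("movie frames and ROI mask shapes disagree")
    traces = []
    for rid in rois.roi_ids():
        sel = rois.labels == rid
        if not sel.any():
            raise ValueError(f"ROI {rid} is empty")
        traces.append(Trace(values=movie[:, sel].mean(axis=1), fs=fs, roi_id=rid))
    return traces


def robust_zscore(trace: Trace) -> Trace:
    """z = (x − median) / (1.4826 · MAD), over the whole series."""
    x = trace.values
    if x.size < 3:
        raise ValueError("robust z-score needs at least 3 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero: trace has no spread")
    return replace(trace, values=(x - med) / (MAD_SCALE * mad))


def gaussian_smooth(trace: Trace, sigma_s: float = 1.0) -> Trace:
    """Gaussian convolution with σ = sigma_s·fs samples, reflect boundary."""
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if sigma_s == 0:
        return replace(trace, values=trace.values.copy())
    return replace(
        trace, values=ndimage.gaussian_filter1d(trace.values, sigma_s * trace.fs, mode="reflect")
    )


def detect_peaks(trace: Trace, threshold_z: float = 3.0, min_sep_s: float = 1.0) -> List[int]:
    """Local maxima at or above the hard threshold.

    Strictly greater than both neighbors (plateaus contribute their first
    index); endpoints are never peaks; peaks closer than ``min_sep_s`` keep
    only the larger.
    """
    distance = max(1, int(round(min_sep_s * trace.fs)))
    peaks, props = signal.find_peaks(
        trace.values, height=threshold_z, distance=distance, plateau_size=1
    )
    return [int(i) for i in props["left_edges"]]


def _interp_crossing(x: np.ndarray, i_below: int, i_above: int, level: float) -> float:
    """Sample position where x crosses level between two adjacent samples."""
    lo, hi = x[i_below], x[i_above]
    if hi == lo:
        return float(i_above)
    frac = (level - lo) / (hi - lo)
    return i_below + frac * (i_above - i_below)


def event_metrics(
    trace: Trace,
    peak: int,
    baseline_window_s: float = 10.0,
    prev_peak: Optional[int] = None,
    next_peak: Optional[int] = None,
) -> CalciumEvent:
    """Amplitude and FDHM of one detected peak.

    Baseline = median of the ``baseline_window_s`` preceding event onset,
    where onset is the last sub-half-maximum sample before the peak (one
    refinement pass from an initial pre-peak estimate).  FDHM is the time
    between the two half-level crossings flanking the peak, linearly
    interpolated; a crossing not found before an adjacent peak or the trace
    boundary flags the FDHM undefined.
    """
    x = trace.values
    n = x.size
    if not (0 <= peak < n):
        raise IndexError("peak index out of range")
    w = max(1, int(round(baseline_window_s * trace.fs)))
    lo_bound = 0 if prev_peak is None else max(0, prev_peak)
    hi_bound = n - 1 if next_peak is None else min(n - 1, next_peak)
    flags: List[str] = []

    def _baseline(before: int) -> float:
        seg = x[max(lo_bound, before - w): before]
        return float(np.median(seg)) if seg.size else float(x[max(lo_bound, before - 1)])

    baseline = _baseline(peak)
    for _ in range(2):  # onset and baseline refine each other once
        half = baseline + (x[peak] - baseline) / 2.0
        onset = None
        for i in range(peak - 1, lo_bound - 1, -1):
            if x[i] < half:
                onset = i
                break
        if onset is None:
            break
        baseline = _baseline(onset + 1)
    amplitude = float(x[peak] - baseline)
    half_level = baseline + amplitude / 2.0

    left: Optional[float] = None
    for i in range(peak - 1, lo_bound - 1, -1):
        if x[i] < half_level:
            left = _interp_crossing(x, i, i + 1, half_level)
            break
    right: Optional[float] = None
    for i in range(peak + 1, hi_bound + 1):
        if x[i] < half_level:
            right = _interp_crossing(x, i, i - 1, half_level)
            break
    fdhm = None
    if left is None or right is None:
        flags.append("fdhm_undefined")
    else:
        fdhm = float((right - left) / trace.fs)
    hwd = None
    if right is None:
        flags.append("decay_truncated")
    else:
        hwd = float((right - peak) / trace.fs)
    return CalciumEvent(
        roi_id=trace.roi_id,
        peak_index=peak,
        peak_time=peak / trace.fs,
        amplitude=amplitude,
        fdhm=fdhm,
        half_width_decay=hwd,
        baseline=baseline,
        flags=flags,
    )


def detect_events(
    trace: Trace,
    threshold_z: float = 3.0,
    min_sep_s: float = 1.0,
    baseline_window_s: float = 10.0,
) -> List[CalciumEvent]:
    """Peak detection plus metrics for every candidate on one trace."""
    peaks = detect_peaks(trace, threshold_z=threshold_z, min_sep_s=min_sep_s)
    events = []
    for j, p in enumerate(peaks):
        events.append(
            event_metrics(
                trace,
                p,
                baseline_window_s=baseline_window_s,
                prev_peak=peaks[j - 1] if j > 0 else None,
                next_peak=peaks[j + 1] if j + 1 < len(peaks) else None,
            )
        )
    return events


def summarize_events(
    events: Sequence[CalciumEvent], duration_s: float, roi_id: int = 0
) -> EventSummary:
    """Event frequency (per min) plus amplitude and FDHM lists.

    Undefined FDHMs are excluded from the FDHM list, so its n may be
    smaller than the amplitude list's.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return EventSummary(
        roi_id=roi_id,
        n_events=len(events),
        frequency_per_min=len(events) / (duration_s / 60.0),
        amplitudes=[e.amplitude for e in events],
        fdhms=[e.fdhm for e in events if e.fdhm is not None],
    )


def astro_event_pipeline(
    traces: Sequence[Trace], cfg: Optional[AstroConfig] = None
) -> Tuple[List[CalciumEvent], List[EventSummary]]:
    """Robust z-score → Gaussian smooth → hard-threshold peaks → metrics."""
    cfg = cfg or AstroConfig()
    all_events: List[CalciumEvent] = []
    summaries: List[EventSummary] = []
    for tr in traces:
        z = gaussian_smooth(robust_zscore(tr), sigma_s=cfg.smooth_sigma_s)
        events = detect_events(
            z,
            threshold_z=cfg.threshold_z,
            min_sep_s=cfg.min_sep_s,
            baseline_window_s=cfg.baseline_window_s,
        )
        all_events.extend(events)
        summaries.append(summarize_events(events, tr.duration_s, roi_id=tr.roi_id))
    return all_events, summaries


def dff_rolling_quantile(
    trace: Trace,
    window: int = 200,
    q: float = 0.08,
    mode: Literal["rolling", "global_min"] = "rolling",
    eps_frac: float = 1e-6,
) -> Tuple[Trace, np.ndarray]:
    """ΔF/F with a rolling-percentile baseline.

    F0(t) is the q-quantile of a centered ``window``-frame window
    (truncated at the boundaries); ``mode="global_min"`` collapses it to
    the scalar minimum of that rolling series.  Returns the ΔF/F trace and
    the baseline used.  Nonpositive F is floored at a small fraction of the
    trace maximum before the quantile (with no effect on positive traces).
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if window < 1 or window > trace.n:
        raise ValueError(f"window must lie in [1, T={trace.n}]")
    f = trace.values.copy()
    if np.any(f <= 0):
        floor = eps_frac * max(f.max(), 1.0)
        f = np.maximum(f, floor)
    f0 = (
        pd.Series(f).rolling(window, center=True, min_periods=1).quantile(q).to_numpy()
    )
    if mode == "global_min":
        f0 = np.full_like(f0, f0.min())
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 is nonpositive even after flooring")
    return replace(trace, values=(f - f0) / f0), f0


def neuro_peak_metrics(
    dff: Trace,
    peak: int,
    baseline_window_s: float = 10.0,
    prev_peak: Optional[int] = None,
    next_peak: Optional[int] = None,
) -> CalciumEvent:
    """Amplitude and half-width of decay of one ΔF/F transient.

    Amplitude as in :func:`event_metrics`; half-width of decay is the time
    from the peak to the first falling-side crossing of baseline +
    amplitude/2, flagged when the decay is truncated.
    """
    return event_metrics(
        dff, peak, baseline_window_s=baseline_window_s, prev_peak=prev_peak, next_peak=next_peak
    )
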