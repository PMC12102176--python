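"""Per-frame signal-to-background ratio and dendritic spine density.

SBR = mean intensity of a signal ROI over mean intensity of a background
ROI, computed per frame; multiplicatively scale-invariant, offset-variant.
Spine density = manual spine count / dendrite length (µm⁻¹); aggregation
reports the mean ± SEM over dendrites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import ImageStack, RoiLabelMask


@dataclass
class SbrMeasure:
    frame_index: int
    signal_mean: float
    background_mean: float
    sbr: float
    depth_um: Optional[float] = None


def sbr(
    frame: np.ndarray,
    rois: RoiLabelMask,
    signal_label: int = 1,
    background_label: int = 2,
    use_max_signal: bool = False,
    frame_index: int = 0,
    depth_um: Optional[float] = None,
) -> SbrMeasure:
    """Ratio of mean signal-ROI to mean background-ROI intensity.

    ``use_max_signal`` substitutes the ROI maximum for the mean in the
    numerator.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != rois.labels.shape:
        raise ValueError("frame and ROI mask shapes disagree")
    sig = rois.labels == signal_label
    bg = rois.labels == background_label
    if not sig.any() or not bg.any():
        raise ValueError("signal and background ROIs must be nonempty")
    if (sig & bg).any():  # cannot occur in a label mask; guards custom masks
        raise ValueError("signal and background ROIs overlap")
    s = float(frame[sig].max() if use_max_signal else frame[sig].mean())
    b = float(frame[bg].mean())
    if b <= 0:
        raise ValueError("background mean must be > 0")
    return SbrMeasure(
        frame_index=frame_index, signal_mean=s, background_mean=b, sbr=s / b, depth_um=depth_um
    )


def auto_rois(frame: np.ndarray, top_frac: float = 0.01, bottom_frac: float = 0.10) -> RoiLabelMask:
    """Percentile-based ROI stand-in for manual placement (synthetic tests
    only): label 1 = brightest ``top_frac`` of pixels, label 2 = dimmest
    ``bottom_frac``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    hi = np.quantile(frame, 1 - top_frac)
    lo = np.quantile(frame, bottom_frac)
    labels = np.zeros(frame.shape, dtype=np.int32)
    labels[frame >= hi] = 1
    labels[(frame <= lo) & (labels == 0)] = 2
    return RoiLabelMask(labels=labels)


def sbr_profile(
    stack: ImageStack,
    rois_per_frame: Sequence[RoiLabelMask] | RoiLabelMask,
    t: int = 0,
    c: int = 0,
    use_max_signal: bool = False,
) -> List[SbrMeasure]:
    """SBR for every z frame; depth_um = z index × z step when calibrated."""
    Z = stack.shape[1]
    z_step = stack.z_step
    out = []
    for z in range(Z):
        roi = rois_per_frame[z] if isinstance(rois_per_frame, (list, tuple)) else rois_per_frame
        out.append(
            sbr(
                stack.data[t, z, c],
                roi,
                use_max_signal=use_max_signal,
                frame_index=z,
                depth_um=z * z_step if z_step is not None else None,
            )
        )
    return out


def spine_density(n_spines: int, dendrite_length_um: float) -> float:
    """Spine count normalized by dendrite length, in µm⁻¹."""
    if dendrite_length_um <= 0:
        raise ValueError("dendrite length must be > 0")
    if n_spines < 0:
        raise ValueError("spine count must be >= 0")
    return n_spines / dendrite_length_um


def aggregate_spine_density(
    counts: Sequence[int], lengths_um: Sequence[float]
) -> Tuple[float, float, float]:
    """Mean, SEM of per-dendrite densities and total dendrite length."""
    if len(counts) != len(lengths_um) or not counts:
        raise ValueError("counts and lengths must be equal-length and nonempty")
    d = np.array([spine_density(n, ln) for n, ln in zip(counts, lengths_um)])
    sem = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
    return float(d.mean()), sem, float(np.sum(lengths_um))
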