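"""Shared image preprocessing: filtering, projection, equalization, binarization.

All operations are pure — inputs are never modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, morphology

from .io import ImageStack


@dataclass
class BinaryMap:
    """A binarized projection and the time index it came from."""

    mask: np.ndarray
    t_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("BinaryMap mask must be 2-D")


def median_filter_xy(stack: ImageStack, kernel: int = 3) -> ImageStack:
    """Median-filter each (t, z, c) plane with a kernel × kernel window.

    Borders use reflect padding. The default 3×3 window removes shot noise
    while preserving thin process edges.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return replace(stack, data=stack.data.copy())
    out = ndimage.median_filter(stack.data, size=(1, 1, 1, kernel, kernel), mode="reflect")
    return replace(stack, data=out)


def _check_tc(stack: ImageStack, t: int, c: int) -> None:
    T, Z, C = stack.shape[:3]
    if not (0 <= t < T):
        raise IndexError(f"time index {t} out of range [0, {T})")
    if not (0 <= c < C):
        raise IndexError(f"channel index {c} out of range [0, {C})")


def max_project_z(stack: ImageStack, t: int, c: int = 0) -> np.ndarray:
    """Maximum-intensity projection along z of one timepoint/channel."""
    _check_tc(stack, t, c)
    return stack.data[t, :, c].max(axis=0)


def avg_project_z(
    stack: ImageStack, t: int, c: int = 0, z_range: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Arithmetic-mean projection over the stated z planes (all by default)."""
    _check_tc(stack, t, c)
    Z = stack.shape[1]
    if z_range is None:
        z_range = range(Z)
    z_idx = list(z_range)
    if not z_idx:
        raise ValueError("z_range must be nonempty")
    if min(z_idx) < 0 or max(z_idx) >= Z:
        raise IndexError(f"z_range {z_idx} out of bounds for Z={Z}")
    return stack.data[t, z_idx, c].mean(axis=0)


def temporal_downsample(stack: ImageStack, factor: int = 3) -> ImageStack:
    """Average each block of ``factor`` consecutive frames into one.

    Trailing frames that do not fill a block are dropped; frame_interval is
    multiplied by the factor (e.g. 3 Hz acquisition → 1 Hz with factor 3).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(stack, data=stack.data.copy())
    T = stack.shape[0]
    if T < factor:
        raise ValueError(f"T={T} shorter than downsample factor {factor}")
    n = T // factor
    data = stack.data[: n * factor]
    out = data.reshape((n, factor) + data.shape[1:]).mean(axis=1)
    fi = stack.frame_interval * factor if stack.frame_interval else None
    return replace(stack, data=out, frame_interval=fi)


def clahe(
    image: np.ndarray, clip_limit: float = 0.01, tiles: Tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization onto [0, 1].

    The image is min–max normalized first, so the result is invariant to
    global affine intensity maps; a constant image is returned as zeros
    (no contrast to equalize).
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    img01 = (img - lo) / (hi - lo)
    ty, tx = tiles
    kernel = (max(1, int(np.ceil(img.shape[0] / ty))), max(1, int(np.ceil(img.shape[1] / tx))))
    return exposure.equalize_adapthist(img01, kernel_size=kernel, clip_limit=clip_limit)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> Tuple[float, BinaryMap]:
    """Otsu's threshold over an n_bins histogram; mask = image > threshold.

    The threshold maximizes between-class variance on the observed min–max
    range.  A constant image has no valid split and raises.
    """
    img = np.asarray(image)
    if img.min() == img.max():
        raise ValueError("Otsu threshold is undefined for a constant image")
    thr = filters.threshold_otsu(img, nbins=n_bins)
    return float(thr), BinaryMap(mask=img > thr)


def remove_small_blobs(bmap: BinaryMap, min_size: int = 100, connectivity: int = 8) -> BinaryMap:
    """Drop connected components smaller than ``min_size`` pixels.

    Components with exactly ``min_size`` pixels are kept ("less than"
    boundary).  8-connectivity by default so thin diagonal processes stay
    whole.  Idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    # max_size semantics remove components of area <= max_size, so the
    # "less than min_size" rule maps to max_size = min_size - 1
    out = morphology.remove_small_objects(bmap.mask, max_size=min_size - 1, connectivity=conn)
    return BinaryMap(mask=out, t_index=bmap.t_index)
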