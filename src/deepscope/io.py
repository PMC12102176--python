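"""Image-stack, ROI-mask, table and config I/O.

Axis convention, used everywhere in the package: intensity data are 5-D
``(T, Z, C, Y, X)`` with singleton axes allowed; y grows downward; all
indices are 0-based.  Stacks are exchanged as plain multi-page TIFF with
the axis order supplied by the caller — no OME metadata parsing.  Physical
calibration comes from the config when the file carries none, and
operations that need it fail loudly rather than assume 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig, load_config  # noqa: F401  (re-exported)

AXES = "TZCYX"


class StackIOError(ValueError):
    """Raised on malformed stacks, masks or axis specifications."""


@dataclass
class ImageStack:
    """A calibrated 5-D intensity grid ordered (T, Z, C, Y, X).

    Calibration fields are optional; pipelines that need one raise
    ``MissingCalibrationError`` when it is absent.
    """

    data: np.ndarray
    pixel_size_xy: Optional[float] = None
    z_step: Optional[float] = None
    frame_interval: Optional[float] = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise StackIOError(f"ImageStack data must be 5-D (T,Z,C,Y,X), got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape):
            raise StackIOError("all five extents must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise StackIOError("intensities must be finite")
        if np.any(self.data < 0):
            raise StackIOError("intensities must be >= 0")
        if self.pixel_size_xy is not None and self.pixel_size_xy <= 0:
            raise StackIOError("pixel_size_xy must be > 0")
        if self.shape[0] > 1 and self.frame_interval is not None and self.frame_interval <= 0:
            raise StackIOError("frame_interval must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{c}" for c in range(self.shape[2])]

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.shape[0]

    def require_frame_interval(self) -> float:
        if self.frame_interval is None:
            raise MissingCalibrationError("frame_interval (s) is required but not set")
        return self.frame_interval

    def require_z_step(self) -> float:
        if self.z_step is None:
            raise MissingCalibrationError("z_step (µm) is required but not set")
        return self.z_step


class MissingCalibrationError(ValueError):
    pass


@dataclass
class RoiLabelMask:
    """2-D integer label image: 0 = background, k >= 1 = ROI k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise StackIOError("ROI mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise StackIOError("ROI mask must be integer-typed")
        if self.labels.min() < 0:
            raise StackIOError("ROI labels must be nonnegative")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    def roi_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


def _expand_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper()
    if len(set(axes)) != len(axes):
        raise StackIOError(f"axes spec {axes!r} names an axis twice")
    if any(a not in AXES for a in axes):
        raise StackIOError(f"axes spec {axes!r} contains letters outside {AXES}")
    if arr.ndim != len(axes):
        raise StackIOError(
            f"axes spec {axes!r} has {len(axes)} axes but file data are {arr.ndim}-D"
        )
    # insert missing axes as singletons, then order as TZCYX
    for a in AXES:
        if a not in axes:
            arr = arr[..., np.newaxis]
            axes = axes + a
    order = [axes.index(a) for a in AXES]
    return np.transpose(arr, order)


def read_stack(
    path: str | Path,
    axes: str,
    *,
    pixel_size_xy: Optional[float] = None,
    z_step: Optional[float] = None,
    frame_interval: Optional[float] = None,
    channel_names: Optional[Sequence[str]] = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    ``axes`` names each dimension of the file once (e.g. ``"TYX"``); missing
    axes become singletons.  Calibration keywords override absent file
    metadata — the file's own tags are deliberately not interpreted.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc
    data = _expand_axes(np.asarray(arr), axes)
    return ImageStack(
        data=data,
        pixel_size_xy=pixel_size_xy,
        z_step=z_step,
        frame_interval=frame_interval,
        channel_names=list(channel_names) if channel_names else [],
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the full 5-D array as a plain TIFF; round-trips with axes "TZCYX"."""
    tifffile.imwrite(str(path), stack.data)


def read_roi_mask(path: str | Path, *, relabel_gaps: bool = False) -> RoiLabelMask:
    """Read an integer label-mask TIFF.

    Label sets with gaps (e.g. {0, 2}) are rejected unless ``relabel_gaps``
    is set, in which case labels are compacted to 1..n preserving order.
    """
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise StackIOError("ROI mask file must contain a single 2-D page")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise StackIOError("ROI mask must contain integer labels")
    if arr.min() < 0:
        raise StackIOError("ROI labels must be nonnegative")
    present = set(int(v) for v in np.unique(arr) if v > 0)
    expected = set(range(1, (max(present) + 1) if present else 1))
    if present != expected:
        if not relabel_gaps:
            raise StackIOError(
                f"ROI labels have gaps: present {sorted(present)}; "
                "pass relabel_gaps=True to compact"
            )
        out = np.zeros_like(arr)
        for new, old in enumerate(sorted(present), start=1):
            out[arr == old] = new
        arr = out
    return RoiLabelMask(labels=arr)


def write_roi_mask(mask: RoiLabelMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.int32))


def write_table(records: Sequence[dict], path: str | Path, *, schema: Optional[Sequence[str]] = None) -> None:
    """Write keyed rows as a UTF-8 CSV with header and '.' decimal separator.

    All rows must share one key set.  An empty list needs a declared
    ``schema`` to produce a header-only file.  Floats round-trip to 1e-9
    relative (full repr is written).
    """
    records = list(records)
    if not records:
        if schema is None:
            raise ValueError("empty record list requires a declared schema")
        pd.DataFrame(columns=list(schema)).to_csv(path, index=False, encoding="utf-8")
        return
    keys = list(records[0].keys())
    for i, r in enumerate(records):
        if list(r.keys()) != keys:
            raise ValueError(f"row {i} keys {list(r.keys())} differ from header {keys}")
    pd.DataFrame.from_records(records, columns=keys).to_csv(
        path, index=False, encoding="utf-8", float_format="%.12g"
    )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
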