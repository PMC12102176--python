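"""Drosophila Kenyon-cell odor-response classification.

Per cell and channel, F0 is the mean of the 17 frames before the first
odor delivery and dF/F0 = (F − F0)/F0.  Axial-motion artifacts common to
both channels are removed by subtracting the nuclear-mCherry dF/F0 from
the GCaMP dF/F0.  A cell is responsive to an odor only if, in every one of
the three trials, its corrected dF/F0 within 10 frames after odor release
exceeds the baseline mean by 2 standard deviations of the pre-stimulus
corrected baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np


@dataclass
class OdorTrial:
    odor_id: str
    onset_frame: int
    trial_index: int  # 1..3


@dataclass
class ResponderCall:
    cell_id: int
    odor_id: str
    peak_dff: List[float]
    passed: List[bool]
    responsive: bool


def baseline_f0(values: np.ndarray, first_onset: int, n_pre: int = 17) -> float:
    """Mean of the n_pre frames immediately preceding the first odor onset."""
    values = np.asarray(values, dtype=np.float64)
    if first_onset < n_pre:
        raise ValueError(
            f"need {n_pre} pre-stimulus frames, first onset is at frame {first_onset}"
        )
    return float(values[first_onset - n_pre: first_onset].mean())


def dff(values: np.ndarray, f0: float) -> np.ndarray:
    """(F − F0) / F0, elementwise."""
    if f0 <= 0:
        raise ValueError("F0 must be > 0")
    return (np.asarray(values, dtype=np.float64) - f0) / f0


def motion_correct(
    gcamp_dff: np.ndarray,
    mcherry_dff: np.ndarray,
    mode: Literal["subtract", "scaled"] = "subtract",
    baseline_n: Optional[int] = None,
) -> np.ndarray:
    """Remove the common-mode motion artifact using the mCherry channel.

    ``subtract`` (default): corrected = gcamp_dff − mcherry_dff, treating
    the artifact as common-mode in dF/F0 units.  ``scaled``: a gain β is
    fitted on the pre-stimulus baseline (least squares) before
    subtraction, for sessions where the channels see the artifact with
    different strength.
    """
    g = np.asarray(gcamp_dff, dtype=np.float64)
    m = np.asarray(mcherry_dff, dtype=np.float64)
    if g.shape != m.shape:
        raise ValueError("channel traces must have equal length")
    if mode == "subtract":
        return g - m
    seg = slice(0, baseline_n) if baseline_n else slice(None)
    ms, gs = m[seg], g[seg]
    var = np.sum((ms - ms.mean()) ** 2)
    beta = 0.0 if var == 0 else float(np.sum((ms - ms.mean()) * (gs - gs.mean())) / var)
    return g - beta * m


def classify_responder(
    corrected: np.ndarray,
    trials: Sequence[OdorTrial],
    window: int = 10,
    k: float = 2.0,
    cell_id: int = 0,
) -> ResponderCall:
    """All-three-trials responder rule for one cell and one odor.

    The threshold is baseline mean + k·STD, both computed on the corrected
    trace before the first odor onset of the session; a trial passes iff
    the maximum corrected dF/F0 in the ``window`` frames after its onset
    exceeds it.  The conjunction over the three trials suppresses
    single-trial false positives.
    """
    corrected = np.asarray(corrected, dtype=np.float64)
    trials = sorted(trials, key=lambda t: t.trial_index)
    if len(trials) != 3:
        raise ValueError(f"expected 3 trials, got {len(trials)}")
    onsets = [t.onset_frame for t in trials]
    if sorted(onsets) != onsets or len(set(onsets)) != 3:
        raise ValueError("trial onsets must be strictly increasing")
    first = onsets[0]
    if first < 2:
        raise ValueError("no pre-stimulus baseline before the first onset")
    base = corrected[:first]
    thresh = float(base.mean() + k * base.std(ddof=1))
    peaks: List[float] = []
    passed: List[bool] = []
    for t in trials:
        seg = corrected[t.onset_frame + 1: t.onset_frame + 1 + window]
        if seg.size == 0:
            raise ValueError(f"trial {t.trial_index} window is empty")
        pk = float(seg.max())
        peaks.append(pk)
        passed.append(pk > thresh)
    return ResponderCall(
        cell_id=cell_id,
        odor_id=trials[0].odor_id,
        peak_dff=peaks,
        passed=passed,
        responsive=all(passed),
    )


def fly_pipeline(
    gcamp: np.ndarray,
    mcherry: np.ndarray,
    trials: Sequence[OdorTrial],
    n_pre: int = 17,
    window: int = 10,
    k: float = 2.0,
    correction: Literal["subtract", "scaled"] = "subtract",
    cell_id: int = 0,
) -> List[ResponderCall]:
    """Raw two-channel traces → per-odor responder calls for one cell."""
    onsets = sorted(t.onset_frame for t in trials)
    first = onsets[0]
    g_dff = dff(gcamp, baseline_f0(gcamp, first, n_pre))
    m_dff = dff(mcherry, baseline_f0(mcherry, first, n_pre))
    corrected = motion_correct(g_dff, m_dff, mode=correction, baseline_n=first)
    calls = []
    odors = sorted({t.odor_id for t in trials})
    for odor in odors:
        sub = [t for t in trials if t.odor_id == odor]
        calls.append(classify_responder(corrected, sub, window=window, k=k, cell_id=cell_id))
    return calls
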