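"""Seeded synthetic-data generators with ground truth for every pipeline.

Each generator is a pure function of its config (seed included): rerunning
with the same config is bit-identical.  Truth summaries (pixel fractions,
event times, responder labels, SBR profiles) are derived from the
generated ground truth itself, never from the rendered images.

The imaging model shared by the image generators is the standard
microscopy one: a clean intensity field is blurred by a Gaussian PSF and
corrupted by Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage, optimize

from .fly import OdorTrial
from .io import ImageStack, RoiLabelMask

# ---------------------------------------------------------------------------
# configs


@dataclass
class SyntheticMotilityConfig:
    """A microglia-like cell: stable arbor, motile terminal fine processes.

    The soma and primary branches persist for the whole session (as in
    vivo, where only the terminal fine processes remodel on a minutes
    scale).  ``p_gain``/``p_loss`` are the target per-interval gained/lost
    pixel fractions (defaults match the reported in vivo day-0 fractions);
    the generator retracts and grows terminal segments until the rendered
    pixel masses hit those targets, so the truth-mask fractions hold by
    construction.
    """

    seed: int
    image_size: int = 256
    n_z: int = 2
    n_timepoints: int = 7
    n_branches: int = 8
    branch_len: int = 30
    n_terminals_per_branch: int = 3
    terminal_len: int = 20
    dilate_radius: int = 2
    soma_radius: int = 6
    p_gain: float = 0.27
    p_loss: float = 0.28
    jitter_px: float = 0.3
    psf_sigma_px: float = 1.0
    background: float = 20.0
    amplitude: float = 200.0
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    frame_interval_s: float = 600.0  # 10-min cadence over a 30-min session
    pixel_size_um: float = 0.16


@dataclass
class SyntheticCalciumConfig:
    """Fluorescence traces with transients over a drifting baseline.

    Kernel amplitude/decay defaults sit near the reported neuronal
    transient statistics (mean amplitude 4.95 %ΔF/F, decay half-width
    3.24 s → tau = 3.24/ln 2 s); the default event rate of 0.5/min is a
    sparse spontaneous-transient regime.
    """

    seed: int
    n_rois: int = 5
    duration_s: float = 600.0
    fs: float = 1.0
    event_rate_per_min: float = 0.5
    amplitude_mean: float = 4.95
    amplitude_sd: float = 0.0
    amplitude_min: float = 1.0
    tau_decay_s: float = 3.24 / np.log(2)
    tau_rise_s: float = 0.3
    baseline: float = 100.0
    drift_frac: float = 0.0  # linear baseline drift over the recording
    noise_sd: float = 0.5  # in trace units (baseline is 100)


@dataclass
class SyntheticFlyConfig:
    """Two-channel Kenyon-cell traces sharing a common motion artifact."""

    seed: int
    n_cells: int = 20
    n_responders: int = 5
    n_partial: int = 2  # respond in only 2 of 3 trials
    n_pre: int = 60  # frames before the first onset (≥ the 17-frame F0)
    inter_trial: int = 45
    n_trials: int = 3
    odor_id: str = "OCT"
    response_amp: float = 0.30  # relative dF/F0 response amplitude
    response_len: int = 8
    artifact_sd: float = 0.03  # common-mode motion artifact (relative)
    artifact_smooth: float = 5.0
    noise_sd: float = 0.01  # per-channel independent noise (relative)
    noise_smooth: float = 1.5  # frames; indicator kinetics make noise temporally smooth
    gcamp_f0: float = 100.0
    mcherry_f0: float = 200.0


@dataclass
class SyntheticDepthConfig:
    """z-stack with exponential depth attenuation over a constant floor."""

    seed: int
    image_size: int = 64
    n_z: int = 30
    z_step_um: float = 10.0
    attenuation_um: float = 300.0
    amplitude: float = 200.0
    background: float = 20.0
    noise_sd: float = 1.0
    disk_radius: int = 10


@dataclass
class SyntheticShiftConfig:
    """Band-limited textured pair with a known subpixel shift."""

    seed: int
    image_size: int = 64
    dy: float = 0.5
    dx: float = 0.25
    texture_sigma: float = 2.0
    snr: float = 10.0


# ---------------------------------------------------------------------------
# microglia time lapse


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r: r + 1, -r: r + 1]
    return (y * y + x * x) <= r * r


def _walk(
    rng: np.random.Generator, start: Tuple[float, float], direction: float, n_steps: int, size: int
) -> np.ndarray:
    """Rasterized wiggly random walk; returns (n, 2) integer pixel coords."""
    pts = []
    y, x = start
    ang = direction
    for _ in range(n_steps):
        ang += rng.normal(0, 0.35)
        y += np.sin(ang)
        x += np.cos(ang)
        yi, xi = int(round(y)), int(round(x))
        if 1 <= yi < size - 1 and 1 <= xi < size - 1:
            pts.append((yi, xi))
    return np.array(pts, dtype=int).reshape(-1, 2)


@dataclass
class _Process:
    pixels: np.ndarray  # (n, 2) skeleton coords
    z: int


def _stamp(pixels: np.ndarray, size: int, dilate: int) -> np.ndarray:
    """Dilated boolean mask of one skeleton's pixels."""
    m = np.zeros((size, size), dtype=bool)
    if len(pixels):
        m[pixels[:, 0], pixels[:, 1]] = True
        if dilate > 0:
            m = ndimage.binary_dilation(m, structure=_disk(dilate))
    return m


def _render_mask(
    soma: np.ndarray, processes: List[_Process], size: int, dilate: int
) -> np.ndarray:
    mask = soma.copy()
    for p in processes:
        mask[p.pixels[:, 0], p.pixels[:, 1]] = True
    if dilate > 0:
        mask = ndimage.binary_dilation(mask, structure=_disk(dilate))
    return mask


@dataclass
class MotilityTruth:
    masks: List[np.ndarray]  # clean structure mask per timepoint
    gained: List[np.ndarray]
    lost: List[np.ndarray]
    frac_stable: List[float]
    frac_gained: List[float]
    frac_lost: List[float]
    tor: List[float]
    jitters: List[Tuple[float, float]]

    @property
    def mean_tor(self) -> float:
        return float(np.mean(self.tor))

    @property
    def mean_fracs(self) -> Tuple[float, float, float]:
        return (
            float(np.mean(self.frac_stable)),
            float(np.mean(self.frac_gained)),
            float(np.mean(self.frac_lost)),
        )


def gen_microglia_timelapse(cfg: SyntheticMotilityConfig) -> Tuple[ImageStack, MotilityTruth]:
    """Render a motile branched cell as a (T, Z, 1, Y, X) stack plus truth.

    The stable core (soma + primary branches) persists; the branches carry
    motile terminal segments.  Per interval, random terminals are retracted
    and new ones grown (preferring fresh territory) until the pixels lost
    from and gained by the union mask reach p_loss·D and p_gain·D with
    D = |B₀|/(1−p_gain), making the truth gained/lost pixel fractions equal
    ``p_gain``/``p_loss`` up to segment-size granularity.  Frames after the
    first get a subpixel translation jitter; all frames get PSF blur and
    Poisson-Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    cy, cx = size / 2 + rng.uniform(-5, 5), size / 2 + rng.uniform(-5, 5)
    soma = np.zeros((size, size), dtype=bool)
    sy, sx = np.nonzero(_disk(cfg.soma_radius))
    soma[sy + int(cy) - cfg.soma_radius, sx + int(cx) - cfg.soma_radius] = True

    # stable primary branches, evenly fanned with angular jitter
    branches: List[_Process] = []
    tip_info: List[Tuple[Tuple[float, float], float]] = []  # (tip coords, direction)
    for b in range(cfg.n_branches):
        ang = 2 * np.pi * b / cfg.n_branches + rng.normal(0, 0.2)
        start = (cy + cfg.soma_radius * np.sin(ang), cx + cfg.soma_radius * np.cos(ang))
        px = _walk(rng, start, ang, cfg.branch_len, size)
        if len(px) == 0:
            continue
        branches.append(_Process(pixels=px, z=int(rng.integers(cfg.n_z))))
        tip_info.append(((float(px[-1, 0]), float(px[-1, 1])), ang))
    if not branches:
        raise ValueError("degenerate geometry: no branches rendered")

    def new_terminal() -> _Process:
        # anchor anywhere on the distal half of a branch, heading outward
        # with a wide angular spread, so terminals rarely overlap each other
        b = int(rng.integers(len(branches)))
        skel = branches[b].pixels
        anchor = skel[int(rng.integers(len(skel) // 2, len(skel)))]
        ang = tip_info[b][1] + rng.normal(0, 1.0)
        n = max(5, int(rng.normal(cfg.terminal_len, cfg.terminal_len * 0.2)))
        return _Process(
            pixels=_walk(rng, (float(anchor[0]), float(anchor[1])), ang, n, size),
            z=int(rng.integers(cfg.n_z)),
        )

    terminals = [
        new_terminal() for _ in range(cfg.n_branches * cfg.n_terminals_per_branch)
    ]

    def render(procs: List[_Process]) -> np.ndarray:
        return _render_mask(soma, branches + procs, size, cfg.dilate_radius)

    core_px = int(_render_mask(soma, branches, size, cfg.dilate_radius).sum())
    masks, frames, jitters = [], [], []
    for t in range(cfg.n_timepoints):
        if t > 0:
            if not terminals:
                raise ValueError("degenerate geometry: no terminal pixels")
            # program the pixel fractions directly: with all gained pixels
            # novel, the interval denominator is D = |B0|/(1−p_gain), so
            # the loss/gain pixel targets are p_loss·D and p_gain·D
            b0 = render(terminals)
            mass0 = int(b0.sum())
            denom = mass0 / (1.0 - cfg.p_gain)
            lost_target = cfg.p_loss * denom
            gained_target = cfg.p_gain * denom
            # retract random terminals and grow new ones until the pixels
            # actually lost from / gained by the union mask hit both
            # targets — measured against the final next-frame mask, so
            # overlap and reclamation are fully accounted for
            core_mask = _render_mask(soma, branches, size, cfg.dilate_radius)
            survivors = list(terminals)
            surv_masks = [_stamp(p.pixels, size, cfg.dilate_radius) for p in survivors]
            births: List[_Process] = []
            birth_masks: List[np.ndarray] = []
            for _ in range(300):
                b1 = core_mask.copy()
                for m in surv_masks + birth_masks:
                    b1 |= m
                lost_px = int((b0 & ~b1).sum())
                gained_px = int((b1 & ~b0).sum())
                need_loss = lost_px < lost_target and len(survivors) > 0
                need_gain = gained_px < gained_target
                if not need_loss and not need_gain:
                    break
                if need_loss:
                    i = int(rng.integers(len(survivors)))
                    survivors.pop(i)
                    surv_masks.pop(i)
                if need_gain:
                    # grow into fresh territory: prefer candidates that do
                    # not overlay pixels of the previous frame (otherwise
                    # they silently reclaim just-lost territory)
                    best_nt, best_m, best_ov = None, None, np.inf
                    for _ in range(8):
                        nt = new_terminal()
                        nm = _stamp(nt.pixels, size, cfg.dilate_radius)
                        area = max(1, int(nm.sum()))
                        ov = int((nm & b0).sum()) / area
                        if ov < best_ov:
                            best_nt, best_m, best_ov = nt, nm, ov
                        if ov < 0.15:
                            break
                    births.append(best_nt)
                    birth_masks.append(best_m)
            terminals = survivors + births
        mask = render(terminals)
        masks.append(mask)
        planes = np.zeros((cfg.n_z, size, size))
        for z in range(cfg.n_z):
            zmask = soma.copy()
            for p in branches + terminals:
                if p.z == z:
                    zmask[p.pixels[:, 0], p.pixels[:, 1]] = True
            zmask = ndimage.binary_dilation(zmask, structure=_disk(cfg.dilate_radius))
            planes[z] = cfg.background + cfg.amplitude * zmask
        jitter = (0.0, 0.0)
        if t > 0 and cfg.jitter_px > 0:
            jitter = tuple(rng.uniform(-cfg.jitter_px, cfg.jitter_px, size=2))
            planes = np.stack(
                [
                    ndimage.shift(pl, jitter, order=1, mode="nearest", prefilter=False)
                    for pl in planes
                ]
            )
        jitters.append((float(jitter[0]), float(jitter[1])))
        if cfg.psf_sigma_px > 0:
            planes = ndimage.gaussian_filter(planes, (0, cfg.psf_sigma_px, cfg.psf_sigma_px))
        noisy = rng.poisson(np.maximum(planes * cfg.photon_scale, 0)) / cfg.photon_scale
        noisy = noisy + rng.normal(0, cfg.read_noise_sd, size=planes.shape)
        frames.append(np.maximum(noisy, 0.0))

    gained, lost = [], []
    fs_, fg_, fl_, tor_ = [], [], [], []
    for i in range(cfg.n_timepoints - 1):
        b0, b1 = masks[i], masks[i + 1]
        g, l, s = b1 & ~b0, b0 & ~b1, b0 & b1
        gained.append(g)
        lost.append(l)
        tot = int(g.sum() + l.sum() + s.sum())
        fs_.append(s.sum() / tot)
        fg_.append(g.sum() / tot)
        fl_.append(l.sum() / tot)
        tor_.append((g.sum() + l.sum()) / tot)
    stack = ImageStack(
        data=np.stack(frames)[:, :, np.newaxis],
        pixel_size_xy=cfg.pixel_size_um,
        frame_interval=cfg.frame_interval_s,
        z_step=3.0,
    )
    truth = MotilityTruth(
        masks=masks,
        gained=gained,
        lost=lost,
        frac_stable=[float(v) for v in fs_],
        frac_gained=[float(v) for v in fg_],
        frac_lost=[float(v) for v in fl_],
        tor=[float(v) for v in tor_],
        jitters=jitters,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# calcium traces


def _event_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential transient, normalized to unit peak."""
    tp = np.maximum(t, 0.0)
    k = np.where(t >= 0, np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise), 0.0)
    t_pk = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    pk = np.exp(-t_pk / tau_decay) - np.exp(-t_pk / tau_rise)
    return k / pk


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def kernel_fdhm(tau_rise: float, tau_decay: float) -> float:
    """Full duration at half maximum of the unit-peak kernel (closed form
    via root finding on the analytic expression)."""
    t_pk = kernel_peak_time(tau_rise, tau_decay)

    def f(t: float) -> float:
        k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
        pk = np.exp(-t_pk / tau_decay) - np.exp(-t_pk / tau_rise)
        return k / pk - 0.5

    left = optimize.brentq(f, 0.0, t_pk)
    hi = t_pk
    while f(hi) > 0:
        hi *= 2
    right = optimize.brentq(f, t_pk, hi)
    return float(right - left)


@dataclass
class CalciumTruth:
    events: List[Dict]  # per ROI: {"times": s, "amplitudes": trace units}
    baseline: List[np.ndarray]  # drifting F0 per ROI
    fdhm_s: float  # analytic FDHM of the (unit) kernel
    half_width_decay_s: float  # analytic decay half-width of the kernel


def gen_calcium_traces(cfg: SyntheticCalciumConfig) -> Tuple[List[np.ndarray], CalciumTruth]:
    """Poisson event times convolved with a double-exponential kernel over
    a drifting baseline, plus Gaussian noise.  Returns raw F traces and the
    generative ground truth (event times/amplitudes, baseline, analytic
    kernel widths).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    t_pk = kernel_peak_time(cfg.tau_rise_s, cfg.tau_decay_s)
    traces, truth_events, baselines = [], [], []
    for _ in range(cfg.n_rois):
        f0 = cfg.baseline * (1.0 + cfg.drift_frac * t / cfg.duration_s)
        n_ev = rng.poisson(cfg.event_rate_per_min * cfg.duration_s / 60.0)
        onsets = np.sort(rng.uniform(0, cfg.duration_s - 4 * cfg.tau_decay_s, size=n_ev))
        amps = np.maximum(
            rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, size=n_ev), cfg.amplitude_min
        )
        sig = np.zeros(n)
        for t0, a in zip(onsets, amps):
            sig += a * _event_kernel(t - t0, cfg.tau_rise_s, cfg.tau_decay_s)
        trace = f0 + sig + rng.normal(0, cfg.noise_sd, size=n)
        traces.append(trace)
        truth_events.append(
            {"times": onsets + t_pk, "onsets": onsets, "amplitudes": amps}
        )
        baselines.append(f0)
    # decay half-width: time from unit peak down to 1/2 on the falling side
    fdhm = kernel_fdhm(cfg.tau_rise_s, cfg.tau_decay_s)

    def _fall(tt: float) -> float:
        k = _event_kernel(np.array([tt]), cfg.tau_rise_s, cfg.tau_decay_s)[0]
        return k - 0.5

    hi = t_pk
    while _fall(hi) > 0:
        hi *= 2
    hwd = float(optimize.brentq(_fall, t_pk, hi) - t_pk)
    truth = CalciumTruth(
        events=truth_events, baseline=baselines, fdhm_s=float(fdhm), half_width_decay_s=hwd
    )
    return traces, truth


# ---------------------------------------------------------------------------
# fly recording


@dataclass
class FlyTruth:
    labels: List[str]  # per cell: "responder" | "partial" | "noise"
    responsive: List[bool]


def gen_fly_recording(
    cfg: SyntheticFlyConfig,
) -> Tuple[List[np.ndarray], List[np.ndarray], List[OdorTrial], FlyTruth]:
    """Two-channel traces with a shared motion artifact and odor-locked
    GCaMP responses for designated responder cells.

    Responders respond in all trials, "partial" cells in all but the last,
    the rest carry artifact and noise only.  Returns (gcamp, mcherry)
    traces per cell, the trial table and truth labels.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_responders + cfg.n_partial > cfg.n_cells:
        raise ValueError("responder counts exceed n_cells")
    onsets = [cfg.n_pre + i * cfg.inter_trial for i in range(cfg.n_trials)]
    n = onsets[-1] + cfg.inter_trial
    trials = [
        OdorTrial(odor_id=cfg.odor_id, onset_frame=o, trial_index=i + 1)
        for i, o in enumerate(onsets)
    ]
    resp_kernel = np.exp(-np.arange(cfg.response_len) / (cfg.response_len / 3.0))
    labels, responsive, gcamps, mcherries = [], [], [], []
    for c in range(cfg.n_cells):
        if c < cfg.n_responders:
            lab, resp_trials = "responder", list(range(cfg.n_trials))
        elif c < cfg.n_responders + cfg.n_partial:
            lab, resp_trials = "partial", list(range(cfg.n_trials - 1))
        else:
            lab, resp_trials = "noise", []
        artifact = ndimage.gaussian_filter1d(
            rng.normal(0, 1, size=n), cfg.artifact_smooth, mode="reflect"
        )
        artifact *= cfg.artifact_sd / max(artifact.std(), 1e-12)
        resp = np.zeros(n)
        for ti in resp_trials:
            o = onsets[ti] + 2  # response peaks a couple of frames after release
            seg = resp_kernel[: n - o]
            resp[o: o + seg.size] += cfg.response_amp * seg
        def channel_noise() -> np.ndarray:
            raw = rng.normal(0, 1, size=n)
            if cfg.noise_smooth > 0:
                raw = ndimage.gaussian_filter1d(raw, cfg.noise_smooth, mode="reflect")
                raw /= max(raw.std(), 1e-12)
            return cfg.noise_sd * raw

        g = cfg.gcamp_f0 * (1 + artifact + resp + channel_noise())
        m = cfg.mcherry_f0 * (1 + artifact + channel_noise())
        labels.append(lab)
        responsive.append(lab == "responder")
        gcamps.append(g)
        mcherries.append(m)
    return gcamps, mcherries, trials, FlyTruth(labels=labels, responsive=responsive)


# ---------------------------------------------------------------------------
# depth stack


@dataclass
class DepthTruth:
    sbr: List[float]
    rois: RoiLabelMask


def gen_depth_stack(cfg: SyntheticDepthConfig) -> Tuple[ImageStack, DepthTruth]:
    """Constant-brightness structure attenuated as exp(−depth/ℓ) over a
    constant background floor; truth SBR per frame from the generative
    parameters.  Label 1 marks the structure ROI, label 2 a background
    corner ROI.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    yy, xx = np.ogrid[:size, :size]
    disk = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) <= cfg.disk_radius**2
    labels = np.zeros((size, size), dtype=np.int32)
    labels[disk] = 1
    labels[: size // 4, : size // 4] = 2
    planes, truth_sbr = [], []
    for z in range(cfg.n_z):
        depth = z * cfg.z_step_um
        a = cfg.amplitude * np.exp(-depth / cfg.attenuation_um)
        clean = cfg.background + a * disk
        truth_sbr.append(float((cfg.background + a) / cfg.background))
        planes.append(np.maximum(clean + rng.normal(0, cfg.noise_sd, size=clean.shape), 0.0))
    stack = ImageStack(
        data=np.stack(planes)[np.newaxis, :, np.newaxis], z_step=cfg.z_step_um
    )
    return stack, DepthTruth(sbr=truth_sbr, rois=RoiLabelMask(labels=labels))


# ---------------------------------------------------------------------------
# shifted pair


def gen_shifted_pair(cfg: SyntheticShiftConfig) -> Tuple[np.ndarray, np.ndarray, Tuple[float, float]]:
    """Band-limited tapered texture and a bilinear-shifted noisy copy.

    Noise SD is set so (texture SD)/(noise SD) = cfg.snr.  Returns
    (reference, moving, (dy, dx)).
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    tex = ndimage.gaussian_filter(rng.normal(size=(size, size)), cfg.texture_sigma)
    w = np.hanning(size)
    tex = tex * w[:, None] * w[None, :]
    tex /= max(tex.std(), 1e-12)
    moving = ndimage.shift(tex, (cfg.dy, cfg.dx), order=1, mode="constant", prefilter=False)
    noise_sd = 1.0 / cfg.snr
    ref = tex + rng.normal(0, noise_sd, size=tex.shape)
    mov = moving + rng.normal(0, noise_sd, size=tex.shape)
    return ref, mov, (cfg.dy, cfg.dx)
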