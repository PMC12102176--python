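# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Conventions

All image data are 5-D `(T, Z, C, Y, X)`; y grows downward; indices are
0-based.  Stacks are plain multi-page TIFF with caller-supplied axis
order — no OME metadata is interpreted, because exported frame sequences
rarely carry reliable tags.  Physical calibration (µm/px, s/frame, µm/z)
comes from the run config when absent from the file; operations that need
it raise rather than assume 1.0.

## Microglial process motility

Pipeline per session: 3×3 median filter per plane → maximum-intensity
z-projection per timepoint → rigid registration of the projection series
→ CLAHE → Otsu threshold → removal of connected components under 100 px
→ ΔB classification per consecutive pair → turnover rate.

**ΔB map.** ΔB = 2·B(tᵢ) − B(tᵢ₊₁) with true=1/false=0, giving stable=1,
gained=−1, lost=2, background=0.  The subtrahend order matters: the
alternative 2·B(tᵢ₊₁) − B(tᵢ) swaps the gained/lost codes and is
rejected (a unit test documents this).  TOR = (N_g+N_l)/(N_s+N_g+N_l);
the session statistic is the arithmetic mean over intervals.  N_s+N_g+N_l
equals |B(tᵢ) ∪ B(tᵢ₊₁)| exactly — asserted as an invariant.

**Registration.** The series is registered to the first frame (chained
pairwise registration accumulates drift; "previous" remains an option).
Within `register_series` the cross-correlation uses a whitened
(phase-normalized) spectrum: consecutive motility timepoints differ not
only by displacement but by genuine structural change, and plain
cross-correlation can lock onto a false peak produced by remodeled
processes, while the whitened peak stays on the common structure.  For
pairs that differ only by noise, plain mean-subtracted cross-correlation
is more precise and is the default of `estimate_shift_xcorr` (subpixel
accuracy ≤ 0.1 px at SNR 10, upsample 10).  A translation-only
Lucas-Kanade solver (iterated 2×2 normal equations on reference
gradients, interior pixels only, tolerance 0.01 px) is provided for
calcium-movie and spine-stack stabilization and agrees with
cross-correlation within 0.2 px on smooth images.

Classification is restricted to the maximal rectangle covered by every
aligned frame, so border fill can never be scored as gained or lost.
All-background intervals have an undefined TOR and are flagged and
excluded from the mean rather than counted as zero, which would bias it.

**Binarization guard.** Otsu always produces a split, even on a frame of
pure noise, where it halves the noise distribution; the resulting
half-density mask percolates (8-connectivity) into components far larger
than the 100-px filter.  A frame is therefore declared structureless —
empty mask — unless the candidate foreground's median exceeds the
background median by at least `snr_floor` (default 4) robust background
spreads on the raw projection.  Structured frames at the SNRs of interest
exceed this by an order of magnitude.

**Open choices.** CLAHE clip limit 0.01 on an 8×8 tile grid (common
defaults; configurable).  Otsu uses 256 bins on the observed min–max
range.  8-connectivity keeps thin diagonal processes whole.  Fractions
are averaged per interval; a pooled-pixel mode is available.  When a ROI
label mask is supplied, counts are restricted to its nonzero pixels.

## Calcium events

**Astrocyte branch.** Movies are temporally downsampled by 3× frame
averaging (3 Hz → 1 Hz; remainder frames dropped).  Microdomain ROIs can
be supplied as label masks; the built-in proposer (temporal-SD map →
Gaussian smooth → Otsu → area-filtered components) is a transparent
stand-in for manual/macro selection.  Per-ROI mean traces are normalized
as z = (x − median)/(1.4826·MAD) over the whole series — the standard
robust location-scale estimate, exact for normal noise — then smoothed
with a Gaussian of σ = 1 s.  Local maxima at or above the hard threshold
(default 3, in the trace's pre-smoothing robust units) become events; the
minimum inter-peak separation should be set on the order of the event
width (1 s default for narrow transients; 8 s in the wide-microdomain
tests).  Plateaus contribute their first index; endpoints are never
peaks.

**Event metrics.** Baseline = median of the `baseline_window` (default
10 s) preceding event onset, where onset is the last sub-half-maximum
sample before the peak (one refinement pass).  Amplitude = peak −
baseline.  FDHM = time between the two crossings of baseline +
amplitude/2 flanking the peak, linearly interpolated between samples;
when a crossing is not found before an adjacent peak or the trace
boundary the FDHM is flagged undefined and excluded from summaries
(frequency still counts the event).  Closed forms are matched within one
sample interval: Gaussian σ → FDHM 2σ√(2 ln 2); exponential decay τ →
decay half-width τ·ln 2; triangles exact.

**Neuronal branch.** F₀(t) is the 0.08-quantile of a centered 200-frame
rolling window (truncated at the boundaries); ΔF/F = (F − F₀)/F₀.  The
phrase "minimum 8th quantile of a rolling window" admits a second
reading — a global scalar, the minimum of the rolling-quantile series —
shipped as `baseline_mode="global_min"`.  The time-varying form is the
default because it is the one that tracks slow drift.  Peak amplitude
and half-width of decay (peak to the falling-side half-amplitude
crossing) reuse the event-metric machinery.

## Odor-responder classification

F₀ per channel = mean of the 17 frames before the first odor delivery;
dF/F₀ = (F − F₀)/F₀.  The correction operator is not further specified in
the source description; subtraction of the mCherry dF/F₀ is adopted
because an axial-motion artifact is common-mode in dF/F₀ units, and a
fitted-gain variant (β estimated on the pre-stimulus baseline) is
provided for sessions where the channels see the artifact unequally.
The response threshold is baseline mean + 2·STD, both computed on the
pre-first-odor segment of the corrected trace; a trial passes iff the
maximum corrected dF/F₀ in the 10 frames after odor release exceeds it,
and a cell is responsive to an odor only if all three trials pass.  The
classification is invariant under a common positive rescaling of the two
raw channels.  Note the single-trial false-positive probability of a
max-over-window rule is scale-free (≈ 5–20% depending on noise
autocorrelation); the three-trial conjunction is what drives the
cell-level false-positive rate to the percent level.

## SBR and spine density

SBR = mean signal-ROI intensity / mean background-ROI intensity, per
frame; depth = z-index × z-step.  ROIs are supplied (placed manually in
practice); an automatic percentile mode (top 1% / bottom 10%) exists for
synthetic tests only.  SBR is invariant to multiplicative intensity
scaling and deliberately not to offsets.  Spine density = count/length
(µm⁻¹); aggregation reports mean ± SEM over dendrites.

## Synthetic data

Each generator is a pure function of its config, seed included
(bit-identical reruns), and truth summaries are computed from the
generated ground truth, never from rendered images.  The imaging model is
Gaussian PSF blur plus Poisson shot noise and Gaussian read noise.

**Motility phantom.** A stable core (soma radius 6 px + 8 primary
branches of ~30 steps) carries motile terminal segments (~20 steps,
5 px thick at 0.16 µm/px — fine processes are ≈1 µm across).  Per
interval the generator retracts random terminals and grows new ones
(rejection-sampled away from just-lost territory, as new processes grow
into fresh neuropil) until the pixels actually lost from and gained by
the union mask reach p_loss·D and p_gain·D, D = |B₀|/(1−p_gain) — so the
programmed pixel fractions (defaults 0.27/0.28, the reported in vivo
day-0 values, implying TOR ≈ 0.55) hold by construction despite segment
overlap.  Frames after the first get subpixel translation jitter
(default ±0.3 px).  Default sessions are 7 timepoints at 10-min cadence,
2 z-planes, 256² px.  Not emulated: depth-dependent background, soma
displacement, process thickness changes, photobleaching — so passing
recovery tests demonstrates correctness of the pixel bookkeeping and
robustness to noise/jitter/PSF, not performance on degraded in vivo data.

**Trace generator.** Poisson event times, double-exponential kernels
normalized to unit peak, drifting baseline, Gaussian noise.  Defaults
follow the reported neuronal transients (amplitude 4.95 %ΔF/F, decay
half-width 3.24 s → τ = 3.24/ln 2 s; rise 0.3 s); event-recovery tests
use astrocyte-microdomain kinetics (rise 1 s, decay 8 s, FDHM ≈ 6 s) at
0.5 events/min with amplitudes ≥ 4 robust-z, because those are the
events the 1-s smoothing and 3-z threshold are meant for.  The analytic
kernel FDHM/half-width are computed by root finding on the kernel
expression, independent of the detection path.  ΔF/F baseline tests use
600 s at 10 Hz, a 50% linear drift and 0.5% noise — soma-averaged traces
are sub-percent noisy — under which the rolling 8th percentile tracks
truth within 2% (quantile bias ≈ 1.4σ plus half-window drift lag).

**Fly generator.** Both channels share a smoothed common-mode artifact
(3% SD); per-channel noise is temporally smoothed (σ = 1.5 frames), as
indicator kinetics make real traces autocorrelated — with white noise
the max-over-10-frames rule would fire on ~20% of trials regardless of
noise amplitude.  Sessions start with 60 pre-odor frames so the
threshold STD is estimated from a usable sample.  Responders respond in
all trials, "partial" cells in the first two only, the rest are noise.

**Depth/shift generators.** Constant-brightness disk attenuated as
exp(−depth/ℓ) over a constant floor (truth SBR in closed form); tapered
band-limited textures with bilinear subpixel shifts at stated SNR.

## Problem sizes and tolerances

Recovery tests use 10 motility sessions (≈12 s), 20-seed event batches
(100 traces), 200-cell fly batches and 30-plane depth stacks; the whole
suite runs in ≈30 s and the acceptance script in ≈15 s on one CPU.
Motility recovery is asserted within ±0.05 (absolute, on fractions and
TOR) against truth masks; events at sensitivity ≥ 0.95 and ≤ 0.05 false
positives/min; registration ≤ 0.1 px; FDHM within one sample; SBR within
10%; detected event matches use the detector's own resolution limit
(min_sep) as the association window.

## Known limitations

Translation-only registration (no rotation/affine/elastic, no 3-D);
motility is 2-D on z-projections by design.  The microdomain ROI
proposer is a stand-in, not a reimplementation of the unpublished macro.
Source separation, spike inference and neuropil correction are out of
scope — traces are assumed extracted.  FDHM of overlapping events is
bounded by adjacent peaks and will underestimate widths at high event
rates.  The structureless-frame guard assumes bright-on-dark structure.
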