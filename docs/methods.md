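# Methods

This note documents the models, procedures, numerical choices, and
known limitations of `ripplemap`. It is written for users who need to
judge what the pipeline computes and what passing its tests does — and
does not — establish about real recordings.

## Ripple detection

The hippocampal LFP is analyzed at 2 kHz (acquisition-rate traces are
anti-alias decimated first, `preprocess.downsample_lfp`). Detection
operates on the **ripple power** signal: a 400-order FIR band-pass
(default 150–250 Hz) applied forward-backward, rectified, and smoothed
with an 8 ms rectangular window. Events are intervals where power
exceeds `mean + k_sd · SD` of the whole-recording power (`k_sd = 3` by
default; 2 is appropriate for voltage-dye sessions with lower SNR, 4
for a conservative variant), extended to where power crosses 75 % of
that threshold. Candidates shorter than the mean duration of all
candidates are discarded — a screen whose purpose is to remove the
brief spurious crossings real recordings produce. The event center is
the largest trough of the band-passed LFP within the event, and events
with centers < 50 ms apart are concatenated (center recomputed over the
union). All filters in the package are zero-phase (forward-backward),
because event *timing* is the core quantity everywhere downstream.

Deliberately open choices, all exposed as configuration: the detection
band (150–250 Hz is used for consistency with the bundle classifier),
computing threshold statistics over the entire recording rather than
NREM-masked epochs (a state mask can be supplied upstream), and
applying the duration screen in a single pass over the initial
candidate set rather than iterating it.

## Bundle classification

Ripples arriving < 200 ms apart form a **bundle**, a distinct event
class. For each detected event the analytic-Morlet (cmor1.5-1.0)
wavelet power averaged over 150–250 Hz is computed on a ±0.4 s window;
supra-threshold excursions (threshold adapted per event as the window
`mean + 2·SD`) lasting ≥ 20 ms (~4 ripple cycles) are
candidate ripples; the excursion chain around the event's own peak with
successive gaps < 200 ms gives `n_ripples`, and `n_ripples ≥ 2` marks
the event bundled. Every event lands in exactly one class. Events
whose window exceeds the recording bounds are skipped with a warning
and reported as single.

## Inter-SWR interval statistics

If SWR generation were a homogeneous Poisson process, inter-event
intervals would be exponential — a straight line in log-count space.
`interval_exponential_fit` histograms the intervals (0.25 s bins by
default), fits a weighted least-squares line to log counts for bins
beyond 0.25 s (weights √N, since var(log N) ≈ 1/N for Poisson counts),
and reports per-bin residuals. Bundled ripples reveal themselves as an
excess of positive residuals below the fit range. Residual z-scores
(residual/√expected) are reported only where the fitted expectation is
≥ 5, where the normal approximation is defensible.

## Asymmetry index

`AI = (A⁺ − A⁻)/(A⁺ + A⁻)`, with A⁻ the mean of a peri-event trace
over lags [−Δt, 0) and A⁺ over (0, Δt], Δt = 0.2 s. Positive AI means
activity follows the event; AI = ±1 are complete right/left skew. The
implementation guards the denominator at 10⁻¹² of the trace's absolute
scale and flags such windows invalid rather than returning an
arbitrary number. AI is computed on raw (not z-scored) traces by
default; optical traces can be negative, in which case AI is no longer
bounded by [−1, 1] — interpretation is left to the caller, and no
automatic shifting is applied.

Quartile partitions use linear-interpolation (type-7) quantiles with
strict inequalities, so ties at Q1/Q3 stay in QR2-3 and each tail holds
at most ⌈n/4⌉ events (exactly n/4 for distinct values with 4 | n).

## Permutation-null z-scoring

Peri-event windows (±1 s, aligned to the nearest frame) are z-scored
per pixel per lag against surrogate windows built by permuting the
inter-event intervals. The surrogate train preserves the interval
multiset; its anchor is drawn uniformly over the feasible range so
surrogate times carry no systematic coincidence with real events
(anchoring at the first real event would pin two surrogate windows per
permutation onto true events and inflate the null SD at lag 0). 100
permutations by default. Under this null, individual z-scored samples
are approximately standard normal (~5 % beyond |z| = 1.96) and entries
of the event-mean map have SD ≈ 1/√n_events.

## Peak times and FWHM amplitudes

Per-region activation peak times t_p come from the mean z-scored ROI
trace; a peak counts as reliable when it exceeds the trace median by 4
robust SDs (1.4826·MAD, falling back to the SD for degenerate traces).
Unreliable regions are reported missing, never imputed (imputation for
group plots is a deliberate non-feature; callers can impute
explicitly). Ties produce equal t_p values, not an artificial order.

FWHM amplitude is the mean of the trace between its half-maximum
crossings around the peak (half-maximum relative to zero, appropriate
for z-scored/band-passed traces; crossings linearly interpolated; the
mean computed by trapezoid with interpolated endpoints, which is exact
for piecewise-linear traces). Deactivation troughs are rectified
first. Traces that never recross half-max inside the window are
flagged invalid.

## Optical flow and direction distributions

Horn–Schunck flow (brightness constancy + global smoothness, Jacobi
iteration; α = 1.0, 100 iterations — values chosen for the smooth
mesoscale signals targeted here and exposed as parameters) is applied
to averaged peri-event stacks. Direction distributions follow a
bootstrap-over-events scheme: each of n_iter iterations draws ~20
events without replacement, averages their frames at lags within
±50 ms of the event center, runs the flow, and records the angle of
the summed (u, v) over the region's pixels — summing before taking the
angle makes the estimate robust to per-pixel noise. The matched null
repeats this at shuffled-interval surrogate timestamps (fresh shuffle
per iteration).

Axis convention: 0° = lateral, 90° = anterior, 180° = medial,
270° = posterior; image columns increase laterally and rows increase
posteriorly (recorded in the atlas JSON).

The Kuiper two-sample statistic V = max(F₁−F₂) + max(F₂−F₁) is
rotation-invariant by construction; p-values use the standard
asymptotic series with Stephens' finite-sample correction on the
effective sample size n₁n₂/(n₁+n₂). Simulated type-I error at
α = 0.05 is 0.05 ± 0.02 for n = 100 per sample.

## Preprocessing

SVD denoising truncates the T×(H·W) data matrix to the smallest rank
capturing 95 % of squared singular values (the cutoff is a package
default, overridable by an explicit rank). ΔF/F₀ uses a
piecewise-linear baseline
from ordinary least-squares line fits on 30 s windows with 50 %
overlap, stitched linearly between window centers and extended with
the end windows' own lines (so a globally linear trend is absorbed
exactly); output is percent change. The 0.1–6 Hz band-pass is a
Hamming windowed-sinc FIR applied forward-backward after per-pixel
mean removal (so DC is rejected exactly); its order follows the
Hamming transition-width rule with a 1 Hz transition, capped so
`filtfilt` padding fits the stack.

## Vigilance scoring

Epochs (5 s default) are labeled from EMG RMS and the hippocampal
theta (6–10 Hz) / delta (1–4 Hz) Welch power ratio: wake when EMG RMS
is at or above the wake threshold; REM when EMG is at or below the REM
threshold and the ratio exceeds 1; NREM otherwise. Thresholds default
to per-recording percentiles (50th/10th) but should be set absolutely
when signal units are known — percentile defaults misbehave on
recordings dominated by a single state. An optional immobility
criterion requires NREM epochs to sit in sub-wake-EMG runs of ≥ 50 s
(standing in for a facial-movement video criterion, which is out of
scope). Band edges and all thresholds are configurable; the defaults
are declared assumptions, echoed into every resolved pipeline config.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analyses
assume*, with closed-form ground truth:

* LFP: 1/f^β Gaussian background (FFT-shaped, β = 1, unit SD) plus
  Hann-windowed ripple-band bursts (default 180 Hz, 80 ms, 8× SD)
  whose deepest trough falls at the scripted time. Brief (15 ms)
  ripple-band transients at a low Poisson rate (0.1 Hz, kept ≥ 0.5 s
  from scripted ripples) emulate the spurious candidates whose removal
  is the duration screen's job; without them a homogeneous synthetic
  event set would be gutted by that screen.
* MUA: baseline 5 spikes/s plus per-event kernels of two half-Gaussians
  (σ = 50 ms, truncation-corrected) whose areas are solved in closed
  form — including the baseline's contribution to the ±0.2 s window
  means — so the expected AI equals the target skew; reachable targets
  satisfy |AI| ≤ M/(M + 2b) (≈ 0.86 at defaults M = 60, b = 5). The
  rate drives a per-sample Poisson spike count, then 3 ms smoothing.
* Imaging: pixel Gaussian noise plus either per-region Gaussian time
  courses (σ_t = 50 ms) peaking at event + scripted lag, or a
  Gaussian-profile plane wave sweeping the window at a scripted angle.
* Scoring signals: rectified Gaussian EMG with state-dependent SD
  (wake 1.0 > NREM 0.3 > REM 0.1) and a hippocampal trace mixing
  band-limited delta/theta noise with state-dependent gains.

These are stand-ins, not biophysics: no sharp-wave component, no
spindle/slow-oscillation coupling, no hemodynamic or optical artifacts,
no motion, no real parcellation geometry (the test atlas is a
rectangular grid). Passing round-trip tests therefore shows the
*pipeline's* correctness and calibration under its own assumptions — it
does not validate detector thresholds or scoring thresholds for any
particular real preparation.

## Problem sizes and reproducibility

Test and acceptance workloads are sized for a laptop-class single
core: detector round trips use 600 s of 2 kHz LFP with 200 events;
direction recovery uses 32×32 stacks, 40 events, and 100 bootstrap
iterations; permutation calibration uses a 200 s, 16×16 stack with 100
permutations. Every stochastic component takes an explicit seed; the
pipeline fans a single global seed into independent per-stage streams
so rerunning one stage never perturbs another, and identical configs
produce identical outputs.
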