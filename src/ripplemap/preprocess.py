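"""Conditioning of raw LFP and imaging stacks.

LFP acquired at 20 kHz is anti-alias decimated to the 2 kHz analysis
rate.  Imaging stacks are SVD-denoised, converted to percent dF/F0
against a slowly varying piecewise-linear baseline (local linear
regression over sliding windows, in the spirit of Chronux's locdetrend),
and band-pass filtered 0.1-6 Hz with a zero-phase FIR filter.  All
temporal filters here run forward-backward so event timing — the core
quantity of the peri-event analyses — is never shifted.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .core import ImageStack, RegionAtlas, TimeSeries

__all__ = [
    "downsample_lfp",
    "svd_denoise",
    "compute_dff",
    "bandpass_optical",
    "roi_trace",
]


def downsample_lfp(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-alias low-pass and decimate to ``target_rate``."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > ts.rate:
        raise ValueError(
            f"target rate {target_rate} Hz exceeds source rate {ts.rate} Hz"
        )
    if target_rate == ts.rate:
        return TimeSeries(ts.samples.copy(), rate=ts.rate, t0=ts.t0)
    frac = Fraction(target_rate / ts.rate).limit_denominator(10000)
    out = signal.resample_poly(ts.samples, frac.numerator, frac.denominator,
                               padtype="line")
    return TimeSeries(out, rate=target_rate, t0=ts.t0)


def svd_denoise(stack: ImageStack, n_components: int | None = None,
                energy: float = 0.95) -> ImageStack:
    """Rank-truncated SVD reconstruction of the T x (H*W) data matrix.

    With ``n_components=None`` the smallest rank capturing ``energy`` of
    the squared singular values is used.
    """
    t, h, w = stack.frames.shape
    x = stack.frames.reshape(t, h * w)
    max_rank = min(t, h * w)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if n_components is None:
        cum = np.cumsum(s**2) / np.sum(s**2)
        n_components = int(np.searchsorted(cum, energy) + 1)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components]
    return ImageStack(recon.reshape(t, h, w), rate=stack.rate, t0=stack.t0)


def _piecewise_linear_baseline(x: np.ndarray, rate: float,
                               window: float) -> np.ndarray:
    """Per-column baseline from local linear fits on 50%-overlapping windows.

    ``x`` is T x P. Each window of ``window`` seconds gets an ordinary
    least-squares line per column; the fitted values at window centers
    are joined piecewise-linearly, with the end windows' own lines used
    beyond the first/last center so a globally linear trend is recovered
    exactly.
    """
    t_n, p = x.shape
    w = min(int(round(window * rate)), t_n)
    if w < 2:
        raise ValueError("baseline window shorter than two samples")
    step = max(w // 2, 1)
    starts = list(range(0, max(t_n - w, 0) + 1, step))
    if starts[-1] != t_n - w:
        starts.append(t_n - w)
    centers = []
    coefs = []  # (slope, intercept) per window per column
    tt = np.arange(t_n, dtype=float)
    design = np.empty((w, 2))
    design[:, 1] = 1.0
    for s0 in starts:
        design[:, 0] = tt[s0:s0 + w]
        beta, *_ = np.linalg.lstsq(design, x[s0:s0 + w], rcond=None)
        centers.append(s0 + (w - 1) / 2.0)
        coefs.append(beta)
    centers_arr = np.asarray(centers)
    base = np.empty_like(x)
    vals = np.stack([b[0] * c + b[1] for b, c in zip(coefs, centers_arr)])
    for j, t_j in enumerate(tt):
        if t_j <= centers_arr[0]:
            b = coefs[0]
            base[j] = b[0] * t_j + b[1]
        elif t_j >= centers_arr[-1]:
            b = coefs[-1]
            base[j] = b[0] * t_j + b[1]
        else:
            k = np.searchsorted(centers_arr, t_j) - 1
            frac = (t_j - centers_arr[k]) / (centers_arr[k + 1] - centers_arr[k])
            base[j] = (1 - frac) * vals[k] + frac * vals[k + 1]
    return base


def compute_dff(stack: ImageStack, baseline_win: float = 30.0) -> ImageStack:
    """Percent fluorescence change against a piecewise-linear baseline.

    F0 is fit per pixel by local linear regression over sliding windows
    of ``baseline_win`` seconds (50% overlap) stitched piecewise-linearly;
    the output is (F - F0) / F0 x 100.  A non-positive baseline anywhere
    signals a non-physical fluorescence trace and raises.
    """
    t, h, w = stack.frames.shape
    if baseline_win >= stack.duration:
        baseline_win = stack.duration
    x = stack.frames.reshape(t, h * w)
    f0 = _piecewise_linear_baseline(x, stack.rate, baseline_win)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 is non-positive; check raw fluorescence")
    dff = (x - f0) / f0 * 100.0
    return ImageStack(dff.reshape(t, h, w), rate=stack.rate, t0=stack.t0)


def bandpass_optical(stack: ImageStack, lo: float = 0.1, hi: float = 6.0,
                     numtaps: int | None = None) -> ImageStack:
    """Zero-phase FIR band-pass of every pixel trace.

    The filter is a Hamming-windowed sinc applied forward-backward;
    pixel means are removed first so DC is rejected exactly.  The
    default order follows the Hamming transition-width rule with a
    transition of max(lo, 1) Hz, capped so filtfilt's padding fits the
    stack length.
    """
    rate = stack.rate
    if not 0 <= lo < hi < rate / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at rate {rate} Hz")
    t = stack.frames.shape[0]
    if numtaps is None:
        trans = max(lo, 1.0)
        numtaps = int(3.3 * rate / trans) | 1
    numtaps = min(numtaps, max((t - 2) // 3, 3) | 1)
    taps = signal.firwin(numtaps, [max(lo, 1e-6), hi], fs=rate,
                         pass_zero=False, window="hamming")
    x = stack.frames.reshape(t, -1)
    x = x - x.mean(axis=0, keepdims=True)
    out = signal.filtfilt(taps, [1.0], x, axis=0)
    return ImageStack(out.reshape(stack.frames.shape), rate=rate, t0=stack.t0)


def roi_trace(stack: ImageStack, atlas: RegionAtlas, region: str,
              box: int | None = 3) -> TimeSeries:
    """Mean optical trace of one region.

    With ``box`` set (default 3), averages the box x box pixel patch at
    the region centroid — the convention for regional example traces;
    with ``box=None`` the full region mask is averaged.
    """
    if box is None:
        mask = atlas.mask(region)
        trace = stack.frames[:, mask].mean(axis=1)
    else:
        r, c = atlas.centroid(region)
        h, w = atlas.labels.shape
        half = box // 2
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        trace = stack.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return TimeSeries(trace, rate=stack.rate, t0=stack.t0)
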