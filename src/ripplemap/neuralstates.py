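"""MUA derivation, up/down-state detection, and vigilance-state scoring.

Multiunit activity is approximated from the LFP by high-pass filtering
above 300 Hz, rectifying, and smoothing with a rectangular window —
~3 ms for hippocampal and 100 ms for neocortical signals.  Up- and
down-states (and optical peak activations) come from a joint amplitude
+ duration threshold on the relevant trace.  Sleep is scored per epoch
from EMG power and the hippocampal theta(6-10 Hz)/delta(1-4 Hz) power
ratio: wake = high EMG; NREM = low EMG, low ratio; REM = lowest EMG,
high ratio, with an optional >= 50 s immobility run criterion for NREM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import TimeSeries

__all__ = [
    "StateInterval",
    "StateThresholds",
    "SleepOptions",
    "compute_mua",
    "detect_threshold_events",
    "score_sleep",
]

HPC_SMOOTH_S = 0.003  # hippocampal MUA smoothing window
CTX_SMOOTH_S = 0.100  # neocortical MUA smoothing window


@dataclass
class StateInterval:
    """One labeled interval: an up/down state, vigilance epoch run, or
    peak activation, with the extremum time when applicable."""

    start: float
    end: float
    kind: str
    peak_time: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval must have start < end")


@dataclass
class StateThresholds:
    """Joint amplitude + duration criterion.

    ``amp_thresh`` is either a value in signal units or a percentile
    string like ``'p60'`` resolved against the signal itself.
    """

    amp_thresh: float | str
    dur_thresh: float

    def __post_init__(self) -> None:
        if self.dur_thresh <= 0:
            raise ValueError("dur_thresh must be positive")

    def resolve(self, samples: np.ndarray) -> float:
        if isinstance(self.amp_thresh, str):
            if not self.amp_thresh.startswith("p"):
                raise ValueError(f"bad percentile spec {self.amp_thresh!r}")
            return float(np.percentile(samples, float(self.amp_thresh[1:])))
        return float(self.amp_thresh)


def compute_mua(lfp: TimeSeries, hp_cutoff: float = 300.0,
                smooth_win: float = HPC_SMOOTH_S,
                numtaps: int = 401) -> TimeSeries:
    """High-pass, rectify, and smooth the LFP into an MUA proxy."""
    if lfp.rate <= 2 * hp_cutoff:
        raise ValueError(
            f"rate {lfp.rate} Hz too low for a {hp_cutoff} Hz high-pass"
        )
    taps = signal.firwin(numtaps, hp_cutoff, fs=lfp.rate, pass_zero=False)
    hp = signal.filtfilt(taps, [1.0], lfp.samples)
    win = max(int(round(smooth_win * lfp.rate)), 1)
    mua = ndimage.uniform_filter1d(np.abs(hp), size=win, mode="nearest")
    return TimeSeries(mua, rate=lfp.rate, t0=lfp.t0)


def detect_threshold_events(
    sig: TimeSeries,
    th: StateThresholds,
    polarity: str = "above",
    kind: str | None = None,
) -> list[StateInterval]:
    """Maximal intervals beyond a threshold, kept if long enough.

    ``polarity='above'`` finds up-states / peak activations (extremum =
    maximum); ``'below'`` finds down-states (extremum = minimum).  Each
    kept interval records the time of its extremum.
    """
    if polarity not in {"above", "below"}:
        raise ValueError("polarity must be 'above' or 'below'")
    amp = th.resolve(sig.samples)
    if not np.isfinite(amp):
        raise ValueError("amplitude threshold must be finite")
    mask = sig.samples > amp if polarity == "above" else sig.samples < amp
    if kind is None:
        kind = "up" if polarity == "above" else "down"
    out: list[StateInterval] = []
    lbl, n = ndimage.label(mask)
    for sl in ndimage.find_objects(lbl) if n else []:
        a, b = sl[0].start, sl[0].stop
        if (b - a) / sig.rate < th.dur_thresh:
            continue
        seg = sig.samples[a:b]
        ext = a + (int(np.argmax(seg)) if polarity == "above" else int(np.argmin(seg)))
        out.append(
            StateInterval(
                start=sig.t0 + a / sig.rate,
                end=sig.t0 + b / sig.rate,
                kind=kind,
                peak_time=sig.t0 + ext / sig.rate,
            )
        )
    return out


@dataclass
class SleepOptions:
    """Thresholds for epoch-wise vigilance scoring.

    ``emg_wake`` / ``emg_rem`` are RMS thresholds in EMG units; when
    None they fall back to per-recording percentiles of the epoch RMS
    distribution (50th and 10th).  ``ratio_thresh`` splits theta- from
    delta-dominant epochs.  ``immobility_min`` (seconds), when set,
    requires NREM epochs to sit inside runs of sub-wake-threshold EMG of
    at least that length.
    """

    emg_wake: float | None = None
    emg_rem: float | None = None
    ratio_thresh: float = 1.0
    theta_band: tuple[float, float] = (6.0, 10.0)
    delta_band: tuple[float, float] = (1.0, 4.0)
    immobility_min: float | None = None


def _band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    nperseg = min(x.size, int(2 * rate))
    f, pxx = signal.welch(x, fs=rate, nperseg=nperseg)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(pxx[sel], f[sel]))


def score_sleep(
    emg: TimeSeries,
    hpc: TimeSeries,
    epoch: float = 5.0,
    opts: SleepOptions | None = None,
) -> list[StateInterval]:
    """Score vigilance states epoch by epoch.

    Every epoch receives exactly one label (the epochs partition the
    recording); consecutive same-label epochs are merged into one
    interval.
    """
    if opts is None:
        opts = SleepOptions()
    if epoch > emg.duration or epoch > hpc.duration:
        raise ValueError("epoch longer than recording")
    n_epochs = int(min(emg.duration, hpc.duration) // epoch)
    rms = np.empty(n_epochs)
    ratio = np.empty(n_epochs)
    for i in range(n_epochs):
        e0, e1 = int(i * epoch * emg.rate), int((i + 1) * epoch * emg.rate)
        h0, h1 = int(i * epoch * hpc.rate), int((i + 1) * epoch * hpc.rate)
        rms[i] = np.sqrt(np.mean(emg.samples[e0:e1] ** 2))
        theta = _band_power(hpc.samples[h0:h1], hpc.rate, opts.theta_band)
        delta = _band_power(hpc.samples[h0:h1], hpc.rate, opts.delta_band)
        ratio[i] = theta / delta if delta > 0 else np.inf
    wake_th = (opts.emg_wake if opts.emg_wake is not None
               else float(np.percentile(rms, 50)))
    rem_th = (opts.emg_rem if opts.emg_rem is not None
              else float(np.percentile(rms, 10)))
    labels = []
    for i in range(n_epochs):
        if rms[i] >= wake_th:
            labels.append("wake")
        elif ratio[i] > opts.ratio_thresh and rms[i] <= rem_th:
            labels.append("REM")
        else:
            labels.append("NREM")
    if opts.immobility_min is not None:
        min_epochs = int(np.ceil(opts.immobility_min / epoch))
        immobile = rms < wake_th
        lbl_arr, n = ndimage.label(immobile)
        run_len = ndimage.sum_labels(immobile, lbl_arr, range(1, n + 1))
        for i in range(n_epochs):
            if labels[i] == "NREM":
                run = lbl_arr[i]
                if run == 0 or run_len[run - 1] < min_epochs:
                    labels[i] = "wake"
    out: list[StateInterval] = []
    start = 0
    for i in range(1, n_epochs + 1):
        if i == n_epochs or labels[i] != labels[start]:
            out.append(
                StateInterval(
                    start=emg.t0 + start * epoch,
                    end=emg.t0 + i * epoch,
                    kind=labels[start],
                )
            )
            start = i
    return out
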