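"""Peri-event alignment, permutation-null z-scoring, and timing statistics.

Signals and image stacks are cut into windows aligned to event centers
(lag 0).  Peri-event activity is normalised against a shuffled-timestamp
null: inter-event intervals are permuted to generate surrogate event
trains, and the per-pixel per-lag mean and SD over all surrogate windows
z-score the observed ones — removing ongoing-activity structure that is
not event-locked.

Timing statistics:

* the asymmetry index AI = (post - pre)/(post + pre), the mean activity
  in the ``dt`` = 0.2 s windows after vs before the event center;
  AI = +1 means all activity follows the event, -1 that it precedes it;
* FWHM amplitude: the mean of a peri-event trace between its half-max
  crossings around the peak (deactivations are rectified first);
* per-region activation peak times t_p and their ascending ordering;
* quartile partition of AI distributions (QR1 below Q1, QR4 above Q3)
  and the proportion of events whose two AI measures match in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageStack, RegionAtlas, TimeSeries

__all__ = [
    "PeriEventEnsemble",
    "AIResult",
    "FWHMAmplitude",
    "extract_windows",
    "zscore_by_shuffled_null",
    "fwhm_amplitude",
    "asymmetry_index",
    "quartile_partition",
    "sign_match_proportion",
    "peri_peak_ripple_power",
    "peak_time_map",
]


@dataclass
class PeriEventEnsemble:
    """Event-aligned windows: events x lag (x H x W)."""

    windows: np.ndarray
    lags: np.ndarray  # seconds, 0 at the event center
    event_ids: np.ndarray  # indices into the source event list
    rate: float

    @property
    def n_events(self) -> int:
        return self.windows.shape[0]

    def mean(self) -> np.ndarray:
        """Average over events: lag (x H x W)."""
        return self.windows.mean(axis=0)


@dataclass
class AIResult:
    """Asymmetry index of one peri-event window."""

    ai: float
    dt: float
    pre_mean: float
    post_mean: float
    valid: bool


@dataclass
class FWHMAmplitude:
    """Full-width-at-half-maximum amplitude of a peri-event trace."""

    amplitude: float
    t1: float
    t2: float
    peak_time: float
    valid: bool


def extract_windows(
    sig: TimeSeries | ImageStack,
    centers: np.ndarray | list,
    half_win: float = 1.0,
) -> PeriEventEnsemble:
    """Cut windows of +-``half_win`` s around each center.

    Windows are aligned to the sample/frame nearest each center; events
    whose window would extend past the recording bounds are excluded
    (never padded).  Raises if no event yields a full window.
    """
    centers = np.asarray(centers, dtype=float)
    data = sig.samples if isinstance(sig, TimeSeries) else sig.frames
    n = data.shape[0]
    half = int(round(half_win * sig.rate))
    wins, ids = [], []
    for i, c in enumerate(centers):
        idx = int(round((c - sig.t0) * sig.rate))
        if idx - half < 0 or idx + half >= n:
            continue
        wins.append(data[idx - half:idx + half + 1])
        ids.append(i)
    if not wins:
        raise ValueError("no event has a full window inside the recording")
    lags = (np.arange(2 * half + 1) - half) / sig.rate
    return PeriEventEnsemble(
        windows=np.stack(wins), lags=lags,
        event_ids=np.asarray(ids), rate=sig.rate,
    )


def shuffle_event_times(
    centers: np.ndarray,
    rng: np.random.Generator,
    anchor_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Surrogate event times from randomly permuted inter-event intervals.

    The inter-event interval multiset (hence the train's total span) is
    preserved.  By default the train keeps the original first event
    time; with ``anchor_range=(lo, hi)`` the first surrogate time is
    drawn uniformly so the whole train fits in ``[lo, hi]``, avoiding
    any systematic coincidence between surrogate and real event times.
    """
    centers = np.sort(np.asarray(centers, dtype=float))
    if centers.size < 2:
        raise ValueError("need at least 2 events to shuffle intervals")
    intervals = np.diff(centers)
    start = centers[0]
    if anchor_range is not None:
        lo, hi = anchor_range
        span = centers[-1] - centers[0]
        if hi - span > lo:
            start = rng.uniform(lo, hi - span)
    return start + np.concatenate(
        [[0.0], np.cumsum(rng.permutation(intervals))]
    )


def zscore_by_shuffled_null(
    stack: ImageStack,
    centers: np.ndarray | list,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    half_win: float = 1.0,
    max_tries: int = 50,
) -> PeriEventEnsemble:
    """Z-score peri-event windows against a shuffled-timestamp null.

    For each of ``n_perm`` permutations the inter-event intervals are
    shuffled into a surrogate event train; the mean and SD stacks over
    all surrogate windows (per pixel, per lag) z-score the observed
    peri-event windows.
    """
    centers = np.sort(np.asarray(centers, dtype=float))
    if centers.size < 2:
        raise ValueError("need at least 2 events")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = extract_windows(stack, centers, half_win)
    valid = centers[obs.event_ids]
    shape = obs.windows.shape[1:]
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    count = 0
    t_lo = stack.t0 + half_win
    t_hi = stack.t0 + stack.duration - half_win
    for _ in range(n_perm):
        for _try in range(max_tries):
            surrogate = shuffle_event_times(valid, rng,
                                            anchor_range=(t_lo, t_hi))
            try:
                ens = extract_windows(stack, surrogate, half_win)
            except ValueError:
                continue
            if ens.n_events == surrogate.size:
                break
        else:
            raise ValueError("could not place surrogate windows in bounds")
        total += ens.windows.sum(axis=0)
        total_sq += (ens.windows**2).sum(axis=0)
        count += ens.n_events
    mean = total / count
    var = np.maximum(total_sq / count - mean**2, 0.0)
    sd = np.sqrt(var)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (obs.windows - mean) / sd_safe
    return PeriEventEnsemble(
        windows=z, lags=obs.lags, event_ids=obs.event_ids, rate=obs.rate
    )


def _interp_crossing(lags: np.ndarray, y: np.ndarray, i: int, j: int,
                     level: float) -> float:
    """Lag where y crosses ``level`` between samples i and j."""
    y0, y1 = y[i], y[j]
    if y1 == y0:
        return float(lags[j])
    frac = (level - y0) / (y1 - y0)
    return float(lags[i] + frac * (lags[j] - lags[i]))


def fwhm_amplitude(
    trace: np.ndarray,
    lags: np.ndarray,
    mode: str = "activation",
) -> FWHMAmplitude:
    """Mean of a peri-event trace across its full width at half maximum.

    ``mode='deactivation'`` negates the trace first (deactivation peaks
    are rectified for comparison).  Half-maximum is taken relative to a
    zero baseline, appropriate for z-scored or band-passed traces.  If
    the trace never falls below half-max inside the window on either
    side, the result is flagged invalid.
    """
    y = np.asarray(trace, dtype=float)
    if mode == "deactivation":
        y = -y
    elif mode != "activation":
        raise ValueError("mode must be 'activation' or 'deactivation'")
    i_p = int(np.argmax(y))
    peak = y[i_p]
    invalid = FWHMAmplitude(np.nan, np.nan, np.nan, np.nan, valid=False)
    if peak <= 0:
        return invalid
    half = peak / 2.0
    i1 = i_p
    while i1 > 0 and y[i1 - 1] >= half:
        i1 -= 1
    if i1 == 0 and y[0] >= half:
        return invalid
    t1 = _interp_crossing(lags, y, i1 - 1, i1, half) if i1 > 0 else lags[0]
    i2 = i_p
    n = y.size
    while i2 < n - 1 and y[i2 + 1] >= half:
        i2 += 1
    if i2 == n - 1 and y[n - 1] >= half:
        return invalid
    t2 = _interp_crossing(lags, y, i2, i2 + 1, half) if i2 < n - 1 else lags[-1]
    # mean over [t1, t2] by trapezoid with interpolated endpoints
    inner = (lags > t1) & (lags < t2)
    xs = np.concatenate([[t1], lags[inner], [t2]])
    ys = np.concatenate([[half], y[inner], [half]])
    amplitude = float(np.trapezoid(ys, xs) / (t2 - t1))
    return FWHMAmplitude(
        amplitude=amplitude, t1=t1, t2=t2,
        peak_time=float(lags[i_p]), valid=True,
    )


def asymmetry_index(
    trace: np.ndarray, lags: np.ndarray, dt: float = 0.2
) -> AIResult:
    """(post - pre)/(post + pre) mean activity in +-``dt`` windows.

    Positive AI means activity tends to follow the event; for a
    nonnegative trace the value lies in [-1, 1].  When the denominator
    vanishes (relative to the trace's absolute scale) the result is
    flagged invalid.
    """
    lags = np.asarray(lags, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if lags[0] > -dt + 1e-12 or lags[-1] < dt - 1e-12:
        raise ValueError(f"window must span at least [-{dt}, {dt}] s")
    pre_mask = (lags >= -dt) & (lags < 0)
    post_mask = (lags > 0) & (lags <= dt)
    pre = float(trace[pre_mask].mean())
    post = float(trace[post_mask].mean())
    denom = post + pre
    scale = float(np.max(np.abs(trace))) or 1.0
    if abs(denom) < 1e-12 * scale:
        return AIResult(np.nan, dt, pre, post, valid=False)
    return AIResult((post - pre) / denom, dt, pre, post, valid=True)


def quartile_partition(ais: list[AIResult] | np.ndarray) -> list[str | None]:
    """Label events by where their AI falls in the session distribution.

    QR1: below the first quartile; QR4: above the third; the rest QR2-3
    (strict inequalities, so ties at the quartiles stay in QR2-3).
    Invalid AI values receive None.
    """
    if len(ais) and isinstance(ais[0], AIResult):
        vals = np.array([a.ai if a.valid else np.nan for a in ais])
    else:
        vals = np.asarray(ais, dtype=float)
    valid = vals[np.isfinite(vals)]
    if valid.size < 4:
        raise ValueError("need at least 4 valid AI values")
    q1, q3 = np.quantile(valid, [0.25, 0.75])  # linear-interpolation quantiles
    labels: list[str | None] = []
    for v in vals:
        if not np.isfinite(v):
            labels.append(None)
        elif v < q1:
            labels.append("QR1")
        elif v > q3:
            labels.append("QR4")
        else:
            labels.append("QR2-3")
    return labels


def sign_match_proportion(ai_a, ai_b) -> float:
    """Fraction of paired events whose AI values agree in sign."""
    a = np.asarray([x.ai if isinstance(x, AIResult) else x for x in ai_a], float)
    b = np.asarray([x.ai if isinstance(x, AIResult) else x for x in ai_b], float)
    if a.size != b.size:
        raise ValueError("paired AI lists must have equal length")
    if a.size == 0:
        raise ValueError("empty AI lists")
    return float(np.mean(np.sign(a) == np.sign(b)))


def peri_peak_ripple_power(
    power: TimeSeries,
    peak_times: np.ndarray | list,
    half_win: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, FWHMAmplitude]:
    """Mean ripple power around neocortical peak activations.

    The reverse alignment: ripple-power windows centered on optical peak
    activation times, averaged, and summarised by the FWHM amplitude of
    the mean trace.  Returns (lags, mean trace, FWHM result).
    """
    ens = extract_windows(power, peak_times, half_win)
    mean_trace = ens.mean()
    fw = fwhm_amplitude(mean_trace, ens.lags, mode="activation")
    return ens.lags, mean_trace, fw


def peak_time_map(
    z_mean: np.ndarray,
    lags: np.ndarray,
    atlas: RegionAtlas,
    search_window: tuple[float, float] = (-0.5, 0.5),
    z_thresh: float = 4.0,
) -> tuple[dict[str, float], list[str], list[str]]:
    """Per-region activation peak times from a mean peri-event stack.

    For each atlas region the mean trace over its pixels is searched for
    an activation peak within ``search_window``.  A peak counts as
    reliable when it exceeds the trace median by ``z_thresh`` robust SDs
    (1.4826 x MAD); regions without a reliable peak are reported missing
    rather than imputed.  Returns (t_p per region, regions sorted by
    ascending t_p, missing regions).
    """
    sel = (lags >= search_window[0]) & (lags <= search_window[1])
    peak_times: dict[str, float] = {}
    missing: list[str] = []
    for region in atlas.region_names:
        mask = atlas.mask(region)
        trace = z_mean[:, mask].mean(axis=1)[sel]
        med = np.median(trace)
        sigma = 1.4826 * np.median(np.abs(trace - med))
        if sigma == 0:
            sigma = trace.std()
        if sigma == 0 or (trace.max() - med) / sigma < z_thresh:
            missing.append(region)
            continue
        peak_times[region] = float(lags[sel][int(np.argmax(trace))])
    if not peak_times:
        raise ValueError("no region has a reliable activation peak")
    ordering = sorted(peak_times, key=peak_times.get)
    return peak_times, ordering, missing
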