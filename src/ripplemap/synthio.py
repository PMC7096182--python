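"""Synthetic recordings with known ground truth.

Every downstream stage of the pipeline (ripple detection, bundling,
asymmetry-index timing, peri-event mapping, optical flow, sleep scoring)
is exercised against signals produced here, where the injected events,
skews, lags, wave directions and vigilance states are known exactly.

The generators emulate the statistical structure the analyses assume —
they are deliberately not biophysical simulations:

* hippocampal LFP = 1/f^beta background noise plus Hann-windowed
  ripple-band (150-250 Hz) sinusoid bursts at scripted times, with the
  carrier phased so the deepest trough falls exactly at the event center;
* MUA = a nonnegative firing-rate trace (baseline + per-event kernel of
  two half-Gaussians with unequal areas) optionally sampled through a
  Poisson spike process; the kernel areas are solved in closed form so
  the expected asymmetry index over +-0.2 s equals a target skew;
* imaging stacks = pixel noise plus event-locked transients, either
  per-region Gaussian time courses with scripted peak-time lags, or a
  plane wave sweeping across the window at a scripted angle;
* sleep-scoring inputs = EMG with state-dependent variance and a
  hippocampal trace whose delta (1-4 Hz) and theta (6-10 Hz) content
  follows a scripted vigilance-state schedule.

All generators are deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import ImageStack, RegionAtlas, TimeSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "sample_ripple_times",
    "generate_lfp",
    "generate_mua",
    "generate_stack",
    "generate_scoring_signals",
]

# Stable per-generator RNG stream offsets so that e.g. regenerating the
# stack does not perturb the LFP noise.
_STREAMS = {"lfp": 0, "mua": 1, "stack": 2, "scoring": 3, "times": 4}


def _rng(config: "SynthConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS[stream]])
    )


@dataclass
class SynthConfig:
    """Global parameters of a synthetic session.

    ``ripple_amp`` is expressed as a multiple of the background SD
    (the background is normalised to unit SD).
    """

    duration: float
    lfp_rate: float = 2000.0
    img_rate: float = 100.0
    ripple_freq: float = 180.0
    ripple_amp: float = 8.0
    ripple_dur: float = 0.08
    noise_exponent: float = 1.0
    blip_rate: float = 0.1
    blip_dur: float = 0.015
    blip_amp: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.lfp_rate <= 0 or self.img_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if not 150.0 <= self.ripple_freq <= 250.0:
            raise ValueError("ripple_freq must lie in the 150-250 Hz band")
        if self.ripple_dur <= 0:
            raise ValueError("ripple_dur must be positive")


@dataclass
class GroundTruth:
    """Scripted events and structure injected into a synthetic session.

    ``bundle_membership`` assigns a bundle id to each ripple; ripples
    sharing an id form one bundle and must be separated by < 200 ms.
    ``mua_skew`` is the target asymmetry index of the MUA kernel per
    event, ``wave_angle`` the propagation direction per event (degrees,
    0 = lateral, 90 = anterior), ``region_lags`` the scripted per-region
    activation peak lag in seconds, and ``state_schedule`` a list of
    (start_s, end_s, state) vigilance intervals.
    """

    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bundle_membership: np.ndarray | None = None
    mua_skew: np.ndarray | None = None
    wave_angle: np.ndarray | None = None
    region_lags: dict[str, float] = field(default_factory=dict)
    state_schedule: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ripple_times = np.asarray(self.ripple_times, dtype=float)
        n = self.ripple_times.size
        if n > 1 and not np.all(np.diff(self.ripple_times) > 0):
            raise ValueError("ripple_times must be strictly increasing")
        if self.bundle_membership is None:
            self.bundle_membership = np.arange(n)
        self.bundle_membership = np.asarray(self.bundle_membership, dtype=int)
        if self.bundle_membership.size != n:
            raise ValueError("bundle_membership length mismatch")
        for bid in np.unique(self.bundle_membership):
            t = self.ripple_times[self.bundle_membership == bid]
            if t.size > 1 and np.any(np.diff(t) >= 0.200):
                raise ValueError(
                    f"bundle {bid}: members must be separated by < 200 ms"
                )
        if self.mua_skew is None:
            self.mua_skew = np.zeros(n)
        self.mua_skew = np.asarray(self.mua_skew, dtype=float)
        if self.mua_skew.size != n:
            raise ValueError("mua_skew length mismatch")
        if self.wave_angle is None:
            self.wave_angle = np.zeros(n)
        self.wave_angle = np.asarray(self.wave_angle, dtype=float) % 360.0
        if self.wave_angle.size != n:
            raise ValueError("wave_angle length mismatch")
        for name, lag in self.region_lags.items():
            if not math.isfinite(lag):
                raise ValueError(f"region lag for {name!r} must be finite")
        prev_end = None
        for start, end, state in sorted(self.state_schedule):
            if end <= start:
                raise ValueError("schedule interval must have end > start")
            if state not in {"wake", "NREM", "REM"}:
                raise ValueError(f"unknown vigilance state {state!r}")
            if prev_end is not None and start < prev_end - 1e-12:
                raise ValueError("state_schedule intervals overlap")
            prev_end = end

    @property
    def n_events(self) -> int:
        return self.ripple_times.size


def sample_ripple_times(
    config: SynthConfig,
    n_events: int,
    min_gap: float = 0.5,
    margin: float = 1.5,
    bundle_fraction: float = 0.0,
    bundle_gap: tuple[float, float] = (0.10, 0.18),
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw scripted ripple times, optionally with bundled pairs.

    Events are placed uniformly at random in ``[margin, duration-margin]``
    subject to a minimum separation ``min_gap``; a ``bundle_fraction`` of
    them receives a second ripple at a gap drawn from ``bundle_gap``
    (< 200 ms, so the pair forms one bundle).
    """
    if rng is None:
        rng = _rng(config, "times")
    lo, hi = margin, config.duration - margin
    if hi <= lo:
        raise ValueError("duration too short for the requested margin")
    times: list[float] = []
    attempts = 0
    while len(times) < n_events and attempts < 200 * max(n_events, 1):
        t = rng.uniform(lo, hi)
        if all(abs(t - s) >= min_gap for s in times):
            times.append(t)
        attempts += 1
    if len(times) < n_events:
        raise ValueError("could not place events with the requested spacing")
    times.sort()
    all_times: list[float] = []
    bundle_ids: list[int] = []
    n_bundled = int(round(bundle_fraction * n_events))
    bundled_idx = set(rng.choice(n_events, size=n_bundled, replace=False))
    for i, t in enumerate(times):
        all_times.append(t)
        bundle_ids.append(i)
        if i in bundled_idx:
            all_times.append(t + rng.uniform(*bundle_gap))
            bundle_ids.append(i)
    order = np.argsort(all_times)
    return GroundTruth(
        ripple_times=np.asarray(all_times)[order],
        bundle_membership=np.asarray(bundle_ids)[order],
    )


def _powerlaw_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, normalised to SD 1."""
    white = rng.standard_normal(n)
    if beta == 0:
        return white / white.std()
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def generate_lfp(config: SynthConfig, truth: GroundTruth) -> TimeSeries:
    """Hippocampal LFP: 1/f^beta background plus ripple bursts.

    Each burst is a Hann-windowed sinusoid at ``config.ripple_freq``
    lasting ``config.ripple_dur`` with peak amplitude
    ``config.ripple_amp`` times the background SD.  The carrier is
    ``-cos`` relative to the event time, so the largest trough — the
    detector's center definition — coincides with the scripted time.

    Real hippocampal recordings also contain brief supra-threshold
    ripple-band transients (muscle/electrical artifacts, stray
    oscillation cycles) that the detector's duration screen exists to
    remove; these are emulated as short Hann bursts of duration
    ``config.blip_dur`` at Poisson rate ``config.blip_rate``, kept at
    least 0.5 s away from every scripted ripple so they never confound
    the scripted event structure.
    """
    rate = config.lfp_rate
    n = int(round(config.duration * rate))
    rng = _rng(config, "lfp")
    lfp = _powerlaw_noise(rng, n, config.noise_exponent)

    def _add_burst(t_c: float, dur: float, amp: float) -> None:
        half = int(round(dur / 2 * rate))
        width = 2 * half + 1
        env = np.hanning(width)
        t_rel = (np.arange(width) - half) / rate
        c = int(round(t_c * rate))
        burst = -amp * env * np.cos(
            2 * np.pi * config.ripple_freq * (t_rel + (c / rate - t_c))
        )
        lo, hi = c - half, c + half + 1
        lfp[max(lo, 0):min(hi, n)] += burst[max(lo, 0) - lo:width - (hi - min(hi, n))]

    for t_c in truth.ripple_times:
        if t_c - config.ripple_dur / 2 < 0 or t_c + config.ripple_dur / 2 > config.duration:
            raise ValueError(f"ripple at {t_c} s does not fit inside the recording")
        _add_burst(t_c, config.ripple_dur, config.ripple_amp)
    if config.blip_rate > 0:
        n_blips = rng.poisson(config.blip_rate * config.duration)
        placed = 0
        for _ in range(20 * n_blips + 20):
            if placed >= n_blips:
                break
            t_b = rng.uniform(0.1, config.duration - 0.1)
            if truth.ripple_times.size and np.min(
                np.abs(truth.ripple_times - t_b)
            ) < 0.5:
                continue
            _add_burst(t_b, config.blip_dur, config.blip_amp)
            placed += 1
    return TimeSeries(lfp, rate=rate)


def _half_gaussian_kernel(
    t: np.ndarray, area_pre: float, area_post: float, sigma: float, dt: float
) -> np.ndarray:
    """Two half-Gaussians carrying the given areas within [-dt, 0) / (0, dt]."""
    # truncation correction so each side's area inside its dt window is exact
    frac = erf(dt / (sigma * math.sqrt(2.0)))
    g = np.exp(-0.5 * (t / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    k = np.where(t < 0, 2.0 * area_pre * g, 2.0 * area_post * g) / frac
    return k


def generate_mua(
    config: SynthConfig,
    truth: GroundTruth,
    baseline: float = 5.0,
    event_rate: float = 60.0,
    kernel_sigma: float = 0.05,
    dt: float = 0.2,
    sample_spikes: bool = True,
    smooth_win: float = 0.003,
) -> TimeSeries:
    """Multiunit-activity rate trace with per-event controllable skew.

    The underlying rate is ``baseline`` (spikes/s) plus, per event, a
    kernel of two half-Gaussians whose areas are solved so that the
    expected asymmetry index AI = (post - pre)/(post + pre) over the
    +-``dt`` windows (baseline included) equals ``truth.mua_skew``.
    With the window-mean excess rate M = ``event_rate`` and baseline b,
    the target is reachable only for |skew| <= M / (M + 2 b).

    If ``sample_spikes`` the rate drives an inhomogeneous Poisson spike
    count per sample, which is then boxcar-smoothed — mimicking what a
    rectified high-passed LFP would deliver.
    """
    skews = truth.mua_skew
    if np.any(np.abs(skews) > 1):
        raise ValueError("mua_skew must lie in [-1, 1]")
    reach = event_rate / (event_rate + 2 * baseline)
    if np.any(np.abs(skews) > reach + 1e-12):
        raise ValueError(
            f"target skew unreachable: |skew| <= {reach:.3f} for "
            f"baseline={baseline}, event_rate={event_rate}"
        )
    rate_hz = config.lfp_rate
    n = int(round(config.duration * rate_hz))
    rate_trace = np.full(n, float(baseline))
    half = int(round(dt * rate_hz))
    t_rel = (np.arange(2 * half + 1) - half) / rate_hz
    for t_c, s in zip(truth.ripple_times, skews):
        # window means: m_post - m_pre = s * (M + 2b), m_post + m_pre = M
        diff = s * (event_rate + 2 * baseline)
        m_post = (event_rate + diff) / 2.0
        m_pre = (event_rate - diff) / 2.0
        k = _half_gaussian_kernel(t_rel, m_pre * dt, m_post * dt, kernel_sigma, dt)
        c = int(round(t_c * rate_hz))
        lo, hi = c - half, c + half + 1
        a, b = max(lo, 0), min(hi, n)
        rate_trace[a:b] += k[a - lo:k.size - (hi - b)]
    if sample_spikes:
        rng = _rng(config, "mua")
        counts = rng.poisson(rate_trace / rate_hz)
        mua = counts * rate_hz  # back to spikes/s units
        w = max(int(round(smooth_win * rate_hz)), 1)
        mua = np.convolve(mua, np.ones(w) / w, mode="same")
    else:
        mua = rate_trace
    return TimeSeries(np.maximum(mua, 0.0), rate=rate_hz)


def generate_stack(
    config: SynthConfig,
    truth: GroundTruth,
    atlas: RegionAtlas,
    mode: str = "region_lags",
    amp: float = 1.0,
    noise_sd: float = 0.1,
    sigma_t: float = 0.05,
    dip_amp: float = 0.0,
    dip_lead: float = 0.15,
    wave_sigma: float = 6.0,
    wave_window: float = 0.25,
) -> ImageStack:
    """Imaging stack with event-locked transients.

    ``mode='region_lags'``: each region named in ``truth.region_lags``
    receives a Gaussian time course of SD ``sigma_t`` peaking at
    event_time + lag (events snapped to the nearest frame).  An optional
    pre-event deactivation dip of amplitude ``dip_amp`` leads each event
    by ``dip_lead`` seconds.

    ``mode='plane_wave'``: a Gaussian-profile wavefront (spatial SD
    ``wave_sigma`` pixels) sweeps across the window along each event's
    ``truth.wave_angle`` within +-``wave_window`` s of the event.  Axis
    convention: 0 deg = lateral (increasing column), 90 deg = anterior
    (decreasing row).
    """
    h, w = atlas.labels.shape
    rate = config.img_rate
    n = int(round(config.duration * rate))
    rng = _rng(config, "stack")
    frames = (
        rng.standard_normal((n, h, w)) * noise_sd
        if noise_sd > 0
        else np.zeros((n, h, w))
    )
    t = np.arange(n) / rate
    if mode == "region_lags":
        for region, lag in truth.region_lags.items():
            mask = atlas.mask(region)  # KeyError for unknown regions
            profile = np.zeros(n)
            for t_e in truth.ripple_times:
                t_snap = round(t_e * rate) / rate  # nearest-frame alignment
                profile += amp * np.exp(-0.5 * ((t - t_snap - lag) / sigma_t) ** 2)
                if dip_amp:
                    profile -= dip_amp * np.exp(
                        -0.5 * ((t - t_snap + dip_lead) / sigma_t) ** 2
                    )
            frames[:, mask] += profile[:, None]
    elif mode == "plane_wave":
        rows, cols = np.mgrid[0:h, 0:w]
        px = cols - (w - 1) / 2.0
        py = rows - (h - 1) / 2.0
        half_diag = math.hypot(h, w) / 2.0
        speed = (2 * half_diag + 6 * wave_sigma) / (2 * wave_window)
        for t_e, ang in zip(truth.ripple_times, truth.wave_angle):
            theta = math.radians(ang)
            dx, dy = math.cos(theta), -math.sin(theta)
            proj = dx * px + dy * py
            i0 = int(round((t_e - wave_window) * rate))
            i1 = int(round((t_e + wave_window) * rate))
            for i in range(max(i0, 0), min(i1 + 1, n)):
                pos = speed * (t[i] - t_e)
                frames[i] += amp * np.exp(-0.5 * ((proj - pos) / wave_sigma) ** 2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not np.all(np.isfinite(frames)):
        raise ValueError("generated stack contains non-finite values")
    return ImageStack(frames, rate=rate)


# state -> (EMG sd, delta gain, theta gain)
_STATE_PARAMS = {
    "wake": (1.0, 0.8, 1.0),
    "NREM": (0.3, 2.0, 0.4),
    "REM": (0.1, 0.4, 2.0),
}


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [lo, hi] Hz via FFT masking."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_scoring_signals(
    config: SynthConfig, truth: GroundTruth
) -> tuple[TimeSeries, TimeSeries]:
    """EMG and hippocampal traces following the scripted state schedule.

    EMG is rectified Gaussian noise whose SD is largest in wake, small in
    NREM, smallest in REM.  The hippocampal trace mixes delta-band
    (1-4 Hz) and theta-band (6-10 Hz) noise with state-dependent gains:
    delta dominates NREM, theta dominates REM.
    """
    schedule = sorted(truth.state_schedule)
    if not schedule:
        raise ValueError("state_schedule is empty")
    if schedule[0][0] > 1e-9 or schedule[-1][1] < config.duration - 1e-9:
        raise ValueError("state_schedule must cover [0, duration]")
    rate = config.lfp_rate
    n = int(round(config.duration * rate))
    rng = _rng(config, "scoring")
    emg_sd = np.zeros(n)
    delta_gain = np.zeros(n)
    theta_gain = np.zeros(n)
    for start, end, state in schedule:
        sl = slice(int(round(start * rate)), int(round(end * rate)))
        sd, dg, tg = _STATE_PARAMS[state]
        emg_sd[sl] = sd
        delta_gain[sl] = dg
        theta_gain[sl] = tg
    emg = np.abs(rng.standard_normal(n) * emg_sd)
    delta = _band_noise(rng, n, rate, 1.0, 4.0)
    theta = _band_noise(rng, n, rate, 6.0, 10.0)
    broadband = 0.15 * rng.standard_normal(n)
    hpc = delta_gain * delta + theta_gain * theta + broadband
    return TimeSeries(emg, rate=rate), TimeSeries(hpc, rate=rate)
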