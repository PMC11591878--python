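"""Detection and morphometry of spreading-depression waves on the DC signal.

A CSD wave appears as a multi-second negative DC excursion of several mV.
Candidates are found per channel where the 1 Hz-smoothed trace stays at least
``csd_candidate_threshold`` mV below a running (percentile) baseline for
``csd_min_duration`` seconds; the onset is then refined to the most negative
local minimum of the first time-derivative within ``onset_search_window``
before the trough (ties broken toward the latest time, i.e. the steepest part
of the depolarizing front); per-channel events co-occurring within
``csd_merge_window`` are grouped into one wave.

Morphometry follows the standard DC-shift conventions: the baseline is the
trace mean 20–10 s before the wave onset; the amplitude is the maximal
negative deflection from that baseline; the half-duration (T1/2) is the width
at half amplitude; the rise time (RT) spans the interpolated 20 % and 80 %
crossings on the depolarizing front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps

from .core import AnalysisConfig, DomainError, LAYERS, LayerMap, Session, decimate_dc

__all__ = [
    "ChannelWave",
    "CsdWave",
    "CsdSessionSummary",
    "detect_csd_waves",
    "measure_amplitude",
    "measure_baseline",
    "measure_half_duration",
    "measure_rise_time",
    "summarize_csd",
]


@dataclass
class ChannelWave:
    """Per-channel measurement of one wave."""

    channel: int
    layer: str
    onset_time: float
    trough_time: float
    baseline: float  # mV
    amplitude: float  # mV, positive magnitude
    half_duration: float  # s
    rise_time: float  # s
    truncated: bool = False
    flags: list = field(default_factory=list)


@dataclass
class CsdWave:
    """One detected spreading-depression event across the probe."""

    wave_id: int
    channels: dict[int, ChannelWave]

    @property
    def onset_time(self) -> float:
        return min(cw.onset_time for cw in self.channels.values())

    @property
    def trough_time(self) -> float:
        return min(cw.trough_time for cw in self.channels.values())

    def layers_reached(self) -> tuple[str, ...]:
        reached = {cw.layer for cw in self.channels.values()}
        return tuple(lay for lay in LAYERS if lay in reached)


# ---------------------------------------------------------------------------
# morphometry operators (1-D trace + sample interval)
# ---------------------------------------------------------------------------

def measure_baseline(
    trace: np.ndarray,
    dt: float,
    anchor_time: float,
    window: tuple[float, float] = (-20.0, -10.0),
) -> float:
    """Mean of ``trace`` over ``anchor_time + window`` (s), in mV.

    The window is anchored to the wave-onset estimate.  If it extends before
    t=0 it is shrunk with a warning, never silently."""
    a = anchor_time + window[0]
    b = anchor_time + window[1]
    if b <= 0:
        raise DomainError("baseline window entirely before the recording start")
    if a < 0:
        warnings.warn(
            f"baseline window [{a:.1f}, {b:.1f}] s shrunk to start at 0",
            stacklevel=2,
        )
        a = 0.0
    i0, i1 = int(round(a / dt)), max(int(round(a / dt)) + 1, int(round(b / dt)))
    return float(np.mean(trace[i0:i1]))


def measure_amplitude(
    trace: np.ndarray,
    dt: float,
    baseline: float,
    window: Optional[tuple[int, int]] = None,
) -> float:
    """Maximal negative deflection from ``baseline`` (positive magnitude, mV)."""
    seg = trace if window is None else trace[window[0]:window[1]]
    return float(baseline - np.min(seg))


def _cross_time(trace, dt, i, level, offset=0):
    """Linear-interpolated time of the level crossing between i-1 and i."""
    v0, v1 = trace[i - 1], trace[i]
    frac = 0.0 if v1 == v0 else (level - v0) / (v1 - v0)
    return (offset + i - 1 + frac) * dt


def measure_half_duration(
    trace: np.ndarray,
    dt: float,
    baseline: float,
    amplitude: float,
    window: Optional[tuple[int, int]] = None,
) -> tuple[float, bool]:
    """Width at half amplitude, with linear interpolation between samples.

    Returns ``(t_half, truncated)``; ``truncated`` is True when the recovery
    never re-crosses the half level inside the window (e.g. session end), in
    which case the width extends to the window edge.
    """
    i0, i1 = (0, trace.size) if window is None else window
    seg = trace[i0:i1]
    level = baseline - amplitude / 2.0
    below = seg < level
    if not np.any(below):
        raise DomainError("trace never crosses the half-amplitude level")
    down = np.flatnonzero(~below[:-1] & below[1:]) + 1
    up = np.flatnonzero(below[:-1] & ~below[1:]) + 1
    if down.size == 0:
        raise DomainError("no downward half-level crossing (truncated start)")
    t_down = _cross_time(seg, dt, down[0], level, offset=i0)
    if up.size == 0 or up[-1] < down[0]:
        return float((i1 - 1) * dt - t_down), True
    t_up = _cross_time(seg, dt, up[-1], level, offset=i0)
    return float(t_up - t_down), False


def measure_rise_time(
    trace: np.ndarray,
    dt: float,
    baseline: float,
    amplitude: float,
    trough_index: int,
    start_index: int = 0,
) -> float:
    """Time between the 20 % and 80 % crossings on the depolarizing front.

    A non-monotonic front is handled by taking the first 20 % crossing and
    the last 80 % crossing before the trough.
    """
    seg = trace[start_index:trough_index + 1]
    lvl20 = baseline - 0.2 * amplitude
    lvl80 = baseline - 0.8 * amplitude
    b20 = seg < lvl20
    b80 = seg < lvl80
    d20 = np.flatnonzero(~b20[:-1] & b20[1:]) + 1
    d80 = np.flatnonzero(~b80[:-1] & b80[1:]) + 1
    if d20.size == 0 or d80.size == 0:
        raise DomainError("front never crosses the 20 %/80 % levels")
    t20 = _cross_time(seg, dt, d20[0], lvl20, offset=start_index)
    t80 = _cross_time(seg, dt, d80[-1], lvl80, offset=start_index)
    return float(t80 - t20)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _running_baseline(x: np.ndarray, rate: float, span_s: float, q: float) -> np.ndarray:
    """Running high-percentile baseline, computed on a 1 Hz grid.

    Negative wave excursions occupy well under half of any window, so a high
    percentile tracks the resting DC level (and slow drift) through waves.
    """
    step = max(1, int(round(rate)))
    coarse = x[::step]
    size = max(3, int(round(span_s)) | 1)
    size = min(size, coarse.size if coarse.size % 2 else coarse.size + 1)
    filt = ndimage.percentile_filter(coarse, q, size=size, mode="nearest")
    idx = np.arange(x.size) / step
    return np.interp(idx, np.arange(coarse.size), filt)


def _candidate_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Contiguous True runs of at least ``min_len`` samples."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return [(a, b) for a, b in zip(starts, ends) if b - a >= min_len]


def _latest_argmin(x: np.ndarray) -> int:
    """Index of the minimum; ties broken toward the latest occurrence."""
    return x.size - 1 - int(np.argmin(x[::-1]))


def detect_csd_waves(
    session: Session,
    config: Optional[AnalysisConfig] = None,
) -> list[CsdWave]:
    """Detect spreading-depression waves on the decimated DC signal.

    Detection runs on ``t >= kcl_time``.  Returns waves ordered by earliest
    per-channel onset; an empty list (not an error) when nothing is found.
    """
    config = config or AnalysisConfig()
    if session.probe.n_sites == 0:
        raise DomainError("session has no channels")
    rate = min(config.dc_rate, session.sample_rate)
    lfp = decimate_dc(session, rate)
    dt = 1.0 / rate
    n = lfp.shape[1]

    # order-1 low-pass: under filtfilt its kernel is a positive double
    # exponential, so the step response is monotone and wave troughs are not
    # overshot (amplitude stays unbiased on plateau-shaped waves)
    sos = sps.butter(1, config.csd_lowpass_hz, btype="low", fs=rate, output="sos")
    smooth = sps.sosfiltfilt(sos, lfp, axis=1)

    # per-channel candidate troughs
    candidates: list[tuple[float, int, int, int]] = []  # (t_trough, ch, i_trough, run)
    per_channel_troughs: dict[int, list[int]] = {ch: [] for ch in range(lfp.shape[0])}
    i_kcl = int(round(session.kcl_time * rate))
    min_len = max(1, int(round(config.csd_min_duration * rate)))
    for ch in range(lfp.shape[0]):
        x = smooth[ch]
        base = _running_baseline(x, rate, config.baseline_span_s,
                                 config.baseline_percentile)
        mask = x < base - config.csd_candidate_threshold
        mask[:i_kcl] = False
        for a, b in _candidate_runs(mask, min_len):
            i_tr = a + int(np.argmin(x[a:b]))
            candidates.append((i_tr * dt, ch, i_tr, a))
            per_channel_troughs[ch].append(i_tr)

    if not candidates:
        return []
    candidates.sort()

    # group per-channel events co-occurring within the merge window
    clusters: list[list[tuple[float, int, int, int]]] = [[candidates[0]]]
    for cand in candidates[1:]:
        if cand[0] - clusters[-1][-1][0] <= config.csd_merge_window:
            clusters[-1].append(cand)
        else:
            clusters.append([cand])

    waves: list[CsdWave] = []
    search = int(round(config.onset_search_window * rate))
    for cl in clusters:
        channels: dict[int, ChannelWave] = {}
        for t_tr, ch, i_tr, _run in cl:
            flags: list[str] = []
            if ch in channels:
                flags.append("duplicate-candidate-in-wave")
                continue
            x = smooth[ch]
            # measurement window bounded by neighbouring events on this channel
            troughs = np.array(per_channel_troughs[ch])
            w0, w1 = i_tr - int(120 * rate), i_tr + int(120 * rate)
            prev = troughs[troughs < i_tr]
            nxt = troughs[troughs > i_tr]
            if prev.size:
                w0 = max(w0, (prev[-1] + i_tr) // 2)
            if nxt.size:
                w1 = min(w1, (i_tr + nxt[0]) // 2)
            w0, w1 = max(0, w0), min(n, w1)

            s0 = max(w0, i_tr - search)
            deriv = np.gradient(x[s0:i_tr + 1], dt)
            i_on = s0 + _latest_argmin(deriv)
            onset_t = i_on * dt

            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                baseline = measure_baseline(x, dt, onset_t, config.baseline_window)
            if caught:
                flags.append("baseline-window-shrunk")
            amplitude = measure_amplitude(x, dt, baseline, (w0, w1))
            half, truncated = measure_half_duration(
                x, dt, baseline, amplitude, (w0, w1)
            )
            if truncated:
                flags.append("half-duration-truncated")
            rise = measure_rise_time(x, dt, baseline, amplitude, i_tr, w0)
            channels[ch] = ChannelWave(
                channel=ch,
                layer=session.layers.layer_of(ch),
                onset_time=onset_t,
                trough_time=t_tr,
                baseline=baseline,
                amplitude=amplitude,
                half_duration=half,
                rise_time=rise,
                truncated=truncated,
                flags=flags,
            )
        if channels:
            waves.append(CsdWave(wave_id=-1, channels=channels))

    waves.sort(key=lambda w: w.onset_time)
    for i, w in enumerate(waves):
        w.wave_id = i
    return waves


# ---------------------------------------------------------------------------
# session summary
# ---------------------------------------------------------------------------

@dataclass
class CsdSessionSummary:
    """Counts, generation period and per-layer morphometry of a session."""

    n_waves: int
    generation_period_min: Optional[float]
    layer_stats: pd.DataFrame  # columns: layer, metric, mean, sem, n
    propagation: pd.DataFrame  # wave × layer bool


def _mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return float("nan"), float("nan"), 0
    sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(v)), sem, n


def summarize_csd(
    session: Session,
    waves: list[CsdWave],
    first_wave_only: bool = True,
    pool: str = "channels_then_waves",
) -> CsdSessionSummary:
    """Aggregate detected waves into session-level statistics.

    ``first_wave_only`` restricts the amplitude–temporal statistics to the
    first wave (the convention for between-animal comparison); all-wave
    aggregation is the alternative.  ``pool`` selects whether channel values
    are averaged within layer per wave first (``"channels_then_waves"``) or
    all channel measurements are pooled across waves (``"pooled"``).
    """
    if pool not in ("channels_then_waves", "pooled"):
        raise DomainError(f"unknown pooling '{pool}'")
    n_waves = len(waves)
    if n_waves == 0:
        period = None
    elif n_waves == 1:
        period = 0.0
    else:
        onsets = [w.onset_time for w in waves]
        period = (max(onsets) - min(onsets)) / 60.0

    selected = waves[:1] if first_wave_only else waves
    metrics = ("amplitude", "half_duration", "rise_time")
    rows = []
    for lay in LAYERS:
        for metric in metrics:
            if pool == "channels_then_waves":
                per_wave = []
                for w in selected:
                    vals = [getattr(cw, metric) for cw in w.channels.values()
                            if cw.layer == lay]
                    if vals:
                        per_wave.append(np.mean(vals))
                mean, sem, nn = _mean_sem(np.asarray(per_wave))
            else:
                vals = [getattr(cw, metric) for w in selected
                        for cw in w.channels.values() if cw.layer == lay]
                mean, sem, nn = _mean_sem(np.asarray(vals))
            rows.append({"layer": lay, "metric": metric, "mean": mean,
                         "sem": sem, "n": nn})
    layer_stats = pd.DataFrame(rows)
    propagation = pd.DataFrame(
        [{lay: (lay in w.layers_reached()) for lay in LAYERS} for w in waves],
        index=[w.wave_id for w in waves],
        dtype=bool,
    )
    return CsdSessionSummary(
        n_waves=n_waves,
        generation_period_min=period,
        layer_stats=layer_stats,
        propagation=propagation,
    )


def waves_to_frame(waves: list[CsdWave], layers: LayerMap) -> pd.DataFrame:
    """Flat event table (one row per wave × channel) for CSV export."""
    rows = []
    for w in waves:
        for cw in w.channels.values():
            rows.append({
                "wave_id": w.wave_id,
                "channel": cw.channel,
                "layer": cw.layer,
                "onset_s": cw.onset_time,
                "trough_s": cw.trough_time,
                "amplitude_mV": cw.amplitude,
                "t_half_s": cw.half_duration,
                "rise_time_s": cw.rise_time,
                "truncated": cw.truncated,
            })
    return pd.DataFrame(rows)
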