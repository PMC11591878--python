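"""Multi-unit activity: threshold-crossing extraction and rate statistics.

MUA is extracted from the wideband signal by zero-phase band-pass filtering
(300–3000 Hz) and detecting negative excursions beyond a multiple (default 5)
of the per-channel noise SD, which is estimated robustly (median absolute
deviation scaled to SD) on a quiet epoch before KCl application so that
bursts do not inflate the threshold.  Layer rates average the per-channel
event frequency over the channels of a layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import signal as sps

from .core import AnalysisConfig, DomainError, LAYERS, LayerMap, Session

__all__ = [
    "SpikeTrainSet",
    "detect_mua",
    "layer_rate",
    "onset_increment",
    "recovery_fraction",
    "sep_spike_rates",
]

_MAD_TO_SD = 1.0 / 0.6745


@dataclass
class SpikeTrainSet:
    """Threshold-crossing event times per channel with detection metadata."""

    events: dict[int, np.ndarray]  # channel -> sorted times (s)
    thresholds: dict[int, float]  # mV (negative-going)
    noise_sd: dict[int, float]  # mV
    band: tuple[float, float]
    dead_time_ms: float
    duration: float

    def __post_init__(self) -> None:
        dead = self.dead_time_ms / 1000.0
        for ch, t in self.events.items():
            t = np.asarray(t, dtype=float)
            if t.size > 1:
                if np.any(np.diff(t) < dead - 1e-12):
                    raise DomainError(
                        f"channel {ch} events violate the {dead*1e3:.1f} ms dead time"
                    )
            self.events[ch] = t


def detect_mua(session: Session, config: Optional[AnalysisConfig] = None) -> SpikeTrainSet:
    """Extract MUA event times from the full-rate wideband signal.

    Events are negative threshold crossings timestamped at the local minimum,
    with a dead time applied.  The noise SD is the scaled MAD of the filtered
    signal over the 60 s preceding KCl application; if that epoch is missing
    the whole recording is used with a warning.
    """
    config = config or AnalysisConfig()
    lo, hi = config.mua_band
    fs = session.sample_rate
    if fs < 2.0 * hi:
        raise DomainError(
            f"sample rate {fs} Hz too low for the {lo}-{hi} Hz MUA band"
        )
    sos = sps.butter(3, (lo, hi), btype="bandpass", fs=fs, output="sos")
    dead = int(round(config.mua_dead_time_ms / 1000.0 * fs))

    q1 = int(round(max(0.0, session.kcl_time - 60.0) * fs))
    q2 = int(round(session.kcl_time * fs))
    quiet_ok = q2 - q1 >= int(fs)
    if not quiet_ok:
        warnings.warn(
            "no quiet epoch before kcl_time; estimating noise on the whole "
            "recording", stacklevel=2,
        )

    events: dict[int, np.ndarray] = {}
    thresholds: dict[int, float] = {}
    noise_sd: dict[int, float] = {}
    for ch in range(session.probe.n_sites):
        xf = sps.sosfiltfilt(sos, session.signal[ch].astype(np.float64))
        quiet = xf[q1:q2] if quiet_ok else xf
        sd = float(np.median(np.abs(quiet - np.median(quiet))) * _MAD_TO_SD)
        thr = -config.mua_threshold_sd * sd
        noise_sd[ch] = sd
        thresholds[ch] = thr
        if sd == 0.0:
            events[ch] = np.array([])
            continue
        below = xf < thr
        starts = np.flatnonzero(~below[:-1] & below[1:]) + 1
        ends = np.flatnonzero(below[:-1] & ~below[1:]) + 1
        if below[0]:
            starts = np.r_[0, starts]
        if below[-1]:
            ends = np.r_[ends, below.size]
        peaks = np.array(
            [a + np.argmin(xf[a:b]) for a, b in zip(starts, ends)], dtype=int
        )
        if peaks.size:
            kept = [peaks[0]]
            for p in peaks[1:]:
                if p - kept[-1] >= dead:
                    kept.append(p)
            peaks = np.array(kept)
        events[ch] = peaks / fs
    return SpikeTrainSet(
        events=events,
        thresholds=thresholds,
        noise_sd=noise_sd,
        band=(lo, hi),
        dead_time_ms=config.mua_dead_time_ms,
        duration=session.duration,
    )


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def _channel_rate(times: np.ndarray, window: tuple[float, float]) -> float:
    a, b = window
    if b <= a:
        raise DomainError("window must have positive duration")
    return float(np.count_nonzero((times >= a) & (times < b)) / (b - a))


def layer_rate(
    trains: SpikeTrainSet,
    layers: LayerMap,
    window: tuple[float, float],
) -> dict[str, Optional[float]]:
    """Per-layer MUA frequency: channel count/duration averaged over the
    layer's channels.  An empty layer yields ``None`` (missing, not zero)."""
    out: dict[str, Optional[float]] = {}
    for lay in LAYERS:
        sites = [ch for ch in layers.sites(lay) if ch in trains.events]
        if not sites:
            out[lay] = None
            continue
        out[lay] = float(np.mean(
            [_channel_rate(trains.events[ch], window) for ch in sites]
        ))
    return out


def onset_increment(
    trains: SpikeTrainSet,
    onset: Union[float, "object"],
    layers: LayerMap,
    half_window: float = 10.0,
) -> dict[str, Optional[float]]:
    """MUA frequency increment at a wave onset per layer (sign preserved).

    Rate over ``[onset, onset + half_window]`` minus rate over
    ``[onset - half_window, onset]``.  ``onset`` may be a time in seconds or
    a detected wave object, in which case each channel's own onset anchors
    its windows (the wave front reaches channels at different times), with
    the wave-level onset as fallback for channels without an event.
    """
    wave_channels = getattr(onset, "channels", None)
    t_wave = float(getattr(onset, "onset_time", onset))

    def channel_onset(ch: int) -> float:
        if wave_channels is not None and ch in wave_channels:
            return float(wave_channels[ch].onset_time)
        return t_wave

    clipped = False
    out: dict[str, Optional[float]] = {}
    for lay in LAYERS:
        sites = [ch for ch in layers.sites(lay) if ch in trains.events]
        if not sites:
            out[lay] = None
            continue
        incs = []
        for ch in sites:
            t_on = channel_onset(ch)
            pre = (t_on - half_window, t_on)
            post = (t_on, t_on + half_window)
            if pre[0] < 0 or post[1] > trains.duration:
                clipped = True
                pre = (max(0.0, pre[0]), pre[1])
                post = (post[0], min(trains.duration, post[1]))
            incs.append(
                _channel_rate(trains.events[ch], post)
                - _channel_rate(trains.events[ch], pre)
            )
        out[lay] = float(np.mean(incs))
    if clipped:
        warnings.warn("onset windows clipped by session edges", stacklevel=2)
    return out


def sep_spike_rates(
    trains: SpikeTrainSet,
    stim_times: np.ndarray,
    layers: LayerMap,
    sep_onset_ms: Union[float, dict] = 5.0,
    during_ms: tuple[float, float] = (0.0, 20.0),
    after_ms: tuple[float, float] = (20.0, 520.0),
) -> tuple[dict, dict]:
    """MUA rates during (0–20 ms) and after (20–520 ms) the evoked response.

    Windows are anchored to the SEP onset: stimulus time plus ``sep_onset_ms``
    (a scalar nominal conduction delay, or a per-layer dict, e.g. measured
    onsets).  Counts are pooled across stimuli, per channel, then averaged
    within layer.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise DomainError("sep_spike_rates requires at least one stimulus")
    if not isinstance(sep_onset_ms, dict):
        sep_onset_ms = {lay: float(sep_onset_ms) for lay in LAYERS}

    def pooled(ch: int, lay: str, win_ms: tuple[float, float]) -> float:
        t = trains.events[ch]
        anchor = stim_times + sep_onset_ms[lay] / 1000.0
        a = anchor + win_ms[0] / 1000.0
        b = anchor + win_ms[1] / 1000.0
        count = sum(
            np.count_nonzero((t >= ai) & (t < bi)) for ai, bi in zip(a, b)
        )
        total = np.sum(b - a)
        return count / total

    during: dict[str, Optional[float]] = {}
    after: dict[str, Optional[float]] = {}
    for lay in LAYERS:
        sites = [ch for ch in layers.sites(lay) if ch in trains.events]
        if not sites:
            during[lay] = after[lay] = None
            continue
        during[lay] = float(np.mean([pooled(ch, lay, during_ms) for ch in sites]))
        after[lay] = float(np.mean([pooled(ch, lay, after_ms) for ch in sites]))
    return during, after


def recovery_fraction(
    trains: SpikeTrainSet,
    layers: LayerMap,
    reference_window: tuple[float, float],
    probe_window: tuple[float, float],
) -> dict[str, Optional[float]]:
    """Post/pre MUA rate per layer in percent (100 % = full recovery).

    ``reference_window`` should lie before KCl application; ``probe_window``
    is typically a minute starting 5 min after the last wave.  A zero
    reference rate yields ``None`` (undefined, reported missing).
    """
    ref = layer_rate(trains, layers, reference_window)
    post = layer_rate(trains, layers, probe_window)
    out: dict[str, Optional[float]] = {}
    for lay in LAYERS:
        if ref[lay] is None or post[lay] is None or ref[lay] == 0.0:
            out[lay] = None
        else:
            out[lay] = 100.0 * post[lay] / ref[lay]
    return out
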