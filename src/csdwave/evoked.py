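"""Sensory evoked potentials: depth profiles, source-density maps, recovery.

A whisker deflection evokes a short-latency negative LFP trough (the SEP) in
the barrel column.  Per channel, the profile measures the trough amplitude
(µV), the latency from stimulus to trough, and the onset where the response
front leaves a ±2 SD noise band of the pre-stimulus residual.  The
current-source-density map is the (sign-flipped) second spatial difference of
the baseline-subtracted average LFP along the probe, so current sinks are
negative; the most superficial and deepest sites have no interior neighbours
and are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AnalysisConfig, DomainError, LAYERS, LayerMap, Session, decimate_dc

__all__ = [
    "EvokedAverage",
    "SepChannel",
    "SepProfile",
    "SourceDensityMap",
    "average_sep",
    "measure_sep",
    "principal_whisker",
    "sep_recovery_timeline",
    "source_density",
]

logger = logging.getLogger(__name__)


@dataclass
class EvokedAverage:
    """Stimulus-triggered mean LFP, baseline-subtracted per channel."""

    data: np.ndarray  # [site, time] mV
    times_ms: np.ndarray  # relative to the stimulus
    dc_rate: float
    n_stimuli: int
    n_excluded: int


@dataclass
class SepChannel:
    channel: int
    layer: str
    responsive: bool
    onset_ms: Optional[float] = None
    peak_latency_ms: Optional[float] = None
    amplitude_uv: Optional[float] = None


@dataclass
class SepProfile:
    """Per-channel SEP metrics with per-layer mean ± SEM."""

    channels: list[SepChannel]
    layer_stats: pd.DataFrame  # layer, metric, mean, sem, n
    n_stimuli: int
    principal_whisker: bool = False

    def best_amplitude(self) -> Optional[float]:
        vals = [c.amplitude_uv for c in self.channels if c.responsive]
        return max(vals) if vals else None

    def best_latency(self) -> Optional[float]:
        vals = [c.peak_latency_ms for c in self.channels if c.responsive]
        return min(vals) if vals else None


@dataclass
class SourceDensityMap:
    """Second-spatial-derivative map over interior sites (sinks negative)."""

    data: np.ndarray  # [interior site, time]
    times_ms: np.ndarray
    interior_sites: np.ndarray
    sink_negative: bool
    units: str = "mV/mm^2"


def average_sep(
    session: Session,
    stim_times: Optional[Sequence[float]] = None,
    config: Optional[AnalysisConfig] = None,
    window_ms: tuple[float, float] = (-1000.0, 100.0),
    exclude_spans: Optional[Sequence[tuple[float, float]]] = None,
) -> EvokedAverage:
    """Stimulus-triggered average LFP with the 1 s pre-stimulus mean removed.

    ``exclude_spans`` (e.g. trough-to-recovery spans of detected CSD waves)
    drops stimuli falling inside them; the excluded count is reported.
    """
    config = config or AnalysisConfig()
    stim = np.asarray(
        session.stim_times if stim_times is None else stim_times, dtype=float
    )
    if stim.size == 0:
        raise DomainError("average_sep requires at least one stimulus")
    if window_ms[0] > -1000.0:
        raise DomainError("window must cover 1 s pre-stimulus for the baseline")
    rate = min(config.dc_rate, session.sample_rate)
    lfp = decimate_dc(session, rate)
    n = lfp.shape[1]
    i_pre = int(round(-window_ms[0] / 1000.0 * rate))
    i_post = int(round(window_ms[1] / 1000.0 * rate))

    n_excluded = 0
    epochs = []
    for st in stim:
        if exclude_spans and any(a <= st <= b for a, b in exclude_spans):
            n_excluded += 1
            continue
        c = int(round(st * rate))
        if c - i_pre < 0 or c + i_post + 1 > n:
            n_excluded += 1
            continue
        epochs.append(lfp[:, c - i_pre:c + i_post + 1])
    if not epochs:
        raise DomainError("no usable stimuli after exclusion")
    avg = np.mean(epochs, axis=0)
    i_bsl = int(round(1.0 * rate))  # 1 s segment right before the stimulus
    avg = avg - np.mean(avg[:, i_pre - i_bsl:i_pre], axis=1, keepdims=True)
    times_ms = (np.arange(-i_pre, i_post + 1) / rate) * 1000.0
    return EvokedAverage(
        data=avg,
        times_ms=times_ms,
        dc_rate=rate,
        n_stimuli=len(epochs),
        n_excluded=n_excluded,
    )


def _mean_sem(vals: list[float]) -> tuple[float, float, int]:
    v = np.asarray(vals, dtype=float)
    n = v.size
    if n == 0:
        return float("nan"), float("nan"), 0
    sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(v)), sem, n


def measure_sep(
    avg: EvokedAverage,
    layers: LayerMap,
    config: Optional[AnalysisConfig] = None,
) -> SepProfile:
    """Trough amplitude, latency and onset per channel of an averaged SEP.

    The peak is the most negative sample within ``sep_peak_window`` ms after
    the stimulus; the amplitude is its magnitude in µV; the onset is the last
    pre-peak time at which the trace sits inside the noise band (±2 × the
    pre-stimulus residual SD) before heading into the trough.  A channel with
    no trough beyond the noise band is marked non-responsive (missing, not
    zero).
    """
    config = config or AnalysisConfig()
    post = (avg.times_ms > 0) & (avg.times_ms <= config.sep_peak_window)
    pre = avg.times_ms < 0
    channels: list[SepChannel] = []
    for ch in range(avg.data.shape[0]):
        v = avg.data[ch]
        band = 2.0 * float(np.std(v[pre])) + 1e-12
        vp = v[post]
        i_min = int(np.argmin(vp))
        trough = vp[i_min]
        lay = layers.layer_of(ch)
        if trough >= -band:
            channels.append(SepChannel(channel=ch, layer=lay, responsive=False))
            continue
        t_post = avg.times_ms[post]
        latency = float(t_post[i_min])
        amplitude = float(-trough * 1000.0)  # mV -> µV
        # onset: last time before the trough still inside the noise band
        i_peak_global = np.flatnonzero(post)[i_min]
        pre_peak = v[:i_peak_global]
        inside = np.flatnonzero(pre_peak >= -band)
        onset = float(avg.times_ms[inside[-1]]) if inside.size else None
        channels.append(SepChannel(
            channel=ch, layer=lay, responsive=True,
            onset_ms=onset, peak_latency_ms=latency, amplitude_uv=amplitude,
        ))

    rows = []
    for lay in LAYERS:
        resp = [c for c in channels if c.layer == lay and c.responsive]
        for metric, attr in (("latency_ms", "peak_latency_ms"),
                             ("amplitude_uv", "amplitude_uv")):
            mean, sem, n = _mean_sem([getattr(c, attr) for c in resp])
            rows.append({"layer": lay, "metric": metric, "mean": mean,
                         "sem": sem, "n": n})
    return SepProfile(
        channels=channels,
        layer_stats=pd.DataFrame(rows),
        n_stimuli=avg.n_stimuli,
    )


def principal_whisker(profiles: dict) -> object:
    """Identify the principal vibrissa among candidate whisker profiles.

    The principal whisker produces the largest-amplitude, shortest-latency
    response.  Candidates may be :class:`SepProfile` objects (their best
    responsive channel is used) or ``(amplitude_uv, latency_ms)`` pairs.
    Amplitude decides; equal amplitudes fall back to the shorter latency; a
    conflict between the amplitude and latency winners is resolved in favour
    of amplitude with a logged warning.
    """
    if not profiles:
        raise DomainError("no candidate whiskers")

    def amp_lat(p):
        if isinstance(p, SepProfile):
            return p.best_amplitude(), p.best_latency()
        a, l = p
        return float(a), float(l)

    items = {k: amp_lat(p) for k, p in profiles.items()}
    by_amp = max(items, key=lambda k: (items[k][0], -items[k][1]))
    by_lat = min(items, key=lambda k: (items[k][1], -items[k][0]))
    if by_amp != by_lat:
        logger.warning(
            "principal-whisker conflict: amplitude favours %r, latency %r; "
            "choosing by amplitude", by_amp, by_lat,
        )
    return by_amp


def source_density(
    avg: Union[EvokedAverage, np.ndarray],
    site_spacing_um: float,
    sink_negative: bool = True,
    times_ms: Optional[np.ndarray] = None,
) -> SourceDensityMap:
    """Second spatial derivative of the averaged LFP along the probe.

    For each interior site i the second difference
    ``(V[i-1] - 2 V[i] + V[i+1]) / h²`` is formed per time sample on the
    baseline-subtracted average; by default the sign is flipped so that
    current sinks (local negative LFP curvature maxima) come out negative,
    matching the standard definition ``-σ ∂²φ/∂z²`` up to the conductivity
    factor.  ``sink_negative=False`` yields the plain second difference.
    Output units are mV/mm².
    """
    if isinstance(avg, EvokedAverage):
        data, times_ms = avg.data, avg.times_ms
    else:
        data = np.asarray(avg, dtype=float)
        if times_ms is None:
            times_ms = np.arange(data.shape[1], dtype=float)
    if data.shape[0] < 3:
        raise DomainError("source density needs at least 3 sites")
    if site_spacing_um <= 0:
        raise DomainError("site spacing must be positive and uniform")
    h_mm = site_spacing_um / 1000.0
    d2 = (data[:-2] - 2.0 * data[1:-1] + data[2:]) / h_mm**2
    if sink_negative:
        d2 = -d2
    return SourceDensityMap(
        data=d2,
        times_ms=np.asarray(times_ms),
        interior_sites=np.arange(1, data.shape[0] - 1),
        sink_negative=sink_negative,
    )


# ---------------------------------------------------------------------------
# recovery timeline
# ---------------------------------------------------------------------------

@dataclass
class RecoveryTimeline:
    """SEP amplitude vs. time as % of the pre-KCl reference, per layer."""

    bin_centers_s: np.ndarray
    percent: dict[str, np.ndarray]  # layer -> % per bin (NaN where no stim)
    checkpoints: dict[float, dict[str, float]]  # minutes after last wave
    reference_uv: dict[str, float]
    last_wave_onset: float


def _single_trial_amplitudes(
    session: Session,
    stim: np.ndarray,
    config: AnalysisConfig,
    layers: LayerMap,
) -> dict[str, np.ndarray]:
    """Per-stimulus SEP amplitude (µV) averaged over each layer's channels."""
    rate = min(config.dc_rate, session.sample_rate)
    lfp = decimate_dc(session, rate)
    n = lfp.shape[1]
    i_pre = int(round(1.0 * rate))
    i_post = int(round(config.sep_peak_window / 1000.0 * rate))
    out = {lay: np.full(stim.size, np.nan) for lay in LAYERS}
    site_idx = {lay: layers.sites(lay) for lay in LAYERS}
    for k, st in enumerate(stim):
        c = int(round(st * rate))
        if c - i_pre < 0 or c + i_post + 1 > n:
            continue
        seg = lfp[:, c - i_pre:c + i_post + 1]
        bsl = np.mean(seg[:, :i_pre], axis=1, keepdims=True)
        amp_uv = -(np.min(seg[:, i_pre + 1:] - bsl, axis=1)) * 1000.0
        for lay in LAYERS:
            if site_idx[lay].size:
                out[lay][k] = float(np.mean(amp_uv[site_idx[lay]]))
    return out


def sep_recovery_timeline(
    session: Session,
    waves: Sequence,
    stim_times: Optional[Sequence[float]] = None,
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 60.0,
    checkpoints_min: tuple[float, ...] = (5.0, 30.0),
) -> RecoveryTimeline:
    """Track SEP amplitude through recurrent CSD as % of the pre-KCl mean.

    Per-stimulus amplitudes (suppression-phase responses are measured, not
    excluded) are binned at ``bin_s``; recovery checkpoints report the mean
    over ``[t_last + c, t_last + c + bin_s]`` for each checkpoint ``c``
    minutes after the last wave onset.  Raises when no pre-KCl stimuli exist
    to define the reference.
    """
    config = config or AnalysisConfig()
    if not waves:
        raise DomainError("recovery timeline requires at least one wave")
    stim = np.asarray(
        session.stim_times if stim_times is None else stim_times, dtype=float
    )
    pre_mask = stim < session.kcl_time
    if not np.any(pre_mask):
        raise DomainError("no pre-KCl stimuli to define the reference level")
    amps = _single_trial_amplitudes(session, stim, config, session.layers)
    reference = {
        lay: float(np.nanmean(amps[lay][pre_mask])) for lay in LAYERS
    }
    t_last = max(float(getattr(w, "onset_time", w)) for w in waves)

    edges = np.arange(0.0, session.duration + bin_s, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    percent: dict[str, np.ndarray] = {}
    for lay in LAYERS:
        ref = reference[lay]
        vals = np.full(centers.size, np.nan)
        if ref and np.isfinite(ref):
            idx = np.digitize(stim, edges) - 1
            for b in range(centers.size):
                sel = amps[lay][idx == b]
                sel = sel[np.isfinite(sel)]
                if sel.size:
                    vals[b] = 100.0 * np.mean(sel) / ref
        percent[lay] = vals

    checkpoints: dict[float, dict[str, float]] = {}
    for c in checkpoints_min:
        a = t_last + c * 60.0
        b = a + bin_s
        row = {}
        for lay in LAYERS:
            ref = reference[lay]
            sel = amps[lay][(stim >= a) & (stim < b)]
            sel = sel[np.isfinite(sel)]
            row[lay] = (
                float(100.0 * np.mean(sel) / ref)
                if sel.size and ref and np.isfinite(ref)
                else float("nan")
            )
        checkpoints[c] = row
    return RecoveryTimeline(
        bin_centers_s=centers,
        percent=percent,
        checkpoints=checkpoints,
        reference_uv=reference,
        last_wave_onset=t_last,
    )
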