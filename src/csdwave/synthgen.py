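"""Seeded generator of synthetic laminar sessions with known ground truth.

The generator emulates what a 16-site DC-coupled laminar probe sees during
2 h of recurrent KCl-evoked spreading depression: per-layer DC wave excursions
with controllable amplitude / half-duration / rise time and layer-limited
propagation, whisker-evoked LFP templates locked to a stimulus schedule,
multi-unit spiking (background, onset burst, post-wave suppression with
partial recovery) rendered as brief negative transients, plus Gaussian
wideband noise and slow DC drift.  Every measurable quantity the analysis
pipeline reports has a corresponding ground-truth entry.

The default CSD waveform family is piecewise linear with a plateau,
constructed so that the morphometry operators applied to the noiseless
waveform return exactly the generator parameters:

* descent is a linear ramp of duration ``rise_time / 0.6`` (the 20–80 % span
  of a linear ramp is 0.6 of its duration),
* the plateau at ``-amplitude`` plus a symmetric linear recovery make the
  width at half amplitude equal ``half_duration``.

A smooth sigmoid-flank family is available (``family="sigmoid"``) without the
exact-inversion guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core import (
    LAYERS,
    DomainError,
    ProbeGeometry,
    Session,
    assign_layers,
)
from .lesion import LesionStack

__all__ = [
    "GeneratorConfig",
    "LesionSpec",
    "WaveSpec",
    "control_preset",
    "hhcy_preset",
    "generate_lesion_stack",
    "generate_session",
    "generate_spike_train",
    "make_csd_waveform",
]


def _per_layer(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to all layers; validate a dict has every layer."""
    if isinstance(value, dict):
        missing = set(LAYERS) - set(value)
        if missing:
            raise DomainError(f"{name} missing layers {sorted(missing)}")
        return {k: float(value[k]) for k in LAYERS}
    return {k: float(value) for k in LAYERS}


@dataclass
class WaveSpec:
    """One scheduled CSD wave: start time and the layers it reaches."""

    t_start: float
    reach: tuple[str, ...] = LAYERS


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic session.

    Wave morphometry (`csd_*`), evoked-potential templates (`sep_*`) and
    spiking rates are per-layer dicts keyed by ``{"L2/3", "L4", "L5/6"}``
    (scalars broadcast).  Spike trains are Poisson with a hard minimum ISI
    (``min_isi``) and intensity compensated so the realized rate equals the
    nominal rate in expectation.
    """

    duration: float = 7200.0
    sample_rate: float = 32000.0
    n_sites: int = 16
    site_spacing: float = 100.0
    tip_depth: float = 1700.0
    layer_boundaries: tuple[float, float] = (600.0, 1000.0)
    kcl_time: float = 180.0

    # CSD waves
    waves: list[WaveSpec] = field(default_factory=list)
    csd_amplitude: dict | float = field(
        default_factory=lambda: {"L2/3": 8.8, "L4": 12.9, "L5/6": 16.7}
    )  # mV
    csd_half_duration: dict | float = field(
        default_factory=lambda: {"L2/3": 23.2, "L4": 25.6, "L5/6": 19.01}
    )  # s
    csd_rise_time: dict | float = field(
        default_factory=lambda: {"L2/3": 3.2, "L4": 4.1, "L5/6": 5.4}
    )  # s
    waveform_family: str = "plinear"
    propagation_delay_per_site: float = 0.3  # s per 100 µm, top to bottom
    min_wave_separation: float = 60.0

    # sensory evoked potentials
    sep_amplitude_uv: Optional[dict] = None
    sep_peak_ms: Optional[dict] = None
    sep_onset_ms: Optional[dict] = None
    stim_times: Optional[Sequence[float]] = None
    stim_interval: tuple[float, float] = (5.0, 10.0)
    stim_start: float = 10.0
    sep_suppression_fraction: float = 0.0
    sep_recovery_tau: float = 90.0  # s

    # spiking
    background_rate: dict | float = 0.0  # 1/s per layer
    onset_burst_rate: dict | float = 0.0  # added 1/s during the burst
    burst_duration: float = 10.0  # s from the wave front
    suppression_fraction: float = 0.0
    recovery_tau: float = 120.0  # s
    sep_during_extra: dict | float = 0.0  # added 1/s in the during-SEP window
    sep_after_extra: dict | float = 0.0
    sep_window_during_ms: tuple[float, float] = (0.0, 20.0)
    sep_window_after_ms: tuple[float, float] = (20.0, 520.0)
    min_isi: float = 0.002  # s, hard minimum inter-spike interval
    spike_amp_mult: float = 8.0  # spike amplitude as multiple of noise SD
    spike_amp_floor: float = 0.05  # mV, used when noise_sd == 0

    # noise
    noise_sd: float = 0.2  # mV, Gaussian wideband
    drift_sd: float = 0.3  # mV, slow DC drift (30 s knots)
    seed: int = 0

    def validate(self) -> None:
        amp = _per_layer(self.csd_amplitude, "csd_amplitude")
        half = _per_layer(self.csd_half_duration, "csd_half_duration")
        rise = _per_layer(self.csd_rise_time, "csd_rise_time")
        for lay in LAYERS:
            if amp[lay] <= 0:
                raise DomainError(f"amplitude must be positive in {lay}")
            if not (0 < rise[lay] and rise[lay] / 0.6 <= half[lay]):
                raise DomainError(
                    f"need 0 < rise_time <= 0.6*half_duration in {lay}"
                )
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise DomainError("suppression_fraction must be in [0, 1]")
        if not 0.0 <= self.sep_suppression_fraction <= 1.0:
            raise DomainError("sep_suppression_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise DomainError("noise SDs must be non-negative")
        onsets = [w.t_start for w in self.waves]
        if onsets != sorted(onsets):
            raise DomainError("wave onsets must be sorted")
        if any(b - a < self.min_wave_separation
               for a, b in zip(onsets, onsets[1:])):
            raise DomainError(
                f"wave onsets closer than {self.min_wave_separation} s"
            )
        # full wave span: descent + plateau + recovery = descent + T1/2
        span = max(rise[l] / 0.6 + half[l] for l in LAYERS)
        delay = (self.n_sites - 1) * self.propagation_delay_per_site
        if onsets and onsets[-1] + delay + span > self.duration:
            raise DomainError("wave schedule exceeds the session duration")
        if onsets and onsets[0] < 0:
            raise DomainError("wave onset before t=0")


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def plinear_segments(amplitude: float, half_duration: float, rise_time: float):
    """Breakpoints ``(times, values)`` of the piecewise-linear wave family.

    Times are relative to the descent start.  Descent duration is
    ``rise_time/0.6``; the plateau makes the half-amplitude width equal
    ``half_duration``; the recovery ramp mirrors the descent.
    """
    if amplitude <= 0:
        raise DomainError("amplitude must be positive")
    if rise_time <= 0:
        raise DomainError("rise_time must be positive")
    descent = rise_time / 0.6
    plateau = half_duration - descent
    if plateau < 0:
        raise DomainError(
            "rise_time too long for half_duration (need rise_time <= "
            "0.6 * half_duration)"
        )
    times = np.array([0.0, descent, descent + plateau, 2 * descent + plateau])
    values = np.array([0.0, -amplitude, -amplitude, 0.0])
    return times, values


def make_csd_waveform(
    amplitude: float,
    half_duration: float,
    rise_time: float,
    dc_rate: float,
    lead: float = 30.0,
    tail: float = 10.0,
    family: str = "plinear",
) -> np.ndarray:
    """Single-channel noiseless CSD waveform sampled at ``dc_rate``.

    Baseline 0 mV, trough ``-amplitude``; the morphometry operators recover
    ``(amplitude, half_duration, rise_time)`` exactly (to interpolation
    precision) for the default piecewise-linear family.  The wave descent
    starts at ``t = lead`` seconds.
    """
    if family == "plinear":
        bt, bv = plinear_segments(amplitude, half_duration, rise_time)
        n = int(round((lead + bt[-1] + tail) * dc_rate))
        t = np.arange(n) / dc_rate
        return np.interp(t, bt + lead, bv)
    if family == "sigmoid":
        if not (0 < rise_time and rise_time / 0.6 <= half_duration):
            raise DomainError("need 0 < rise_time <= 0.6*half_duration")
        tau_r = rise_time / math.log(16.0)  # 20->80 % span of a logistic
        tau_f = 2.0 * tau_r
        t_mid = lead + rise_time / 0.6 / 2
        t_fall = t_mid + half_duration
        n = int(round((t_fall + 6 * tau_f + tail) * dc_rate))
        t = np.arange(n) / dc_rate
        v = -amplitude / (
            (1 + np.exp(-(t - t_mid) / tau_r)) * (1 + np.exp((t - t_fall) / tau_f))
        )
        return v
    raise DomainError(f"unknown waveform family '{family}'")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def generate_spike_train(
    rate: float,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    min_isi: float = 0.002,
    t_prev: Optional[float] = None,
) -> list[float]:
    """Dead-time-modified Poisson spike times on ``[t0, t1)``.

    ISIs are ``min_isi + Exp(lambda_e)`` with ``lambda_e = r / (1 - r*min_isi)``
    so the mean ISI is exactly ``1/r`` (realized rate unbiased for the nominal
    rate).  ``t_prev`` carries the dead time across segment boundaries.
    """
    if rate <= 0:
        return []
    if rate * min_isi >= 0.95:
        raise DomainError(
            f"rate {rate}/s incompatible with min_isi {min_isi}s"
        )
    lam_e = rate / (1.0 - rate * min_isi)
    out: list[float] = []
    t = t0 if t_prev is None else max(t0, t_prev + min_isi)
    t = t + rng.exponential(1.0 / lam_e)
    while t < t1:
        out.append(t)
        t += min_isi + rng.exponential(1.0 / lam_e)
    return out


def _rate_segments(edges: np.ndarray, rate_fn) -> list[tuple[float, float, float]]:
    """Piecewise-constant (start, end, rate) segments from sorted edges."""
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        segs.append((a, b, float(rate_fn(0.5 * (a + b)))))
    return segs


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _draw_stims(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.stim_times is not None:
        return np.asarray(config.stim_times, dtype=float)
    needs_stims = config.sep_amplitude_uv is not None or np.any(
        [v for v in _per_layer(config.sep_during_extra, "sep_during_extra").values()]
    )
    if not needs_stims:
        return np.array([])
    lo, hi = config.stim_interval
    times = []
    t = config.stim_start
    while t < config.duration - 1.0:
        times.append(t)
        t += rng.uniform(lo, hi)
    return np.asarray(times)


def _sep_multiplier(t: float, wave_starts: np.ndarray, frac: float, tau: float) -> float:
    """Evoked-response suppression factor at time ``t`` (1 = unaffected)."""
    if frac <= 0 or wave_starts.size == 0:
        return 1.0
    past = wave_starts[wave_starts <= t]
    if past.size == 0:
        return 1.0
    return 1.0 - frac * math.exp(-(t - past[-1]) / tau)


def generate_session(config: GeneratorConfig) -> Session:
    """Render a synthetic session; identical seeds give identical output."""
    config.validate()
    probe = ProbeGeometry(config.n_sites, config.site_spacing, config.tip_depth)
    layers = assign_layers(probe, config.layer_boundaries)
    fs = config.sample_rate
    n = int(round(config.duration * fs))

    amp = _per_layer(config.csd_amplitude, "csd_amplitude")
    half = _per_layer(config.csd_half_duration, "csd_half_duration")
    rise = _per_layer(config.csd_rise_time, "csd_rise_time")
    bg = _per_layer(config.background_rate, "background_rate")
    burst = _per_layer(config.onset_burst_rate, "onset_burst_rate")
    sep_during = _per_layer(config.sep_during_extra, "sep_during_extra")
    sep_after = _per_layer(config.sep_after_extra, "sep_after_extra")

    ss = np.random.SeedSequence([int(config.seed), 0x5EED])
    children = ss.spawn(2 + 3 * config.n_sites)
    stim_rng = np.random.default_rng(children[0])
    stim_times = _draw_stims(config, stim_rng)

    wave_starts = np.array([w.t_start for w in config.waves])
    spike_amp = (
        config.spike_amp_mult * config.noise_sd
        if config.noise_sd > 0
        else config.spike_amp_floor
    )
    kern_len = max(4, int(round(fs * 0.001)))
    kern = -np.sin(2 * np.pi * np.arange(kern_len) / kern_len)

    signal = np.zeros((config.n_sites, n), dtype=np.float32)
    gt_waves = [
        {
            "t_start": float(w.t_start),
            "reach": list(w.reach),
            "channel_onsets": {},
            "channel_fronts": {},
        }
        for w in config.waves
    ]
    gt_spikes: dict[int, list[float]] = {}

    for ch in range(config.n_sites):
        lay = layers.layer_of(ch)
        noise_rng = np.random.default_rng(children[2 + 3 * ch])
        drift_rng = np.random.default_rng(children[2 + 3 * ch + 1])
        spike_rng = np.random.default_rng(children[2 + 3 * ch + 2])
        buf = np.zeros(n, dtype=np.float64)

        if config.noise_sd > 0:
            buf += noise_rng.normal(0.0, config.noise_sd, n)
        if config.drift_sd > 0:
            knot_t = np.arange(0.0, config.duration + 30.0, 30.0)
            knots = drift_rng.normal(0.0, config.drift_sd, knot_t.size)
            buf += np.interp(np.arange(n) / fs, knot_t, knots)

        # CSD waves: per-channel onset delay along the probe, layer-limited
        descent = rise[lay] / 0.6
        suppression_starts = []
        for iw, w in enumerate(config.waves):
            if lay not in w.reach:
                continue
            t_ch = w.t_start + ch * config.propagation_delay_per_site
            front = t_ch + descent
            gt_waves[iw]["channel_onsets"][ch] = t_ch
            gt_waves[iw]["channel_fronts"][ch] = front
            suppression_starts.append(front + config.burst_duration)
            if config.waveform_family == "plinear":
                bt, bv = plinear_segments(amp[lay], half[lay], rise[lay])
                i0 = int(np.floor(t_ch * fs))
                i1 = min(n, int(np.ceil((t_ch + bt[-1]) * fs)) + 1)
                tt = np.arange(i0, i1) / fs
                buf[i0:i1] += np.interp(tt, bt + t_ch, bv)
            else:
                wv = make_csd_waveform(
                    amp[lay], half[lay], rise[lay], fs,
                    lead=0.0, tail=0.0, family=config.waveform_family,
                )
                i0 = int(np.floor(t_ch * fs))
                i1 = min(n, i0 + wv.size)
                buf[i0:i1] += wv[: i1 - i0]

        # evoked templates locked to stimuli, scaled by post-wave suppression
        if config.sep_amplitude_uv is not None:
            sep_amp = _per_layer(config.sep_amplitude_uv, "sep_amplitude_uv")
            sep_peak = _per_layer(config.sep_peak_ms, "sep_peak_ms")
            sep_onset = (
                _per_layer(config.sep_onset_ms, "sep_onset_ms")
                if config.sep_onset_ms is not None
                else {k: max(0.5, v - 5.0) for k, v in sep_peak.items()}
            )
            w_ms = sep_peak[lay] - sep_onset[lay]
            if w_ms <= 0:
                raise DomainError("sep_peak_ms must exceed sep_onset_ms")
            a_mv = sep_amp[lay] / 1000.0
            for st in stim_times:
                m = _sep_multiplier(
                    st, wave_starts, config.sep_suppression_fraction,
                    config.sep_recovery_tau,
                )
                on = st + sep_onset[lay] / 1000.0
                i0 = int(np.ceil(on * fs))
                i1 = min(n, int(np.floor((on + 2 * w_ms / 1000.0) * fs)) + 1)
                if i1 <= i0:
                    continue
                tt = np.arange(i0, i1) / fs - on
                buf[i0:i1] += (
                    -m * a_mv / 2.0
                    * (1 - np.cos(np.pi * tt / (w_ms / 1000.0)))
                )

        # spiking: piecewise-constant inhomogeneous rate with dead time
        has_spikes = (
            bg[lay] > 0
            or (burst[lay] > 0 and suppression_starts)
            or sep_during[lay] > 0
            or sep_after[lay] > 0
        )
        if has_spikes:
            edges = {0.0, config.duration}
            burst_windows = []
            for iw, w in enumerate(config.waves):
                if lay not in w.reach or burst[lay] <= 0:
                    continue
                f = gt_waves[iw]["channel_fronts"].get(ch)
                if f is None:
                    continue
                burst_windows.append((f, min(config.duration, f + config.burst_duration)))
                edges.update(burst_windows[-1])
            sup_starts = np.array(sorted(suppression_starts))
            if config.suppression_fraction > 0 and sup_starts.size:
                edges.update(
                    np.arange(sup_starts[0], config.duration, 1.0).tolist()
                )
            sep_windows = {"during": [], "after": []}
            for st in stim_times:
                for key, (w0, w1) in (
                    ("during", config.sep_window_during_ms),
                    ("after", config.sep_window_after_ms),
                ):
                    a = st + w0 / 1000.0
                    b = min(config.duration, st + w1 / 1000.0)
                    if sep_during[lay] > 0 or sep_after[lay] > 0:
                        sep_windows[key].append((a, b))
                        edges.update((a, b))
            edges = np.array(sorted(e for e in edges if 0 <= e <= config.duration))

            def rate_fn(t: float) -> float:
                r = bg[lay]
                if config.suppression_fraction > 0 and sup_starts.size:
                    past = sup_starts[sup_starts <= t]
                    if past.size:
                        r *= 1.0 - config.suppression_fraction * math.exp(
                            -(t - past[-1]) / config.recovery_tau
                        )
                for a, b in burst_windows:
                    if a <= t < b:
                        r += burst[lay]
                for a, b in sep_windows["during"]:
                    if a <= t < b:
                        r += sep_during[lay]
                for a, b in sep_windows["after"]:
                    if a <= t < b:
                        r += sep_after[lay]
                return r

            times: list[float] = []
            t_prev: Optional[float] = None
            for a, b, r in _rate_segments(edges, rate_fn):
                new = generate_spike_train(
                    r, a, b, spike_rng, config.min_isi, t_prev
                )
                if new:
                    times.extend(new)
                    t_prev = new[-1]
                elif times:
                    t_prev = times[-1]
            ch_gt = []
            for t_sp in times:
                i0 = int(round(t_sp * fs))
                if i0 >= n:
                    continue
                i1 = min(n, i0 + kern_len)
                buf[i0:i1] += spike_amp * kern[: i1 - i0]
                ch_gt.append((i0 + kern_len / 4.0) / fs)  # negative-lobe peak
            gt_spikes[ch] = ch_gt

        signal[ch] = buf

    cfg_dict = asdict(config)
    cfg_dict["waves"] = [
        {"t_start": w.t_start, "reach": list(w.reach)} for w in config.waves
    ]
    ground_truth = {
        "config": cfg_dict,
        "stim_times": stim_times.tolist(),
        "waves": gt_waves,
        "spike_times": {str(k): v for k, v in gt_spikes.items()},
        "spike_amplitude_mv": spike_amp,
    }
    return Session(
        signal=signal,
        sample_rate=fs,
        probe=probe,
        layers=layers,
        stim_times=stim_times,
        kcl_time=config.kcl_time,
        duration=config.duration,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# presets encoding the two experimental groups
# ---------------------------------------------------------------------------

def _fit_schedule(duration: float, first_onset: float, n_waves: int,
                  period_min: float, margin: float):
    """Scale a preset wave schedule down to a short session.

    Keeps the wave density of the full-length preset; the margin leaves room
    for the last wave to complete (propagation delay + wave span)."""
    avail = duration - first_onset - margin
    if n_waves and avail <= 0:
        raise DomainError(
            f"duration {duration}s too short for waves starting at "
            f"{first_onset}s"
        )
    if n_waves and period_min * 60.0 > avail:
        n_waves = max(1, int(round(n_waves * avail / (period_min * 60.0))))
        period_min = avail / 60.0 if n_waves > 1 else 0.0
    return n_waves, period_min


def _schedule(n_waves: int, first_onset: float, period_min: float,
              reach_fn=None) -> list[WaveSpec]:
    onsets = np.linspace(first_onset, first_onset + period_min * 60.0, n_waves)
    waves = []
    for t in onsets:
        reach = LAYERS if reach_fn is None else reach_fn(t)
        waves.append(WaveSpec(t_start=float(t), reach=tuple(reach)))
    return waves


def control_preset(
    duration: float = 7200.0,
    sample_rate: float = 500.0,
    seed: int = 0,
    n_waves: int = 19,
    first_onset: float = 300.0,
    period_min: float = 86.0,
    **overrides,
) -> GeneratorConfig:
    """Control-group session: 19 waves spanning 86 min, full-column
    propagation, near-complete post-wave recovery.  Shorter durations get a
    proportionally scaled-down schedule at the same wave density."""
    # margin: slowest control wave span (descent + T1/2) plus probe delay
    n_waves, period_min = _fit_schedule(duration, first_onset, n_waves,
                                        period_min, margin=40.0)
    cfg = GeneratorConfig(
        duration=duration,
        sample_rate=sample_rate,
        seed=seed,
        waves=_schedule(n_waves, first_onset, period_min),
        csd_amplitude={"L2/3": 8.8, "L4": 12.9, "L5/6": 16.7},
        csd_half_duration={"L2/3": 23.2, "L4": 25.6, "L5/6": 19.01},
        csd_rise_time={"L2/3": 3.2, "L4": 4.1, "L5/6": 5.4},
        sep_amplitude_uv={"L2/3": 1017.39, "L4": 1174.42, "L5/6": 962.56},
        sep_peak_ms={"L2/3": 11.55, "L4": 10.24, "L5/6": 9.95},
        sep_suppression_fraction=1.0,
        sep_recovery_tau=90.0,
        background_rate={"L2/3": 1.9, "L4": 19.4, "L5/6": 26.0},
        onset_burst_rate={"L2/3": 60.0, "L4": 95.0, "L5/6": 146.0},
        suppression_fraction=0.3,
        recovery_tau=120.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def hhcy_preset(
    duration: float = 7200.0,
    sample_rate: float = 500.0,
    seed: int = 0,
    n_waves: int = 26,
    first_onset: float = 300.0,
    period_min: float = 69.0,
    **overrides,
) -> GeneratorConfig:
    """Hyperhomocysteinemia-group session: 26 waves spanning 69 min, later
    waves progressively limited to deeper layers, long-lasting suppression.
    Shorter durations get a proportionally scaled-down schedule."""
    # margin: slowest hHCY wave span (descent + T1/2) plus probe delay
    n_waves, period_min = _fit_schedule(duration, first_onset, n_waves,
                                        period_min, margin=55.0)

    def reach(t: float) -> tuple[str, ...]:
        if t > 35.0 * 60.0:
            return ("L5/6",)
        if t > 17.5 * 60.0:
            return ("L4", "L5/6")
        return LAYERS

    cfg = GeneratorConfig(
        duration=duration,
        sample_rate=sample_rate,
        seed=seed,
        waves=_schedule(n_waves, first_onset, period_min, reach),
        csd_amplitude={"L2/3": 7.8, "L4": 9.8, "L5/6": 10.3},
        csd_half_duration={"L2/3": 36.1, "L4": 38.4, "L5/6": 36.9},
        csd_rise_time={"L2/3": 7.1, "L4": 6.3, "L5/6": 5.6},
        sep_amplitude_uv={"L2/3": 1153.77, "L4": 1117.42, "L5/6": 743.31},
        sep_peak_ms={"L2/3": 11.76, "L4": 11.87, "L5/6": 11.11},
        sep_suppression_fraction=1.0,
        sep_recovery_tau=1.0e6,
        background_rate={"L2/3": 2.2, "L4": 32.0, "L5/6": 37.9},
        onset_burst_rate={"L2/3": 98.0, "L4": 195.0, "L5/6": 165.0},
        suppression_fraction=0.9,
        recovery_tau=1.0e6,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# lesion stacks
# ---------------------------------------------------------------------------

@dataclass
class LesionSpec:
    """Analytic solid (or explicit area list) sliced at a fixed thickness."""

    shape: str = "cylinder"  # cylinder | ellipsoid | areas
    slice_thickness_um: float = 400.0
    n_slices: int = 5
    radius_mm: Optional[float] = None
    semi_axes_mm: Optional[tuple[float, float, float]] = None
    target_volume_mm3: Optional[float] = None
    areas_mm2: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.slice_thickness_um <= 0:
            raise DomainError("slice thickness must be positive")
        if self.n_slices < 1:
            raise DomainError("need at least one slice")


def generate_lesion_stack(spec: LesionSpec) -> LesionStack:
    """Per-slice lesion areas of an analytic solid (midplane cross-sections).

    For a cylinder with ``target_volume_mm3`` the radius is solved so that the
    slab integral (sum of areas × thickness) equals the target exactly.
    """
    th_mm = spec.slice_thickness_um / 1000.0
    if spec.shape == "areas":
        if spec.areas_mm2 is None:
            raise DomainError("shape='areas' requires areas_mm2")
        areas = np.asarray(spec.areas_mm2, dtype=float)
    elif spec.shape == "cylinder":
        if spec.target_volume_mm3 is not None:
            r = math.sqrt(
                spec.target_volume_mm3 / (spec.n_slices * th_mm * math.pi)
            )
        elif spec.radius_mm is not None:
            r = spec.radius_mm
        else:
            raise DomainError("cylinder requires radius_mm or target_volume_mm3")
        areas = np.full(spec.n_slices, math.pi * r * r)
    elif spec.shape == "ellipsoid":
        if spec.semi_axes_mm is None:
            raise DomainError("ellipsoid requires semi_axes_mm=(a, b, c)")
        a, b, c = spec.semi_axes_mm
        z = (np.arange(spec.n_slices) + 0.5) * th_mm - spec.n_slices * th_mm / 2
        frac = np.clip(1.0 - (z / c) ** 2, 0.0, None) if c > 0 else np.zeros_like(z)
        areas = math.pi * a * b * frac
    else:
        raise DomainError(f"unknown lesion shape '{spec.shape}'")
    if np.any(areas < 0):
        raise DomainError("lesion areas must be non-negative")
    return LesionStack(
        areas_mm2=areas,
        slice_thickness_um=spec.slice_thickness_um,
        provenance=f"synthetic:{spec.shape}",
    )
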