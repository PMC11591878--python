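"""Shared data model for laminar DC-coupled recordings.

A :class:`Session` bundles the multichannel wideband signal (mV, site-major),
the probe geometry, the cortical-layer map, stimulus and KCl event times, and
optionally the ground truth of the synthetic generator that produced it.
Sessions are stored on disk as a directory with a raw float32 signal, a JSON
metadata file and CSV event tables, so no binary container dependency is
required.

Depth convention: site index 0 is the most superficial contact; depths are
positive downward (µm below the pia), so ``site_depths`` is strictly
increasing and the deepest contact sits at ``tip_depth``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "LAYERS",
    "DomainError",
    "FormatError",
    "IntegrityError",
    "ProbeGeometry",
    "LayerMap",
    "AnalysisConfig",
    "Session",
    "assign_layers",
    "decimate_dc",
    "load_session",
    "save_session",
]

#: Laminar compartments of the cortical column, ordered by depth.
LAYERS = ("L2/3", "L4", "L5/6")


class DomainError(ValueError):
    """A parameter is outside the domain an operation is defined on."""


class FormatError(ValueError):
    """A session directory is malformed (missing or inconsistent metadata)."""


class IntegrityError(ValueError):
    """Stored data contradicts its own metadata (e.g. sample-count mismatch)."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear silicon probe with uniformly spaced contacts.

    Parameters
    ----------
    n_sites : int
        Number of recording sites (>= 3; the current-source-density estimator
        needs interior sites).
    site_spacing : float
        Inter-site distance, µm.
    tip_depth : float
        Depth of the deepest site below the pia, µm.
    """

    n_sites: int = 16
    site_spacing: float = 100.0
    tip_depth: float = 1700.0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise DomainError("probe needs at least 3 sites")
        if self.site_spacing <= 0:
            raise DomainError("site_spacing must be positive")
        if self.tip_depth <= (self.n_sites - 1) * self.site_spacing:
            raise DomainError("tip_depth places superficial sites above the pia")

    @property
    def site_depths(self) -> np.ndarray:
        """Depth of each site in µm, index 0 = most superficial."""
        i = np.arange(self.n_sites)
        return self.tip_depth - (self.n_sites - 1 - i) * self.site_spacing


@dataclass(frozen=True)
class LayerMap:
    """Assignment of probe sites to {L2/3, L4, L5/6} by depth band."""

    boundaries: tuple[float, float]
    assignment: tuple[str, ...]

    def sites(self, layer: str) -> np.ndarray:
        """Indices of the sites assigned to ``layer``."""
        return np.flatnonzero(np.asarray(self.assignment) == layer)

    def counts(self) -> dict[str, int]:
        return {lay: int(len(self.sites(lay))) for lay in LAYERS}

    def layer_of(self, site: int) -> str:
        return self.assignment[site]


def assign_layers(
    probe: ProbeGeometry, boundaries: tuple[float, float] = (600.0, 1000.0)
) -> LayerMap:
    """Partition probe sites into supragranular / granular / infragranular.

    A site at depth ``z`` is L2/3 when ``z <= boundaries[0]``, L4 when
    ``boundaries[0] < z <= boundaries[1]``, L5/6 otherwise.  Boundaries must be
    strictly increasing and lie inside ``(0, tip_depth)``.
    """
    b0, b1 = float(boundaries[0]), float(boundaries[1])
    if not (0.0 < b0 < b1 < probe.tip_depth):
        raise DomainError(
            f"layer boundaries {boundaries} outside probe span (0, {probe.tip_depth})"
        )
    labels = []
    for z in probe.site_depths:
        if z <= b0:
            labels.append("L2/3")
        elif z <= b1:
            labels.append("L4")
        else:
            labels.append("L5/6")
    return LayerMap(boundaries=(b0, b1), assignment=tuple(labels))


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the acquisition/analysis conventions of DC-coupled laminar
    CSD studies: MUA band 300–3000 Hz with a 5-SD negative threshold, a 20 s
    onset search window before the wave trough, a baseline taken 20–10 s
    before the wave, and a 100 ms window for the evoked-potential trough.
    """

    dc_rate: float = 1000.0  # Hz, decimated rate for DC/LFP analysis
    mua_band: tuple[float, float] = (300.0, 3000.0)
    mua_threshold_sd: float = 5.0
    mua_dead_time_ms: float = 1.0
    csd_candidate_threshold: float = 2.0  # mV below running baseline
    csd_min_duration: float = 5.0  # s below threshold to accept a candidate
    csd_merge_window: float = 60.0  # s, inter-channel grouping window
    onset_search_window: float = 20.0  # s before the trough
    baseline_window: tuple[float, float] = (-20.0, -10.0)  # s relative to onset
    sep_peak_window: float = 100.0  # ms after the stimulus
    csd_lowpass_hz: float = 1.0  # smoothing for candidate detection
    baseline_span_s: float = 180.0  # running-baseline window
    baseline_percentile: float = 80.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mua_band[0] >= self.mua_band[1]:
            raise DomainError("mua_band must be (low, high) with low < high")
        if self.csd_candidate_threshold <= 0:
            raise DomainError("csd_candidate_threshold must be positive")


@dataclass
class Session:
    """One recording: signal matrix, geometry, layers and event times.

    ``signal`` is ``[site, sample]`` in mV (DC-coupled wideband, float32 on
    disk).  ``stim_times`` are whisker-deflection onsets (s), ``kcl_time`` the
    KCl application onset (s).  ``ground_truth`` carries the generator record
    when the session is synthetic.
    """

    signal: np.ndarray
    sample_rate: float
    probe: ProbeGeometry
    layers: LayerMap
    stim_times: np.ndarray
    kcl_time: float
    duration: float
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.signal.ndim != 2:
            raise IntegrityError("signal must be 2-D [site, sample]")
        if self.signal.shape[0] != self.probe.n_sites:
            raise IntegrityError(
                f"signal has {self.signal.shape[0]} rows but probe declares "
                f"{self.probe.n_sites} sites"
            )
        n_expected = int(round(self.duration * self.sample_rate))
        if self.signal.shape[1] != n_expected:
            raise IntegrityError(
                f"signal has {self.signal.shape[1]} samples but duration × rate "
                f"= {n_expected}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise IntegrityError("signal contains non-finite values")
        for name, t in (("kcl_time", np.atleast_1d(self.kcl_time)),
                        ("stim_times", self.stim_times)):
            if t.size and (np.min(t) < 0 or np.max(t) > self.duration):
                raise IntegrityError(f"{name} outside [0, duration]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.shape[1]) / self.sample_rate


def decimate_dc(session: Session, dc_rate: float) -> np.ndarray:
    """Anti-alias filter and downsample the signal to ``dc_rate``.

    The DC offset is preserved (polyphase FIR resampling with unity DC gain
    and edge padding; no high-pass stage), so slow negative shifts survive.
    Returns a float64 matrix ``[site, ceil(duration * dc_rate)]``.
    """
    fs = session.sample_rate
    if dc_rate > fs:
        raise DomainError(f"dc_rate {dc_rate} exceeds the sample rate {fs}")
    if dc_rate == fs:
        return session.signal.astype(np.float64)
    frac = Fraction(int(round(dc_rate * 1000)), int(round(fs * 1000)))
    up, down = frac.numerator, frac.denominator
    return sps.resample_poly(
        session.signal.astype(np.float64), up, down, axis=1, padtype="line"
    )


# ---------------------------------------------------------------------------
# on-disk format: signal.bin + meta.json + stims.csv (+ ground_truth.json)
# ---------------------------------------------------------------------------

_META_FIELDS = ("sample_rate", "n_sites", "spacing_um", "tip_depth_um",
                "duration_s", "kcl_time_s", "units")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_session(session: Session, path) -> Path:
    """Write ``session`` to ``path`` (directory, created if needed).

    The signal round-trips bit-exactly (little-endian float32, site-major).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(session.signal, dtype="<f4")
    sig.tofile(path / "signal.bin")
    meta = {
        "sample_rate": session.sample_rate,
        "n_sites": session.probe.n_sites,
        "spacing_um": session.probe.site_spacing,
        "tip_depth_um": session.probe.tip_depth,
        "duration_s": session.duration,
        "kcl_time_s": session.kcl_time,
        "units": "mV",
        "layer_boundaries_um": list(session.layers.boundaries),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame({"time_s": session.stim_times}).to_csv(
        path / "stims.csv", index=False
    )
    gt_path = path / "ground_truth.json"
    if session.ground_truth is not None:
        gt_path.write_text(json.dumps(_jsonable(session.ground_truth), indent=1))
    elif gt_path.exists():
        gt_path.unlink()
    return path


def load_session(path) -> Session:
    """Read a session directory written by :func:`save_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in _META_FIELDS:
        if key not in meta:
            raise FormatError(f"meta.json missing field '{key}'")
    if meta["units"] != "mV":
        raise FormatError(f"unsupported units '{meta['units']}' (expected mV)")
    n_sites = int(meta["n_sites"])
    raw = np.fromfile(path / "signal.bin", dtype="<f4")
    if raw.size % n_sites != 0:
        raise IntegrityError(
            f"signal.bin has {raw.size} samples, not a multiple of "
            f"{n_sites} sites"
        )
    signal = raw.reshape(n_sites, -1)
    stims = pd.read_csv(path / "stims.csv")
    if "time_s" not in stims.columns:
        raise FormatError("stims.csv missing 'time_s' column")
    probe = ProbeGeometry(
        n_sites=n_sites,
        site_spacing=float(meta["spacing_um"]),
        tip_depth=float(meta["tip_depth_um"]),
    )
    boundaries = tuple(meta.get("layer_boundaries_um", (600.0, 1000.0)))
    ground_truth = None
    if (path / "ground_truth.json").exists():
        ground_truth = json.loads((path / "ground_truth.json").read_text())
    return Session(
        signal=signal,
        sample_rate=float(meta["sample_rate"]),
        probe=probe,
        layers=assign_layers(probe, boundaries),
        stim_times=stims["time_s"].to_numpy(),
        kcl_time=float(meta["kcl_time_s"]),
        duration=float(meta["duration_s"]),
        ground_truth=ground_truth,
    )
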