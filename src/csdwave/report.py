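"""Group-level statistics and the end-to-end pipeline driver.

Values are reported as M ± m (mean and standard error of the mean).  Group
comparisons use nonparametric tests: Mann–Whitney for two independent
samples, Kruskal–Wallis for more than two, Wilcoxon signed-rank for related
samples; exact p-values are used where sample size permits, asymptotic
otherwise, and the method is recorded per row.  No multiple-testing
correction is applied — callers comparing many metrics should keep that in
mind when reading the p column.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import csd_events, evoked, spikes
from .core import AnalysisConfig, DomainError, LAYERS, Session, load_session

__all__ = ["ComparisonRow", "compare_groups", "group_table", "run_pipeline"]

ALPHA = 0.05


@dataclass
class ComparisonRow:
    metric: str
    test: str
    statistic: float
    p: Optional[float]
    method: str
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.p is not None and np.isfinite(self.p):
            self.significant = bool(self.p < ALPHA)


def compare_groups(
    *samples: Sequence[float],
    paired: bool = False,
    metric: str = "",
) -> ComparisonRow:
    """Nonparametric comparison of two or more samples.

    Two independent samples → Mann–Whitney rank-sum; more than two →
    Kruskal–Wallis; ``paired=True`` (two equal-length samples) → Wilcoxon
    signed-rank.  Degenerate inputs (all ties / all-zero differences) yield a
    missing p with a warning rather than an error.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise DomainError("need at least two samples")
    for a in arrays:
        if a.size < 2:
            raise DomainError("each sample needs at least two observations")
    if paired:
        if len(arrays) != 2 or arrays[0].size != arrays[1].size:
            raise DomainError("paired comparison needs two equal-length samples")
        diffs = arrays[0] - arrays[1]
        if np.all(diffs == 0):
            warnings.warn(
                "all paired differences are zero; p undefined", stacklevel=2
            )
            return ComparisonRow(metric, "wilcoxon", float("nan"), None,
                                 "degenerate")
        exact = arrays[0].size <= 25 and not np.any(diffs == 0)
        res = stats.wilcoxon(
            arrays[0], arrays[1], method="exact" if exact else "approx"
        )
        return ComparisonRow(metric, "wilcoxon", float(res.statistic),
                             float(res.pvalue),
                             "exact" if exact else "asymptotic")
    if len(arrays) == 2:
        pooled = np.concatenate(arrays)
        if np.unique(pooled).size == 1:
            warnings.warn("all observations tied; p undefined", stacklevel=2)
            return ComparisonRow(metric, "mann-whitney", float("nan"), None,
                                 "degenerate")
        has_ties = np.unique(pooled).size < pooled.size
        exact = max(a.size for a in arrays) <= 20 and not has_ties
        res = stats.mannwhitneyu(
            arrays[0], arrays[1], alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        return ComparisonRow(metric, "mann-whitney", float(res.statistic),
                             float(res.pvalue),
                             "exact" if exact else "asymptotic")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; p undefined", stacklevel=2)
        return ComparisonRow(metric, "kruskal-wallis", float("nan"), None,
                             "degenerate")
    res = stats.kruskal(*arrays)
    return ComparisonRow(metric, "kruskal-wallis", float(res.statistic),
                         float(res.pvalue), "asymptotic")


def group_table(per_session: pd.DataFrame) -> pd.DataFrame:
    """M ± m summary per (group, layer, metric) from per-session values.

    Expects columns ``group, layer, metric, value`` (one row per session and
    metric); group means are unweighted means of per-session values.
    """
    def agg(v: pd.Series) -> pd.Series:
        v = v.dropna()
        n = len(v)
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return pd.Series({"mean": v.mean() if n else np.nan, "sem": sem, "n": n})

    out = (
        per_session.groupby(["group", "layer", "metric"])["value"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _session_metrics(session: Session, config: AnalysisConfig) -> list[dict]:
    """Run detect → measure → rates → SEP on one session; flat metric rows."""
    rows: list[dict] = []
    waves = csd_events.detect_csd_waves(session, config)
    summary = csd_events.summarize_csd(session, waves)
    rows.append({"layer": "all", "metric": "n_waves", "value": summary.n_waves})
    if summary.generation_period_min is not None:
        rows.append({"layer": "all", "metric": "generation_period_min",
                     "value": summary.generation_period_min})
    for _, r in summary.layer_stats.iterrows():
        if np.isfinite(r["mean"]):
            rows.append({"layer": r["layer"], "metric": f"csd_{r['metric']}",
                         "value": r["mean"]})

    if session.sample_rate >= 2.0 * config.mua_band[1]:
        trains = spikes.detect_mua(session, config)
        bg_win = (max(0.0, session.kcl_time - 60.0), session.kcl_time)
        for lay, r in spikes.layer_rate(trains, session.layers, bg_win).items():
            if r is not None:
                rows.append({"layer": lay, "metric": "mua_background_hz",
                             "value": r})

    pre_stims = session.stim_times[session.stim_times < session.kcl_time]
    if pre_stims.size:
        avg = evoked.average_sep(session, pre_stims, config)
        profile = evoked.measure_sep(avg, session.layers, config)
        for _, r in profile.layer_stats.iterrows():
            if np.isfinite(r["mean"]):
                rows.append({"layer": r["layer"], "metric": f"sep_{r['metric']}",
                             "value": r["mean"]})
    return rows


@dataclass
class ReportBundle:
    group_table: pd.DataFrame
    comparisons: pd.DataFrame
    qc: dict
    per_session: pd.DataFrame


def run_pipeline(
    sessions: Sequence,
    config: Optional[AnalysisConfig] = None,
    out_dir: Optional[Path] = None,
) -> ReportBundle:
    """Execute the full analysis over several sessions and aggregate.

    ``sessions`` is a sequence of ``(session_or_path, group_label)`` pairs.
    Per-session failures are isolated, recorded in the QC log, and do not
    abort the run.  With ``out_dir`` set, writes ``group_table.csv``,
    ``comparisons.csv``, ``per_session.csv`` and ``qc.json``.
    """
    if not sessions:
        raise DomainError("run_pipeline requires at least one session")
    config = config or AnalysisConfig()
    qc: dict = {"failures": {}, "n_sessions": len(sessions),
                "config_hash": hashlib.sha256(
                    json.dumps(vars(config), sort_keys=True, default=str)
                    .encode()).hexdigest()[:16]}
    all_rows = []
    for i, (item, group) in enumerate(sessions):
        try:
            session = item if isinstance(item, Session) else load_session(item)
            for row in _session_metrics(session, config):
                row.update({"session": i, "group": group})
                all_rows.append(row)
        except Exception as exc:  # noqa: BLE001 - isolate per-session failures
            qc["failures"][str(i)] = f"{type(exc).__name__}: {exc}"
    per_session = pd.DataFrame(all_rows)
    if per_session.empty:
        raise DomainError("every session failed; see qc['failures']")
    table = group_table(per_session)

    comp_rows = []
    groups = sorted(per_session["group"].unique())
    if len(groups) >= 2:
        for (layer, metric), sub in per_session.groupby(["layer", "metric"]):
            samples = [
                sub[sub["group"] == g]["value"].dropna().to_numpy()
                for g in groups
            ]
            if any(s.size < 2 for s in samples):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row = compare_groups(*samples, metric=f"{layer}:{metric}")
            comp_rows.append(vars(row))
    comparisons = pd.DataFrame(comp_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "group_table.csv", index=False)
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        per_session.to_csv(out_dir / "per_session.csv", index=False)
        (out_dir / "qc.json").write_text(json.dumps(qc, indent=1))
    return ReportBundle(group_table=table, comparisons=comparisons, qc=qc,
                        per_session=per_session)
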