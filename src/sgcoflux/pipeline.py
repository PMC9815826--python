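"""End-to-end orchestration: simulate -> detect -> events -> entropy -> stats.

The pipeline turns a cohort of recording sessions into three tables —
per-animal event rates, per-channel entropy summaries, and event-partitioned
entropy — and then runs the group statistics on them. Each stage writes its
artifacts under an output directory together with a manifest (parameter echo,
file hashes, timestamps); re-running with an unchanged configuration skips
stages whose outputs are already present and only regenerates what is missing.

Single timing convention throughout: timestamps are seconds from session
start, bins are left-closed right-open, and every sliding window is causal,
covering (t - W, t].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .entropy import entropy_series, event_partition, summarize_entropy
from .errors import InsufficientDataError, SessionExcludedError
from .events import (
    DEFAULT_C_GRID,
    DEFAULT_T_GRID,
    EventSeries,
    ThresholdSelection,
    coactivity_series,
    cofluctuation,
    detect_events,
    fit_lognormal,
    select_convergent_thresholds,
    sliding_rate,
)
from .io import read_spikes_csv, write_ground_truth, write_session, write_spikes_csv
from .specificity import make_bins, specificity_map
from .spikes import DetectorParams, detect_spikes
from .stats import compare_scalar_by_group, fit_entropy_lme, fit_event_entropy_lme
from .synthetic import CohortConfig, RecordingSession, SpikeTrain, generate_cohort

__all__ = [
    "AnalysisParams",
    "ChannelQualityRule",
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "exclude_channels",
    "session_event_analysis",
    "session_entropy_analysis",
    "cohort_tables",
    "run_all",
]


@dataclass
class ChannelQualityRule:
    """Mask channels that are noise-dominated or nearly silent."""

    max_noise_ratio: float = 5.0  # robust SD vs median-channel robust SD
    min_spikes: int = 10  # per-session floor, checked when counts are given


@dataclass
class AnalysisParams:
    """Windowing, binning and threshold-grid parameters for every stage."""

    rate_bin: float = 0.1  # s
    stat_window: float = 10.0  # s
    corr_window: float = 60.0  # s
    step: float = 1.0  # s
    spec_window: float = 15.0  # s
    n_bins: int = 20
    lo_pct: float = 1.0
    hi_pct: float = 99.0
    C_grid: tuple = tuple(float(c) for c in DEFAULT_C_GRID)
    T_grid: tuple = tuple(float(t) for t in DEFAULT_T_GRID)
    tol: float = 0.4
    statistics: tuple = ("MEAN", "STD")
    detector: DetectorParams = field(default_factory=DetectorParams)
    quality: ChannelQualityRule = field(default_factory=ChannelQualityRule)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str = "results/run"
    use_detected_spikes: bool = True

    def echo(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Top-level keys ``cohort``, ``analysis`` (with optional nested
    ``detector`` and ``quality`` blocks), ``out_dir`` and
    ``use_detected_spikes`` map onto the corresponding dataclasses; dataclass
    validation rejects unknown or invalid values.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    analysis_kw = dict(raw.get("analysis", {}))
    if "detector" in analysis_kw:
        analysis_kw["detector"] = DetectorParams(**analysis_kw["detector"])
    if "quality" in analysis_kw:
        analysis_kw["quality"] = ChannelQualityRule(**analysis_kw["quality"])
    for key in ("C_grid", "T_grid", "statistics"):
        if key in analysis_kw:
            analysis_kw[key] = tuple(analysis_kw[key])
    return PipelineConfig(
        cohort=CohortConfig(**raw.get("cohort", {})),
        analysis=AnalysisParams(**analysis_kw),
        out_dir=str(raw.get("out_dir", "results/run")),
        use_detected_spikes=bool(raw.get("use_detected_spikes", True)),
    )


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict  # stage -> {"files": {name: sha256}, "completed": iso-time}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def robust_noise_sd(trace: np.ndarray) -> float:
    return float(np.median(np.abs(trace)) / 0.6745)


def exclude_channels(
    session: RecordingSession,
    rule: ChannelQualityRule | None = None,
    spike_counts: np.ndarray | None = None,
) -> RecordingSession:
    """Screen channels by noise level (and optionally spike count).

    Channels whose robust noise SD exceeds ``max_noise_ratio`` times the
    median channel's, or whose spike count is below ``min_spikes``, are
    masked. Raises SessionExcludedError if fewer than two channels survive.
    """
    rule = rule or ChannelQualityRule()
    if session.voltage is None:
        return session
    sds = np.array([robust_noise_sd(tr) for tr in session.voltage.traces])
    med = np.median(sds)
    mask = session.voltage.channel_mask.copy()
    if med > 0:
        mask &= sds <= rule.max_noise_ratio * med
    if spike_counts is not None:
        mask &= np.asarray(spike_counts) >= rule.min_spikes
    if mask.sum() < 2:
        raise SessionExcludedError(
            f"{session.animal_id}: only {int(mask.sum())} usable channels remain"
        )
    session.voltage.channel_mask = mask
    return session


def session_event_analysis(
    trains: list[SpikeTrain],
    params: AnalysisParams,
) -> dict[str, dict]:
    """Coactivity -> convergent (C, T) -> events for each sliding-rate statistic.

    Returns per statistic: the threshold selection, the event series at the
    selected pair, the cofluctuation series at the selected C, and its
    log-normal fit (None when too few positive values).
    """
    out: dict[str, dict] = {}
    for stat in params.statistics:
        rates = [
            sliding_rate(tr, params.rate_bin, params.stat_window, params.step, stat)
            for tr in trains
        ]
        co = coactivity_series(rates, params.corr_window, params.step)
        sel = select_convergent_thresholds(
            co, np.asarray(params.C_grid), np.asarray(params.T_grid), params.tol
        )
        cf = cofluctuation(co, sel.C)
        ev = detect_events(cf, sel.T)
        try:
            ln = fit_lognormal(cf)
        except InsufficientDataError:
            ln = None
        out[stat] = {"selection": sel, "cofluctuation": cf, "events": ev, "lognormal": ln}
    return out


def session_entropy_analysis(
    trains: list[SpikeTrain],
    session: RecordingSession,
    params: AnalysisParams,
    events: dict[str, EventSeries] | None = None,
) -> tuple[list, list]:
    """Specificity -> entropy summaries (and event partitions) per channel."""
    bins = make_bins(session.lvp, params.n_bins, params.lo_pct, params.hi_pct)
    summaries = []
    partitions = []
    for tr in trains:
        spec = specificity_map(tr, session.lvp, bins, params.spec_window, params.step)
        es = entropy_series(spec)
        try:
            summaries.append(summarize_entropy(es))
        except InsufficientDataError:
            continue
        if events:
            for stat, ev in events.items():
                partitions.append(event_partition(es, ev))
    return summaries, partitions


def cohort_tables(
    cohort: list[tuple[RecordingSession, list[SpikeTrain]]],
    params: AnalysisParams,
) -> dict[str, pd.DataFrame]:
    """ER, entropy and event-entropy tables for a cohort of (session, trains)."""
    er_rows, ent_rows, evt_rows = [], [], []
    for session, trains in cohort:
        ev_res = session_event_analysis(trains, params)
        for stat, res in ev_res.items():
            sel: ThresholdSelection = res["selection"]
            ln = res["lognormal"]
            er_rows.append(
                {
                    "animal_id": session.animal_id,
                    "group": session.group,
                    "statistic": stat,
                    "C": sel.C,
                    "T": sel.T,
                    "converged": sel.converged,
                    "ER": res["events"].ER,
                    "n_events": len(res["events"].intervals),
                    "mu_fit": ln.mu_fit if ln else np.nan,
                    "sigma_fit": ln.sigma_fit if ln else np.nan,
                    "frac_outside": ln.frac_outside if ln else np.nan,
                }
            )
        events = {stat: res["events"] for stat, res in ev_res.items()}
        summaries, partitions = session_entropy_analysis(trains, session, params, events)
        base = {s.channel_id: s.entropy_mean for s in summaries}
        for s in summaries:
            ent_rows.append(
                {
                    "animal_id": session.animal_id,
                    "group": session.group,
                    "channel": s.channel_id,
                    "entropy_mean": s.entropy_mean,
                    "entropy_std": s.entropy_std,
                    "n_defined": s.n_defined,
                }
            )
        for p in partitions:
            if p.partial:
                continue
            for event_type, m, sd in (
                ("event", p.inside_mean, p.inside_std),
                ("non_event", p.outside_mean, p.outside_std),
            ):
                evt_rows.append(
                    {
                        "animal_id": session.animal_id,
                        "group": session.group,
                        "channel": p.channel_id,
                        "statistic": p.statistic,
                        "event_type": event_type,
                        "baseline_entropy": base.get(p.channel_id, np.nan),
                        "entropy_mean": m,
                        "entropy_std": sd,
                        "n": p.n_inside if event_type == "event" else p.n_outside,
                    }
                )
    return {
        "er": pd.DataFrame(er_rows),
        "entropy": pd.DataFrame(ent_rows),
        "event_entropy": pd.DataFrame(evt_rows),
    }


def group_statistics(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Scalar ER tests plus entropy / event-entropy mixed models, as one table."""
    rows = []
    er = tables["er"]
    for stat in sorted(er["statistic"].unique()):
        sub = er[er["statistic"] == stat]
        try:
            res = compare_scalar_by_group(sub["ER"].to_numpy(), sub["group"].to_numpy())
            rows.append(
                {
                    "comparison": f"ER_{stat}",
                    "model": res.test_name,
                    "beta": res.group_means[1] - res.group_means[0],
                    "ci95": np.nan,
                    "d": res.effect_d,
                    "p": res.p,
                }
            )
        except InsufficientDataError:
            pass
    ent = tables["entropy"]
    if len(ent):
        for outcome in ("entropy_mean", "entropy_std"):
            try:
                res = fit_entropy_lme(ent, outcome=outcome)
                b, ci, drm, p = res.report()
                rows.append(
                    {"comparison": f"{outcome}_group", "model": "lme", "beta": b,
                     "ci95": ci, "d": drm, "p": p}
                )
            except Exception:
                pass
    evt = tables["event_entropy"]
    if len(evt):
        for outcome in ("entropy_mean", "entropy_std"):
            try:
                res = fit_event_entropy_lme(evt, outcome=outcome)
                for term in res.beta:
                    if term == "Intercept":
                        continue
                    rows.append(
                        {
                            "comparison": f"event_{outcome}_{term}",
                            "model": "lme",
                            "beta": res.beta[term],
                            "ci95": res.ci95[term],
                            "d": res.d_rm,
                            "p": res.p[term],
                        }
                    )
            except Exception:
                pass
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Stages run in dependency order; a stage whose outputs already exist under
    an unchanged configuration is skipped, so deleting an intermediate and
    re-running regenerates only that stage and its dependents.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old = json.loads(manifest_path.read_text()) if manifest_path.exists() else None
    cfg_echo = config.echo()
    reuse = old is not None and old.get("config") == json.loads(
        json.dumps(cfg_echo, default=str)
    )
    stages: dict = {}

    def record(stage: str, files: list[Path]) -> None:
        stages[stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "completed": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def cached(stage: str, files: list[Path]) -> bool:
        if not (reuse and old and stage in old.get("stages", {})):
            return False
        if not all(f.exists() for f in files):
            return False
        stages[stage] = old["stages"][stage]
        return True

    # --- stage 1: simulate
    cohort = generate_cohort(config.cohort)
    sim_files = []
    for session, truth in cohort:
        h5 = out / f"{session.animal_id}.h5"
        gt = out / f"{session.animal_id}.truth.json"
        if not (reuse and h5.exists() and gt.exists()):
            write_session(h5, session)
            write_ground_truth(gt, truth)
        sim_files += [h5, gt]
    if not cached("simulate", sim_files):
        record("simulate", sim_files)

    # --- stage 2: spikes (detected from voltage, or ground truth)
    spike_files = []
    per_session_trains: list[tuple[RecordingSession, list[SpikeTrain]]] = []
    for session, truth in cohort:
        csv = out / f"{session.animal_id}.spikes.csv"
        if reuse and csv.exists():
            trains = read_spikes_csv(csv, config.cohort.session_duration)
        elif config.use_detected_spikes and session.voltage is not None:
            counts = []
            trains, pols = [], []
            for c, trace in enumerate(session.voltage.traces):
                det = detect_spikes(trace, session.voltage.fs, config.analysis.detector)
                tr = det.train
                tr.channel_id = c
                trains.append(tr)
                pols.append(det.polarity)
                counts.append(tr.n_spikes)
            session = exclude_channels(session, config.analysis.quality, np.array(counts))
            keep = session.voltage.channel_mask
            kept = [(tr, p) for tr, p in zip(trains, pols) if keep[tr.channel_id]]
            trains = [tr for tr, _ in kept]
            pols = [p for _, p in kept]
            write_spikes_csv(csv, trains, pols)
        else:
            trains = [
                SpikeTrain(times=t, channel_id=c, duration=config.cohort.session_duration)
                for c, t in enumerate(truth.true_spikes)
            ]
            write_spikes_csv(csv, trains)
        per_session_trains.append((session, trains))
        spike_files.append(csv)
    record("spikes", spike_files)

    # --- stages 3-4: events + entropy tables
    tables = cohort_tables(per_session_trains, config.analysis)
    table_files = []
    for name, df in tables.items():
        f = out / f"{name}.csv"
        df.to_csv(f, index=False)
        table_files.append(f)
    record("tables", table_files)

    # --- stage 5: statistics
    report = group_statistics(tables)
    rep_file = out / "stats.csv"
    report.to_csv(rep_file, index=False)
    txt = out / "stats.txt"
    lines = ["(beta, +/-CI, d, p) per comparison:"]
    for _, r in report.iterrows():
        lines.append(
            f"  {r['comparison']:32s} ({r['beta']:+.4g}, +/-{r['ci95']:.4g}, "
            f"{r['d']:.3g}, p={r['p']:.4g}) [{r['model']}]"
        )
    txt.write_text("\n".join(lines) + "\n")
    record("stats", [rep_file, txt])

    manifest = RunManifest(version=__version__, config=cfg_echo, stages=stages)
    manifest.save(manifest_path)
    return manifest
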