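"""Synthetic cohorts of stellate-ganglion-like recording sessions.

This module generates seeded surrogate data with known ground truth for the
whole analysis chain: a quasi-periodic left-ventricular-pressure (LVP)
waveform, cardiac-phase-locked multichannel spike trains with transient
cross-channel rate cofluctuations ("events"), and raw extracellular voltage
traces rendered from those trains.

The statistical structure mirrors what the analysis assumes about real
recordings:

* spiking is an inhomogeneous Poisson process whose intensity is modulated by
  cardiac phase through a von-Mises-style gain ``exp(kappa * cos(phi))``
  normalised by the modified Bessel function ``I0(kappa)`` so that the mean
  rate stays at ``baseline_rate`` regardless of the locking strength;
* the locking gain ``kappa`` drifts per channel as a bounded (reflected)
  random walk, so specificity waxes and wanes over the session;
* short "events" multiply the rate of a random majority subset of channels by
  ``event_gain`` and, for those channels, strengthen phase locking by
  ``event_kappa_boost`` — producing transient high pairwise coactivity with
  more coherent (lower-entropy) specificity inside events;
* heart-failure (HF) sessions use a strictly higher true event rate and a
  larger kappa drift than control sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import i0

from .errors import InvalidParameterError

__all__ = [
    "PressureSeries",
    "SpikeTrain",
    "MultichannelVoltage",
    "RecordingSession",
    "GroundTruth",
    "CohortConfig",
    "generate_lvp",
    "systolic_peaks",
    "cardiac_phase",
    "generate_spike_trains",
    "render_voltage",
    "generate_session",
    "generate_cohort",
]

# fraction of the beat at which systole peaks
_PEAK_FRACTION = 0.3
# sharpness of the pressure pulse
_PULSE_SHAPE = 3.0


@dataclass
class PressureSeries:
    """Continuously sampled pressure waveform (mmHg)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("pressure samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Nearest-sample lookup (no interpolation)."""
        idx = np.clip(
            np.round((np.asarray(t, dtype=float) - self.t0) * self.fs).astype(np.int64),
            0,
            self.samples.size - 1,
        )
        return self.samples[idx]


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for a single channel."""

    times: np.ndarray
    channel_id: int
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise InvalidParameterError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise InvalidParameterError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class MultichannelVoltage:
    """Raw multichannel voltage block (arbitrary units)."""

    traces: np.ndarray  # n_channels x n_samples
    fs: float
    channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces))
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.traces.shape[0], dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.fs


@dataclass
class RecordingSession:
    """Per-animal unit of analysis: voltage + LVP + group label.

    ``voltage`` may be None for spike-train-level analyses that bypass the
    raw-voltage stage (the generator can skip rendering to save memory).
    """

    lvp: PressureSeries
    animal_id: str
    group: str  # "control" | "HF"
    voltage: MultichannelVoltage | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "HF"):
            raise InvalidParameterError(f"unknown group {self.group!r}")


@dataclass
class GroundTruth:
    """Everything the generator drew, for validating the pipeline."""

    true_spikes: list[np.ndarray]
    true_event_intervals: list[tuple[float, float]]
    event_channels: list[np.ndarray]
    kappa: np.ndarray  # per-channel time-averaged locking gain
    regime: dict

    def __post_init__(self) -> None:
        for a, b in self.true_event_intervals:
            if not a < b:
                raise InvalidParameterError("event intervals need start < end")
        starts = [a for a, _ in self.true_event_intervals]
        ends = [b for _, b in self.true_event_intervals]
        if any(s < e for s, e in zip(starts[1:], ends[:-1])):
            raise InvalidParameterError("event intervals must not overlap")

    @property
    def total_burst_time(self) -> float:
        return float(sum(b - a for a, b in self.true_event_intervals))


@dataclass
class CohortConfig:
    """Generator regime: the study conditions for a synthetic cohort.

    Rates and durations are desk-scale stand-ins for multi-hour porcine
    sessions; group asymmetry (HF event rate and kappa drift multipliers)
    encodes the qualitative contrast the analysis is designed to detect.
    """

    n_control: int = 2
    n_hf: int = 2
    n_channels: int = 16
    session_duration: float = 1200.0  # s
    fs_voltage: float = 5000.0  # Hz
    fs_lvp: float = 1000.0  # Hz
    heart_rate: float = 80.0  # bpm, anesthetised porcine range
    systolic: float = 110.0  # mmHg
    diastolic: float = 10.0  # mmHg
    beat_jitter: float = 0.03  # fractional SD of beat periods
    baseline_rate: float = 5.0  # Hz per channel
    event_rate_true: float = 0.005  # events/s (control preset)
    event_duration: float = 10.0  # s
    event_gain: float = 4.0  # multiplicative rate factor inside events
    event_kappa_boost: float = 2.5  # extra locking gain inside events
    kappa_mean: float = 1.5
    kappa_drift_sd: float = 0.05  # per-second random-walk step SD (control)
    kappa_half_range: float = 0.25  # reflection half-range of the walk (control)
    hf_event_rate_factor: float = 6.0
    hf_kappa_drift_factor: float = 4.0
    hf_kappa_range_factor: float = 6.0
    noise_sd: float = 1.0  # voltage units
    spike_amp: float = 8.0  # template amplitude, units of noise_sd
    template_ms: float = 1.0
    render_voltage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "n_channels session_duration fs_voltage fs_lvp heart_rate "
            "baseline_rate event_duration event_gain noise_sd spike_amp "
            "template_ms"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.event_rate_true < 0 or self.kappa_drift_sd < 0 or self.kappa_mean < 0:
            raise InvalidParameterError("rates and gains must be non-negative")
        if self.n_control + self.n_hf < 2:
            raise InvalidParameterError("need at least two animals in total")
        if self.hf_event_rate_factor <= 1 or self.hf_kappa_drift_factor <= 1:
            raise InvalidParameterError("HF factors must exceed 1")

    def for_group(self, group: str) -> "CohortConfig":
        """Preset for one group: HF scales event rate and kappa drift up."""
        if group == "control":
            return self
        cfg = CohortConfig(**asdict(self))
        cfg.event_rate_true = self.event_rate_true * self.hf_event_rate_factor
        cfg.kappa_drift_sd = self.kappa_drift_sd * self.hf_kappa_drift_factor
        cfg.kappa_half_range = self.kappa_half_range * self.hf_kappa_range_factor
        return cfg


def generate_lvp(
    heart_rate: float,
    duration: float,
    fs: float,
    systolic: float = 110.0,
    diastolic: float = 10.0,
    jitter: float = 0.03,
    seed: int | np.random.SeedSequence | None = 0,
) -> PressureSeries:
    """Quasi-periodic LVP surrogate: fast upstroke, slower decay, one pulse per beat.

    Beat periods are jittered multiplicatively around 60/heart_rate. With
    ``jitter=0`` the waveform is exactly periodic and peaks at ``systolic``.
    """
    if duration <= 0 or fs <= 0 or heart_rate <= 0:
        raise InvalidParameterError("heart_rate, duration and fs must be positive")
    if systolic <= diastolic:
        raise InvalidParameterError("systolic must exceed diastolic")
    if jitter < 0:
        raise InvalidParameterError("jitter must be non-negative")

    rng = np.random.default_rng(seed)
    base = 60.0 / heart_rate
    # draw enough beats to cover the session
    n_beats = int(np.ceil(duration / base * (1 + 5 * jitter))) + 3
    periods = base * np.clip(1.0 + jitter * rng.standard_normal(n_beats), 0.5, 1.5)
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    t = np.arange(int(round(duration * fs))) / fs
    beat = np.searchsorted(starts, t, side="right") - 1
    theta = (t - starts[beat]) / periods[beat]  # beat fraction in [0, 1)
    x = theta / _PEAK_FRACTION
    pulse = (x * np.exp(1.0 - x)) ** _PULSE_SHAPE  # 0 at onset, 1 at peak
    samples = diastolic + (systolic - diastolic) * pulse
    return PressureSeries(samples=samples, fs=fs, t0=0.0)


def systolic_peaks(lvp: PressureSeries) -> np.ndarray:
    """Times of successive systolic peaks, from the waveform itself."""
    rng_amp = float(np.ptp(lvp.samples))
    if rng_amp <= 0:
        raise InvalidParameterError("constant pressure has no systolic peaks")
    idx, _ = find_peaks(lvp.samples, prominence=0.3 * rng_amp)
    if idx.size < 2:
        raise InvalidParameterError("need at least two systolic peaks")
    return lvp.t0 + idx / lvp.fs


def cardiac_phase(t: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Cardiac phase (rad): 0 at each systolic peak, linear in time between peaks.

    Outside the first/last peak the neighbouring period is extrapolated.
    """
    t = np.asarray(t, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    i = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    left = peaks[i]
    period = peaks[i + 1] - peaks[i]
    return 2.0 * np.pi * (t - left) / period


def _kappa_walk(
    rng: np.random.Generator,
    n_steps: int,
    mean: float,
    drift_sd: float,
    half_range: float,
) -> np.ndarray:
    """Reflected random walk on [mean - r, mean + r], r = min(half_range, mean).

    The reflection range, not just the step size, sets the session-scale
    variance of the locking gain: a narrow range pins the walk near its mean
    regardless of duration, a wide one lets it saturate the interval.
    """
    r = min(half_range, mean)
    lo, hi = mean - r, mean + r
    walk = np.empty(n_steps)
    k = mean
    steps = drift_sd * rng.standard_normal(n_steps)
    width = hi - lo
    for j in range(n_steps):
        k = k + steps[j]
        if width <= 0:
            k = mean
        else:  # reflect into [lo, hi]
            m = (k - lo) % (2.0 * width)
            k = lo + (m if m <= width else 2.0 * width - m)
        walk[j] = k
    return walk


def generate_spike_trains(
    lvp: PressureSeries,
    config: CohortConfig,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[SpikeTrain], GroundTruth]:
    """Phase-locked inhomogeneous-Poisson spike trains with shared burst events.

    Per channel c the intensity is::

        lambda_c(t) = baseline_rate * exp(kappa_c(t) * cos(phi(t))) / I0(kappa_c(t))
                      * burst_c(t)

    where ``phi`` is cardiac phase (0 at systolic peak), ``kappa_c`` follows a
    reflected random walk, and ``burst_c(t) = event_gain`` inside true event
    intervals for the channels that participate in each event (a uniformly
    drawn subset of at least half the channels) and 1 elsewhere. Inside events
    participating channels additionally get ``kappa + event_kappa_boost``.
    Sampling is by thinning, so the process is exact given the intensity.
    """
    duration = config.session_duration
    if lvp.duration + 0.5 / lvp.fs < duration:
        raise InvalidParameterError("LVP does not cover the session duration")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = config.n_channels

    # --- event intervals: Poisson starts, fixed duration, overlaps discarded
    intervals: list[tuple[float, float]] = []
    members: list[np.ndarray] = []
    if config.event_rate_true > 0:
        n_cand = rng.poisson(config.event_rate_true * duration)
        starts = np.sort(rng.uniform(0.0, max(duration - config.event_duration, 0.0), n_cand))
        last_end = -np.inf
        for s in starts:
            if s >= last_end:
                e = s + config.event_duration
                intervals.append((float(s), float(e)))
                last_end = e
                m = int(rng.integers(int(np.ceil(n / 2)), n + 1))
                members.append(np.sort(rng.choice(n, size=m, replace=False)))

    peaks = systolic_peaks(lvp)

    # --- per-channel kappa walks (piecewise constant per second)
    n_sec = int(np.ceil(duration))
    kappa_walks = np.vstack(
        [
            _kappa_walk(
                rng, n_sec, config.kappa_mean, config.kappa_drift_sd, config.kappa_half_range
            )
            for _ in range(n)
        ]
    )

    # intensity upper bound for thinning
    k_hi = 2.0 * config.kappa_mean + config.event_kappa_boost
    lam_max = config.baseline_rate * (np.exp(k_hi) / i0(k_hi)) * config.event_gain

    ev_starts = np.array([a for a, _ in intervals])
    ev_ends = np.array([b for _, b in intervals])

    trains: list[SpikeTrain] = []
    for c in range(n):
        n_cand = rng.poisson(lam_max * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
        phi = cardiac_phase(t_cand, peaks)
        kap = kappa_walks[c, np.minimum(t_cand.astype(np.int64), n_sec - 1)]

        in_event = np.zeros(t_cand.size, dtype=bool)
        boosted = np.zeros(t_cand.size, dtype=bool)
        if ev_starts.size:
            j = np.searchsorted(ev_starts, t_cand, side="right") - 1
            valid = j >= 0
            inside = valid & (t_cand < ev_ends[np.maximum(j, 0)])
            if inside.any():
                member = np.array([c in members[k] for k in range(len(members))])
                inside &= member[np.maximum(j, 0)]
            in_event = inside
            boosted = inside
        kap_eff = kap + config.event_kappa_boost * boosted
        lam = (
            config.baseline_rate
            * np.exp(kap_eff * np.cos(phi))
            / i0(kap_eff)
            * np.where(in_event, config.event_gain, 1.0)
        )
        keep = rng.uniform(0.0, lam_max, t_cand.size) < lam
        times = np.unique(t_cand[keep])
        trains.append(SpikeTrain(times=times, channel_id=c, duration=duration))

    truth = GroundTruth(
        true_spikes=[tr.times.copy() for tr in trains],
        true_event_intervals=intervals,
        event_channels=members,
        kappa=kappa_walks.mean(axis=1),
        regime=asdict(config),
    )
    return trains, truth


def spike_template(fs: float, template_ms: float = 1.0) -> tuple[np.ndarray, int]:
    """Biphasic (positive-then-negative) template and its positive-peak index.

    The repolarisation lobe is shallower than the depolarisation lobe (factor
    0.5), as in typical extracellular waveforms; the asymmetry also keeps the
    two polarities from tying in the detector's barrier competition.
    """
    if fs < 2000:
        raise InvalidParameterError("fs must be at least 2 kHz to resolve spikes")
    # widen to the narrowest sampled biphasic shape when fs is marginal
    width = max(int(round(template_ms * 1e-3 * fs)), 4)
    k = np.arange(width)
    shape = np.sin(2.0 * np.pi * k / width)
    shape[shape < 0] *= 0.5
    return shape, width // 4


def render_voltage(
    trains: Sequence[SpikeTrain],
    fs: float,
    template_ms: float = 1.0,
    amp: float = 8.0,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
    amp_jitter: float = 0.2,
) -> MultichannelVoltage:
    """Render spike trains onto Gaussian noise as biphasic extracellular spikes.

    Each spike adds ``amp`` (with +/- ``amp_jitter`` fractional uniform jitter)
    times the template, positive peak aligned to ``round(t * fs)``. Overlapping
    spikes sum.
    """
    if fs < 2000:
        raise InvalidParameterError("fs must be at least 2 kHz to resolve spikes")
    if not trains:
        raise InvalidParameterError("need at least one spike train")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    duration = max(tr.duration for tr in trains)
    n_samples = int(round(duration * fs))
    template, peak_idx = spike_template(fs, template_ms)
    width = template.size

    traces = np.empty((len(trains), n_samples), dtype=np.float32)
    for c, tr in enumerate(trains):
        trace = rng.standard_normal(n_samples) * noise_sd
        if tr.n_spikes:
            amps = amp * (1.0 + amp_jitter * rng.uniform(-1.0, 1.0, tr.n_spikes))
            starts = np.round(tr.times * fs).astype(np.int64) - peak_idx
            for s, a in zip(starts, amps):
                lo = max(s, 0)
                hi = min(s + width, n_samples)
                if hi > lo:
                    trace[lo:hi] += a * template[lo - s : hi - s]
        traces[c] = trace
    return MultichannelVoltage(traces=traces, fs=fs)


def generate_session(
    config: CohortConfig,
    group: str,
    animal_id: str,
    seed: np.random.SeedSequence | int,
) -> tuple[RecordingSession, GroundTruth]:
    """One seeded session under the given group's preset."""
    cfg = config.for_group(group)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_lvp, s_trains, s_volt = ss.spawn(3)
    lvp = generate_lvp(
        cfg.heart_rate,
        cfg.session_duration,
        cfg.fs_lvp,
        systolic=cfg.systolic,
        diastolic=cfg.diastolic,
        jitter=cfg.beat_jitter,
        seed=s_lvp,
    )
    trains, truth = generate_spike_trains(lvp, cfg, seed=s_trains)
    voltage = None
    if cfg.render_voltage:
        voltage = render_voltage(
            trains,
            cfg.fs_voltage,
            template_ms=cfg.template_ms,
            amp=cfg.spike_amp * cfg.noise_sd,
            noise_sd=cfg.noise_sd,
            seed=s_volt,
        )
    session = RecordingSession(lvp=lvp, animal_id=animal_id, group=group, voltage=voltage)
    return session, truth


def generate_cohort(config: CohortConfig) -> list[tuple[RecordingSession, GroundTruth]]:
    """Seeded cohort: control sessions then HF sessions.

    Session seeds derive deterministically from ``config.seed`` and the
    session index, so identical configs reproduce bit-identical cohorts.
    """
    out: list[tuple[RecordingSession, GroundTruth]] = []
    idx = 0
    for group, count in (("control", config.n_control), ("HF", config.n_hf)):
        for k in range(count):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,))
            prefix = "C" if group == "control" else "H"
            out.append(generate_session(config, group, f"{prefix}{k + 1:02d}", ss))
            idx += 1
    return out


def simulate_entropy_table(
    n_control: int = 6,
    n_hf: int = 8,
    n_channels: int = 16,
    baseline: float = 0.85,
    group_delta: float = 0.05,
    animal_sd: float = 0.02,
    channel_sd: float = 0.02,
    resid_sd: float = 0.02,
    seed: int | None = 0,
):
    """Channel-nested entropy summaries drawn from the mixed-model data model.

    One row per (animal, channel): outcome = baseline + delta*[HF] + animal
    intercept + channel intercept + residual, all Gaussian. Serves as a
    ground-truth benchmark for the mixed-effects recovery of the group effect.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ch_eff = rng.normal(0.0, channel_sd, n_channels)
    rows = []
    for a in range(n_control + n_hf):
        group = "control" if a < n_control else "HF"
        an_eff = rng.normal(0.0, animal_sd)
        for c in range(n_channels):
            y = (
                baseline
                + (group_delta if group == "HF" else 0.0)
                + an_eff
                + ch_eff[c]
                + rng.normal(0.0, resid_sd)
            )
            rows.append({"animal_id": f"A{a:02d}", "group": group, "channel": c, "outcome": y})
    return pd.DataFrame(rows)


def simulate_event_entropy_table(
    n_control: int = 6,
    n_hf: int = 8,
    n_channels: int = 16,
    baseline: float = 0.85,
    event_deficit: float = 0.01,
    group_delta: float = 0.01,
    statistic_delta: float = 0.005,
    animal_sd: float = 0.02,
    channel_sd: float = 0.02,
    resid_sd: float = 0.02,
    seed: int | None = 0,
):
    """Event-partitioned entropy rows with a planted inside-event deficit.

    One row per (animal, channel, statistic, event_type); the outcome inside
    events is lower by ``event_deficit``. ``baseline_entropy`` echoes each
    channel's session-level mean, as the pipeline would supply it.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ch_eff = rng.normal(0.0, channel_sd, n_channels)
    rows = []
    for a in range(n_control + n_hf):
        group = "control" if a < n_control else "HF"
        an_eff = rng.normal(0.0, animal_sd)
        for c in range(n_channels):
            base_c = baseline + an_eff + ch_eff[c]
            for stat in ("MEAN", "STD"):
                for event_type in ("event", "non_event"):
                    y = (
                        base_c
                        + (group_delta if group == "HF" else 0.0)
                        + (statistic_delta if stat == "STD" else 0.0)
                        - (event_deficit if event_type == "event" else 0.0)
                        + rng.normal(0.0, resid_sd)
                    )
                    rows.append(
                        {
                            "animal_id": f"A{a:02d}",
                            "group": group,
                            "channel": c,
                            "statistic": stat,
                            "event_type": event_type,
                            "baseline_entropy": base_c,
                            "outcome": y,
                        }
                    )
    return pd.DataFrame(rows)
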