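"""Sliding spike rates, pairwise coactivity, cofluctuation events, event rates.

The chain is: per-channel spike counts in contiguous bins -> causal sliding
mean/SD rate series -> pairwise Pearson correlations over a causal window (the
"coactivity" series, one value per channel pair per timestamp) -> the
percentage of pairs whose correlation exceeds a threshold C (the
"cofluctuation" series) -> contiguous intervals opened by an up-crossing of a
second threshold T ("events") -> the event rate ER in events/s.

All windows are causal: the value at time t uses data in (t - W, t] only.
Pearson windows where either rate series is constant are undefined (NaN) and
excluded from the percentage denominators rather than silently zeroed.

The (C, T) pair is chosen per session per statistic by a plateau
("convergence") criterion on the ER(C, T) surface; a log-normal fit of the
cofluctuation distribution with a 68% band serves as a heavy-tail diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InsufficientVarianceError,
    InvalidInputError,
    InvalidParameterError,
)
from .synthetic import SpikeTrain

__all__ = [
    "RateSeries",
    "CoactivitySeries",
    "CofluctuationSeries",
    "EventSeries",
    "LogNormalFit",
    "ThresholdSelection",
    "sliding_rate",
    "coactivity_series",
    "cofluctuation",
    "detect_events",
    "select_convergent_thresholds",
    "fit_lognormal",
    "DEFAULT_C_GRID",
    "DEFAULT_T_GRID",
]

DEFAULT_C_GRID = np.round(np.arange(0.50, 0.951, 0.05), 2)
DEFAULT_T_GRID = np.arange(10.0, 91.0, 10.0)


@dataclass
class RateSeries:
    """Causal sliding statistic (mean or SD) of binned spike rates."""

    values: np.ndarray
    timestamps: np.ndarray
    statistic: str  # "MEAN" | "STD"
    rate_bin: float
    stat_window: float
    step: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.statistic not in ("MEAN", "STD"):
            raise InvalidParameterError("statistic must be MEAN or STD")


@dataclass
class CoactivitySeries:
    """Pairwise Pearson R of sliding rates over a causal correlation window.

    ``R`` is timestamps x pairs; undefined (zero-variance) windows are NaN.
    """

    R: np.ndarray
    timestamps: np.ndarray
    pairs: list[tuple[int, int]]
    corr_window: float
    step: float
    statistic: str


@dataclass
class CofluctuationSeries:
    """Percentage (0-100) of defined pairs with R > C at each timestamp."""

    values: np.ndarray
    timestamps: np.ndarray
    C: float
    statistic: str

    @property
    def step(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0]) if self.timestamps.size > 1 else np.nan


@dataclass
class EventSeries:
    """Binary event indicator, intervals, and the event rate ER (events/s)."""

    indicator: np.ndarray
    timestamps: np.ndarray
    intervals: list[tuple[float, float]]
    T: float
    C: float
    ER: float
    statistic: str


@dataclass
class LogNormalFit:
    """Log-normal fit of positive cofluctuation values and its 68% band."""

    mu_fit: float
    sigma_fit: float
    band: tuple[float, float]
    frac_outside: float
    n: int


@dataclass
class ThresholdSelection:
    """Convergent (C, T) choice plus the audited ER surface."""

    C: float
    T: float
    er_surface: np.ndarray  # len(C_grid) x len(T_grid)
    C_grid: np.ndarray
    T_grid: np.ndarray
    convergent_mask: np.ndarray
    converged: bool


def sliding_rate(
    train: SpikeTrain,
    rate_bin: float = 0.1,
    stat_window: float = 10.0,
    step: float = 1.0,
    statistic: str = "MEAN",
) -> RateSeries:
    """Causal sliding mean or SD of binned spike rates.

    Spikes are counted in contiguous left-closed bins of width ``rate_bin``
    and converted to Hz; at each output timestamp t (multiples of ``step``
    with t >= ``stat_window``) the statistic is taken over the bins inside
    (t - stat_window, t]. The SD uses the n-1 (sample) denominator.
    """
    if statistic not in ("MEAN", "STD"):
        raise InvalidParameterError("statistic must be MEAN or STD")
    if rate_bin <= 0 or stat_window <= 0 or step <= 0:
        raise InvalidParameterError("rate_bin, stat_window and step must be positive")
    if rate_bin > stat_window:
        raise InvalidParameterError("rate_bin must not exceed stat_window")
    if train.duration < stat_window:
        raise InvalidParameterError("train shorter than stat_window")

    n_bins = int(np.floor(train.duration / rate_bin + 1e-9))
    counts = np.zeros(n_bins)
    if train.n_spikes:
        idx = np.floor(train.times / rate_bin).astype(np.int64)
        idx = idx[idx < n_bins]
        np.add.at(counts, idx, 1.0)
    rates = counts / rate_bin

    w = int(round(stat_window / rate_bin))
    t_out = np.arange(stat_window, train.duration * (1 + 1e-12) + 1e-9, step)
    t_out = t_out[np.round(t_out / rate_bin).astype(np.int64) <= n_bins]
    i1 = np.round(t_out / rate_bin).astype(np.int64)
    i0 = i1 - w

    cs = np.concatenate([[0.0], np.cumsum(rates)])
    s1 = cs[i1] - cs[i0]
    if statistic == "MEAN":
        vals = s1 / w
    else:
        cs2 = np.concatenate([[0.0], np.cumsum(rates**2)])
        s2 = cs2[i1] - cs2[i0]
        var = np.maximum(s2 - s1**2 / w, 0.0) / (w - 1)
        vals = np.sqrt(var)
    return RateSeries(
        values=vals,
        timestamps=t_out,
        statistic=statistic,
        rate_bin=rate_bin,
        stat_window=stat_window,
        step=step,
    )


def coactivity_series(
    rates: list[RateSeries],
    corr_window: float = 60.0,
    step: float = 1.0,
) -> CoactivitySeries:
    """Causal sliding pairwise Pearson correlation of rate series.

    All series must share timestamps and statistic. At each output time t the
    correlation uses the rate samples in (t - corr_window, t]; windows where
    either series has zero variance are NaN.
    """
    if len(rates) < 2:
        raise InvalidInputError("need at least two channels")
    t_ref = rates[0].timestamps
    stat = rates[0].statistic
    for r in rates[1:]:
        if r.statistic != stat or r.timestamps.shape != t_ref.shape or not np.allclose(
            r.timestamps, t_ref
        ):
            raise InvalidInputError("rate series timestamps/statistics mismatch")
    s = float(t_ref[1] - t_ref[0])
    w = int(round(corr_window / s))
    if w < 2:
        raise InvalidParameterError("corr_window must span at least two rate samples")
    if t_ref.size < w:
        raise InsufficientDataError("series shorter than corr_window")
    stride = max(int(round(step / s)), 1)

    X = np.vstack([r.values for r in rates])  # C x T
    n_ch = X.shape[0]
    # windows ending at index j cover samples (j-w, j] -> j-w+1 .. j
    ends = np.arange(w - 1, t_ref.size, stride)
    win = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)  # C x (T-w+1) x w
    win = win[:, ends - (w - 1), :]
    mu = win.mean(axis=2, keepdims=True)
    Z = win - mu
    cov = np.einsum("ctw,dtw->tcd", Z, Z)
    sd = np.sqrt(np.einsum("ctw,ctw->ct", Z, Z))  # C x T'
    iu, ju = np.triu_indices(n_ch, k=1)
    denom = sd[iu, :].T * sd[ju, :].T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov[:, iu, ju] / denom
    R[denom <= 0] = np.nan
    R = np.clip(R, -1.0, 1.0)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    return CoactivitySeries(
        R=R,
        timestamps=t_ref[ends],
        pairs=pairs,
        corr_window=corr_window,
        step=stride * s,
        statistic=stat,
    )


def cofluctuation(co: CoactivitySeries, C: float) -> CofluctuationSeries:
    """Percentage of defined channel pairs with R > C at each timestamp."""
    if not 0 < C < 1:
        raise InvalidParameterError("C must be in (0, 1)")
    defined = ~np.isnan(co.R)
    n_def = defined.sum(axis=1)
    n_above = np.nansum(co.R > C, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * n_above / n_def
    vals[n_def == 0] = np.nan
    return CofluctuationSeries(values=vals, timestamps=co.timestamps, C=C, statistic=co.statistic)


def detect_events(cf: CofluctuationSeries, T: float) -> EventSeries:
    """Events as up-crossing/down-crossing intervals of the cofluctuation series.

    An event starts at the first defined timestamp where the series crosses
    from < T to >= T and ends at the next defined timestamp < T (or the end of
    the series). A series that already starts at or above T opens no event
    until it first drops below. Undefined (NaN) timestamps are skipped and do
    not change the crossing state. ER is the event count divided by the
    defined duration in seconds.
    """
    if not 0 < T < 100:
        raise InvalidParameterError("T must be in (0, 100)")
    t = cf.timestamps
    v = cf.values
    step = cf.step if np.isfinite(cf.step) else 1.0
    defined = ~np.isnan(v)
    indicator = np.zeros(t.size, dtype=np.int8)
    intervals: list[tuple[float, float]] = []

    state_above = None  # crossing state, None until the first defined sample
    start: float | None = None
    for k in np.flatnonzero(defined):
        above = v[k] >= T
        if state_above is None:
            state_above = above  # an initial super-threshold run is not an event
        elif above and not state_above:
            start = t[k]
            state_above = True
        elif not above and state_above:
            if start is not None:
                intervals.append((start, float(t[k])))
                start = None
            state_above = False
        if start is not None and above:
            indicator[k] = 1
    if start is not None:
        last = t[defined][-1]
        intervals.append((start, float(last)))

    n_def = int(defined.sum())
    er = len(intervals) / (n_def * step) if n_def else 0.0
    return EventSeries(
        indicator=indicator,
        timestamps=t,
        intervals=intervals,
        T=T,
        C=cf.C,
        ER=er,
        statistic=cf.statistic,
    )


def _er_surface(co: CoactivitySeries, C_grid: np.ndarray, T_grid: np.ndarray) -> np.ndarray:
    er = np.zeros((len(C_grid), len(T_grid)))
    for i, c in enumerate(C_grid):
        cf = cofluctuation(co, float(c))
        for j, tthr in enumerate(T_grid):
            er[i, j] = detect_events(cf, float(tthr)).ER
    return er


def select_convergent_thresholds(
    co: CoactivitySeries,
    C_grid: np.ndarray | None = None,
    T_grid: np.ndarray | None = None,
    tol: float = 0.4,
) -> ThresholdSelection:
    """Pick a (C, T) pair inside a plateau of the ER(C, T) surface.

    A grid point is convergent when ER > 0 and the relative ER change to every
    in-grid 4-neighbour is <= tol. Among convergent points the largest
    connected plateau wins; within it (and among equal-sized plateaus) the
    lowest C, then lowest T, is returned. If no point is convergent the point
    with the smallest summed relative neighbour change is returned, flagged.
    """
    C_grid = DEFAULT_C_GRID if C_grid is None else np.asarray(C_grid, dtype=float)
    T_grid = DEFAULT_T_GRID if T_grid is None else np.asarray(T_grid, dtype=float)
    if np.any(np.diff(C_grid) <= 0) or np.any(np.diff(T_grid) <= 0):
        raise InvalidParameterError("grids must be sorted ascending")
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")

    er = _er_surface(co, C_grid, T_grid)
    nC, nT = er.shape
    conv = np.zeros((nC, nT), dtype=bool)
    rough = np.full((nC, nT), np.inf)
    for i in range(nC):
        for j in range(nT):
            nbrs = [
                er[i + di, j + dj]
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= i + di < nC and 0 <= j + dj < nT
            ]
            if er[i, j] > 0:
                rel = [abs(nb - er[i, j]) / er[i, j] for nb in nbrs]
                rough[i, j] = sum(rel)
                conv[i, j] = all(r <= tol for r in rel)

    if conv.any():
        # connected plateaus under 4-adjacency
        labels = -np.ones((nC, nT), dtype=int)
        comps: list[list[tuple[int, int]]] = []
        for i in range(nC):
            for j in range(nT):
                if conv[i, j] and labels[i, j] < 0:
                    stack = [(i, j)]
                    comp = []
                    labels[i, j] = len(comps)
                    while stack:
                        a, b = stack.pop()
                        comp.append((a, b))
                        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                            x, y = a + di, b + dj
                            if 0 <= x < nC and 0 <= y < nT and conv[x, y] and labels[x, y] < 0:
                                labels[x, y] = len(comps)
                                stack.append((x, y))
                    comps.append(comp)
        best = max(comps, key=lambda comp: (len(comp), [-min(comp)[0], -min(comp)[1]]))
        ci, tj = min(best)
        converged = True
    else:
        finite = np.isfinite(rough)
        if finite.any():
            flat = np.where(finite, rough, np.inf)
            ci, tj = np.unravel_index(np.argmin(flat), flat.shape)
        else:  # all-zero surface: no events anywhere
            ci, tj = 0, 0
        converged = False

    return ThresholdSelection(
        C=float(C_grid[ci]),
        T=float(T_grid[tj]),
        er_surface=er,
        C_grid=C_grid,
        T_grid=T_grid,
        convergent_mask=conv,
        converged=converged,
    )


def fit_lognormal(cf: CofluctuationSeries, min_n: int = 100) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of the positive cofluctuation values.

    ``mu_fit``/``sigma_fit`` are the mean and SD of the natural logs; the band
    is the original-scale ±1-SD interval (68%), and ``frac_outside`` the
    fraction of positive samples outside it — a heavy-tail diagnostic (~0.317
    for a true log-normal).
    """
    v = cf.values
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} positive values, got {v.size}")
    logs = np.log(v)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # ML estimate
    if sigma <= 1e-9 * max(1.0, abs(mu)):
        raise InsufficientVarianceError("cofluctuation values are all equal")
    lo, hi = float(np.exp(mu - sigma)), float(np.exp(mu + sigma))
    frac = float(np.mean((v < lo) | (v > hi)))
    return LogNormalFit(mu_fit=mu, sigma_fit=sigma, band=(lo, hi), frac_outside=frac, n=int(v.size))
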