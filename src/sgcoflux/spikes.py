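"""Unsupervised competitive adaptive-threshold spike detection.

The detector treats positive and negative excursions as two competitors. Both
barriers start at the trace's extreme amplitudes and are moved toward zero in
small multiplicative steps; the first polarity to accumulate a minimal number
of threshold crossings "wins the competition", its crossing extrema are
recorded as multi-unit spikes, and the surrounding samples are masked to zero.
Both starting barriers are then shrunk and the competition repeats, so large
spikes are consumed before smaller ones. Barriers never start below a floor
expressed in robust noise SDs (``median(|x|) / 0.6745``); detection halts
when a round steps below that floor without producing enough crossings, i.e.
when nothing above the noise floor remains to win.

No spike sorting is attempted: the output is a per-channel multi-unit train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .synthetic import SpikeTrain

__all__ = ["DetectorParams", "DetectionResult", "count_crossings", "detect_spikes"]


@dataclass
class DetectorParams:
    """Controls of the barrier competition.

    min_crossings
        Crossing count that ends one competition round.
    barrier_step
        Fractional step toward zero per barrier adjustment.
    barrier_shrink
        Factor (<1) applied to both starting barriers between rounds.
    min_barrier
        Halt height in units of the robust noise SD.
    mask_halfwidth_ms
        Half-width of the zeroed region around each detection.
    """

    min_crossings: int = 3
    barrier_step: float = 0.02
    barrier_shrink: float = 0.8
    min_barrier: float = 4.0
    mask_halfwidth_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.min_crossings < 1:
            raise InvalidParameterError("min_crossings must be >= 1")
        if not 0 < self.barrier_step < 1:
            raise InvalidParameterError("barrier_step must be in (0, 1)")
        if not 0 < self.barrier_shrink < 1:
            raise InvalidParameterError("barrier_shrink must be in (0, 1)")
        if self.min_barrier <= 0 or self.mask_halfwidth_ms <= 0:
            raise InvalidParameterError("min_barrier and mask_halfwidth_ms must be positive")


@dataclass
class DetectionResult:
    train: SpikeTrain
    polarity: np.ndarray  # +1 / -1 per spike, time-sorted
    barrier_history: list[tuple[int, int, float]] = field(default_factory=list)
    robust_sd: float = 0.0


def count_crossings(trace: np.ndarray, barrier: float) -> tuple[int, np.ndarray]:
    """Crossings of a signed barrier: maximal runs of samples beyond it.

    A crossing is a maximal run of consecutive samples with ``x >= barrier``
    (positive barrier) or ``x <= barrier`` (negative barrier); its extremum is
    the sample of largest magnitude in the run.
    """
    if barrier == 0:
        raise InvalidParameterError("barrier must be non-zero")
    trace = np.asarray(trace, dtype=float)
    beyond = trace >= barrier if barrier > 0 else trace <= barrier
    if not beyond.any():
        return 0, np.array([], dtype=np.int64)
    edges = np.diff(beyond.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if beyond[0]:
        starts = np.concatenate([[0], starts])
    if beyond[-1]:
        ends = np.concatenate([ends, [trace.size]])
    extrema = np.empty(starts.size, dtype=np.int64)
    for k, (a, b) in enumerate(zip(starts, ends)):
        seg = trace[a:b]
        extrema[k] = a + (np.argmax(seg) if barrier > 0 else np.argmin(seg))
    return starts.size, extrema


def _runs_from_subset(idx: np.ndarray, vals: np.ndarray, barrier: float):
    """Crossing runs restricted to a sparse candidate subset.

    ``idx`` are sample indices (sorted) whose values may exceed the lowest
    barrier ever tested; runs split where indices are non-adjacent or values
    fall back below the barrier.
    """
    beyond = vals >= barrier if barrier > 0 else vals <= barrier
    if not beyond.any():
        return 0, np.array([], dtype=np.int64)
    sel = np.flatnonzero(beyond)
    # split where selected candidate indices are not consecutive samples
    breaks = np.flatnonzero(np.diff(idx[sel]) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [sel.size]])
    extrema = np.empty(starts.size, dtype=np.int64)
    v = vals[sel]
    for k, (a, b) in enumerate(zip(starts, ends)):
        seg = v[a:b]
        j = np.argmax(seg) if barrier > 0 else np.argmin(seg)
        extrema[k] = idx[sel[a + j]]
    return starts.size, extrema


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    params: DetectorParams | None = None,
) -> DetectionResult:
    """Run the barrier competition on one channel of raw voltage."""
    params = params or DetectorParams()
    trace = np.asarray(trace, dtype=float)
    if np.isnan(trace).any():
        raise InvalidInputError("trace contains NaN")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if trace.size < fs:
        raise InvalidParameterError("need at least 1 s of samples")

    robust_sd = float(np.median(np.abs(trace)) / 0.6745)
    floor = params.min_barrier * robust_sd
    mask_hw = max(int(round(params.mask_halfwidth_ms * 1e-3 * fs)), 1)

    spike_idx: list[int] = []
    spike_pol: list[int] = []
    history: list[tuple[int, int, float]] = []

    peak_abs = float(np.max(np.abs(trace))) if trace.size else 0.0
    if peak_abs == 0.0:
        return DetectionResult(
            train=SpikeTrain(times=np.array([]), channel_id=-1, duration=trace.size / fs),
            polarity=np.array([], dtype=int),
            barrier_history=history,
            robust_sd=robust_sd,
        )
    if floor <= 0:
        # noiseless trace: robust SD degenerates to zero; use a relative floor
        floor = 1e-6 * peak_abs

    # sparse working set: only samples that could ever cross a tested barrier
    cand = np.flatnonzero(np.abs(trace) >= floor)
    cvals = trace[cand].copy()
    alive = np.ones(cand.size, dtype=bool)

    start_plus = float(trace.max())
    start_minus = float(trace.min())
    iteration = 0
    halted = False
    while not halted:
        # starting barriers never begin below the halt height: clamp at the
        # floor, so the final rounds sweep everything remaining above it and
        # the competition ends only when no polarity can win any more
        b_plus = max(start_plus, floor)
        b_minus = min(start_minus, -floor)
        idx = cand[alive]
        vals = cvals[alive]
        pos_mask = vals > 0
        idx_p, vals_p = idx[pos_mask], vals[pos_mask]
        idx_m, vals_m = idx[~pos_mask], vals[~pos_mask]
        winner = 0
        while True:
            # a side whose barrier has fallen below the floor sits out
            if b_plus >= floor:
                n_plus, ext_plus = _runs_from_subset(idx_p, vals_p, b_plus)
            else:
                n_plus, ext_plus = 0, None
            if -b_minus >= floor:
                n_minus, ext_minus = _runs_from_subset(idx_m, vals_m, b_minus)
            else:
                n_minus, ext_minus = 0, None
            plus_ok = n_plus >= params.min_crossings
            minus_ok = n_minus >= params.min_crossings
            if plus_ok or minus_ok:
                if plus_ok and minus_ok:
                    # tie at the same adjustment step: the side with the larger
                    # extremum magnitude wins (equivariant under negation);
                    # exact magnitude ties go to the plus barrier
                    mag_p = float(np.max(trace[ext_plus]))
                    mag_m = float(-np.min(trace[ext_minus]))
                    plus_ok = mag_p >= mag_m
                if plus_ok:
                    winner, ext, b_win = 1, ext_plus, b_plus
                else:
                    winner, ext, b_win = -1, ext_minus, b_minus
                break
            b_plus *= 1.0 - params.barrier_step
            b_minus *= 1.0 - params.barrier_step
            if b_plus < floor and -b_minus < floor:
                halted = True
                break
        if halted or winner == 0:
            break
        history.append((iteration, winner, float(b_win)))
        spike_idx.extend(int(e) for e in ext)
        spike_pol.extend(winner for _ in ext)
        # mask +/- mask_halfwidth around each detection (zero in the working set)
        for e in ext:
            lo, hi = e - mask_hw, e + mask_hw
            a = np.searchsorted(cand, lo)
            b = np.searchsorted(cand, hi, side="right")
            alive[a:b] = False
        start_plus *= params.barrier_shrink
        start_minus *= params.barrier_shrink
        iteration += 1

    order = np.argsort(spike_idx, kind="stable")
    idx_sorted = np.asarray(spike_idx, dtype=np.int64)[order]
    pol_sorted = np.asarray(spike_pol, dtype=int)[order]
    times = idx_sorted / fs
    # masking guarantees uniqueness, but keep the train contract defensive
    uniq = np.concatenate([[True], np.diff(times) > 0]) if times.size else np.array([], bool)
    train = SpikeTrain(times=times[uniq], channel_id=-1, duration=trace.size / fs)
    return DetectionResult(
        train=train,
        polarity=pol_sorted[uniq] if times.size else pol_sorted,
        barrier_history=history,
        robust_sd=robust_sd,
    )
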