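"""Contrastive neural specificity of spike sampling relative to LVP.

The specificity map A(t, b) contrasts how a channel's spikes "sample" the
left-ventricular-pressure waveform against the random-sampling limit: at each
time t, p_spike(b) is the normalised histogram (over LVP amplitude bins b) of
the LVP values observed at the spike times inside the causal window
(t - W, t], and p_rand(b) is the same histogram built from every LVP sample in
that window, i.e. sampling uniform in time with no temporal preference.
A = p_spike - p_rand, so each row sums to zero, rows are bounded in [-1, 1],
and positive entries mark pressure states the channel over-samples (e.g.
near-peak systole when spiking is phase locked to the cardiac cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTargetError, InvalidParameterError
from .synthetic import PressureSeries, SpikeTrain

__all__ = ["TargetBins", "SpecificityMap", "make_bins", "specificity_map"]


@dataclass
class TargetBins:
    """Uniform LVP-amplitude bins; outer bins absorb out-of-range values."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 3 or np.any(np.diff(self.edges) <= 0):
            raise InvalidParameterError("edges must be strictly increasing with B >= 2")

    @property
    def B(self) -> int:
        return self.edges.size - 1

    def index(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value, clipping beyond-range values into the outer bins."""
        return np.clip(np.searchsorted(self.edges, values, side="right") - 1, 0, self.B - 1)


@dataclass
class SpecificityMap:
    """Per-channel time x LVP-bin contrastive sampling metric."""

    A: np.ndarray  # n_timestamps x B, NaN rows where no spikes in window
    timestamps: np.ndarray
    bins: TargetBins
    spec_window: float
    step: float
    channel_id: int = -1
    p_spike: np.ndarray | None = None  # spike-sampling PDF per row
    p_rand: np.ndarray | None = None  # random-sampling (uniform-in-time) PDF

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.A[:, 0])


def make_bins(
    lvp: PressureSeries,
    B: int = 20,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> TargetBins:
    """B uniform-width bins between two percentiles of the LVP amplitude."""
    if B < 2:
        raise InvalidParameterError("need at least 2 bins")
    if not 0 <= lo_pct < hi_pct <= 100:
        raise InvalidParameterError("need 0 <= lo_pct < hi_pct <= 100")
    lo, hi = np.percentile(lvp.samples, [lo_pct, hi_pct])
    if hi <= lo:
        raise DegenerateTargetError("LVP amplitude carries no spread between percentiles")
    return TargetBins(edges=np.linspace(lo, hi, B + 1))


def specificity_map(
    train: SpikeTrain,
    lvp: PressureSeries,
    bins: TargetBins,
    spec_window: float = 15.0,
    step: float = 1.0,
) -> SpecificityMap:
    """A(t, b) = p_spike(b) - p_rand(b) over causal windows (t - W, t].

    LVP is sampled at spike times by nearest-sample lookup. Rows with zero
    spikes in the window are undefined (NaN). A train with no spikes at all
    yields a fully undefined map.
    """
    if spec_window <= 0 or step <= 0:
        raise InvalidParameterError("spec_window and step must be positive")
    if spec_window > train.duration:
        raise InvalidParameterError("spec_window exceeds the recording duration")
    B = bins.B

    # block accumulation: per step-block histograms, then cumulative sums
    n_blocks = int(np.floor(train.duration / step + 1e-9))
    w_blocks = int(round(spec_window / step))

    lvp_bin = bins.index(lvp.samples)
    lvp_block = np.floor((lvp.times - lvp.t0) / step).astype(np.int64)
    keep = lvp_block < n_blocks
    rand_counts = np.bincount(
        lvp_block[keep] * B + lvp_bin[keep], minlength=n_blocks * B
    ).reshape(n_blocks, B)

    spike_counts = np.zeros((n_blocks, B), dtype=np.int64)
    if train.n_spikes:
        sv = lvp.value_at(train.times)
        sb = bins.index(sv)
        sblock = np.floor(train.times / step).astype(np.int64)
        k = sblock < n_blocks
        spike_counts = np.bincount(
            sblock[k] * B + sb[k], minlength=n_blocks * B
        ).reshape(n_blocks, B)

    rand_cum = np.vstack([np.zeros(B), np.cumsum(rand_counts, axis=0)])
    spike_cum = np.vstack([np.zeros(B), np.cumsum(spike_counts, axis=0)])

    ends = np.arange(w_blocks, n_blocks + 1)
    t_out = ends * step
    rw = rand_cum[ends] - rand_cum[ends - w_blocks]
    sw = spike_cum[ends] - spike_cum[ends - w_blocks]

    rand_tot = rw.sum(axis=1, keepdims=True)
    spike_tot = sw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_spike = sw / spike_tot
        p_rand = rw / rand_tot
        A = p_spike - p_rand
    undef = (spike_tot[:, 0] == 0) | (rand_tot[:, 0] == 0)
    A[undef] = np.nan
    p_spike[undef] = np.nan
    return SpecificityMap(
        A=A,
        timestamps=t_out,
        bins=bins,
        spec_window=spec_window,
        step=step,
        channel_id=train.channel_id,
        p_spike=p_spike,
        p_rand=p_rand,
    )
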