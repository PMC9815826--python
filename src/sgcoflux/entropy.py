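"""Entropy coherence of neural specificity, and its event/non-event partition.

Each specificity row A(t, .) is reduced to a normalised Shannon entropy: the
magnitudes |A| are renormalised to a distribution q over LVP bins and
H(t) = -sum_b q ln q / ln B, in normalised units (n.u.) in [0, 1]. Low entropy
means the channel's over/under-sampling is concentrated on few pressure states
(coherent specificity); H = 1 means no preference. Rows with |A| identically
zero are assigned H = 1 (the vanishing-specificity limit). Per channel the
series is summarised by its mean and sample SD, and partitioned by the
cofluctuation event indicator into inside/outside-event statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .events import EventSeries
from .specificity import SpecificityMap

__all__ = [
    "EntropySeries",
    "EntropySummary",
    "EventEntropySummary",
    "entropy_series",
    "summarize_entropy",
    "event_partition",
]


@dataclass
class EntropySeries:
    values: np.ndarray  # n.u. in [0, 1], NaN where the specificity row is undefined
    timestamps: np.ndarray
    channel_id: int


@dataclass
class EntropySummary:
    channel_id: int
    entropy_mean: float
    entropy_std: float
    n_defined: int


@dataclass
class EventEntropySummary:
    channel_id: int
    statistic: str  # coactivity statistic the events came from
    inside_mean: float
    inside_std: float
    outside_mean: float
    outside_std: float
    n_inside: int
    n_outside: int
    partial: bool  # True when one partition is empty


def entropy_series(spec: SpecificityMap, use_p_spike: bool = False) -> EntropySeries:
    """Normalised Shannon entropy of each defined specificity row.

    By default the entropy is taken on the renormalised |A| distribution (the
    specificity magnitudes); ``use_p_spike`` switches the base distribution to
    the spike-sampling PDF itself.
    """
    if use_p_spike:
        if spec.p_spike is None:
            raise InvalidInputError("map carries no spike-sampling PDF")
        A = spec.p_spike
    else:
        A = spec.A
    B = A.shape[1]
    vals = np.full(A.shape[0], np.nan)
    defined = spec.defined
    if defined.any():
        mag = np.abs(A[defined])
        tot = mag.sum(axis=1, keepdims=True)
        h = np.ones(mag.shape[0])  # sum |A| = 0 -> maximal incoherence
        pos = tot[:, 0] > 0
        if pos.any():
            q = mag[pos] / tot[pos]
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(q > 0, q * np.log(q), 0.0)
            h[pos] = -terms.sum(axis=1) / np.log(B)
        vals[defined] = np.clip(h, 0.0, 1.0)
    return EntropySeries(values=vals, timestamps=spec.timestamps, channel_id=spec.channel_id)


def summarize_entropy(es: EntropySeries) -> EntropySummary:
    """Mean and sample SD of the defined entropy samples (one row per channel)."""
    v = es.values[~np.isnan(es.values)]
    if v.size < 2:
        raise InsufficientDataError("need at least two defined entropy samples")
    return EntropySummary(
        channel_id=es.channel_id,
        entropy_mean=float(v.mean()),
        entropy_std=float(v.std(ddof=1)),
        n_defined=int(v.size),
    )


def event_partition(es: EntropySeries, ev: EventSeries) -> EventEntropySummary:
    """Split defined entropy samples by the event indicator.

    Series are joined on nearest timestamps within half an event-series step;
    entropy samples with no event timestamp nearby are dropped. A partition
    with no samples marks the summary partial (excluded from model input).
    """
    if es.timestamps.size == 0 or ev.timestamps.size == 0:
        raise InvalidInputError("empty series")
    step = float(ev.timestamps[1] - ev.timestamps[0]) if ev.timestamps.size > 1 else 1.0
    idx = np.searchsorted(ev.timestamps, es.timestamps)
    idx = np.clip(idx, 0, ev.timestamps.size - 1)
    left = np.clip(idx - 1, 0, ev.timestamps.size - 1)
    use_left = np.abs(ev.timestamps[left] - es.timestamps) < np.abs(
        ev.timestamps[idx] - es.timestamps
    )
    nearest = np.where(use_left, left, idx)
    ok = np.abs(ev.timestamps[nearest] - es.timestamps) <= step / 2 + 1e-9
    ok &= ~np.isnan(es.values)

    inside = ok & (ev.indicator[nearest] == 1)
    outside = ok & (ev.indicator[nearest] == 0)
    vi = es.values[inside]
    vo = es.values[outside]

    def _stats(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return np.nan, np.nan
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    im, isd = _stats(vi)
    om, osd = _stats(vo)
    return EventEntropySummary(
        channel_id=es.channel_id,
        statistic=ev.statistic,
        inside_mean=im,
        inside_std=isd,
        outside_mean=om,
        outside_std=osd,
        n_inside=int(vi.size),
        n_outside=int(vo.size),
        partial=(vi.size == 0 or vo.size == 0),
    )
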