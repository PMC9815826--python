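"""Normalised entropy coherence and its event/non-event partition."""

import numpy as np
import pytest

from sgcoflux.entropy import (
    EntropySeries,
    entropy_series,
    event_partition,
    summarize_entropy,
)
from sgcoflux.errors import InsufficientDataError
from sgcoflux.events import EventSeries
from sgcoflux.specificity import SpecificityMap, TargetBins


def map_from_rows(rows, step=1.0):
    rows = np.asarray(rows, dtype=float)
    B = rows.shape[1]
    return SpecificityMap(
        A=rows,
        timestamps=np.arange(1, rows.shape[0] + 1, dtype=float) * step,
        bins=TargetBins(edges=np.arange(B + 1, dtype=float)),
        spec_window=step,
        step=step,
    )


def event_series(indicator, step=1.0):
    ind = np.asarray(indicator, dtype=np.int8)
    return EventSeries(
        indicator=ind,
        timestamps=np.arange(1, ind.size + 1, dtype=float) * step,
        intervals=[],
        T=50.0,
        C=0.5,
        ER=0.0,
        statistic="MEAN",
    )


class TestEntropySeries:
    def test_uniform_magnitudes_reach_maximum(self):
        es = entropy_series(map_from_rows([[0.1, -0.1, 0.1, -0.1]]))
        assert es.values[0] == pytest.approx(1.0)

    def test_concentrated_magnitude_reaches_zero(self):
        es = entropy_series(map_from_rows([[0.0, 0.8, 0.0, 0.0]]))
        assert es.values[0] == pytest.approx(0.0)

    def test_closed_form_half_quarter_quarter(self):
        # q = (1/2, 1/4, 1/4, 0) over B=4: H = (1.5 ln 2) / ln 4 = 0.75
        es = entropy_series(map_from_rows([[0.5, 0.25, -0.25, 0.0]]))
        assert es.values[0] == pytest.approx(0.75, abs=1e-12)

    def test_zero_rows_map_to_maximal_incoherence(self):
        es = entropy_series(map_from_rows([[0.0, 0.0, 0.0, 0.0]]))
        assert es.values[0] == pytest.approx(1.0)

    def test_undefined_rows_propagate(self):
        rows = np.array([[0.5, -0.5, 0.0], [np.nan, np.nan, np.nan]])
        es = entropy_series(map_from_rows(rows))
        assert np.isnan(es.values[1]) and not np.isnan(es.values[0])

    def test_bounds_on_random_maps(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(-1, 1, size=(50, 20))
        es = entropy_series(map_from_rows(rows))
        assert np.all((es.values >= 0) & (es.values <= 1))


class TestSummarizeEntropy:
    def test_constant_series_has_zero_std(self):
        es = EntropySeries(values=np.full(10, 0.7), timestamps=np.arange(10.0), channel_id=0)
        s = summarize_entropy(es)
        assert s.entropy_mean == pytest.approx(0.7)
        assert s.entropy_std == 0.0

    def test_alternating_series_sample_sd(self):
        vals = np.tile([0.0, 1.0], 5)
        es = EntropySeries(values=vals, timestamps=np.arange(10.0), channel_id=0)
        s = summarize_entropy(es)
        assert s.entropy_mean == pytest.approx(0.5)
        assert s.entropy_std == pytest.approx(np.sqrt(0.25 * 10 / 9))  # ddof=1

    def test_too_few_defined_samples(self):
        es = EntropySeries(
            values=np.array([0.5, np.nan, np.nan]), timestamps=np.arange(3.0), channel_id=0
        )
        with pytest.raises(InsufficientDataError):
            summarize_entropy(es)


class TestEventPartition:
    def test_all_outside_matches_summary(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.4, 0.9, 20)
        es = EntropySeries(values=vals, timestamps=np.arange(1, 21.0), channel_id=2)
        part = event_partition(es, event_series(np.zeros(20)))
        summ = summarize_entropy(es)
        assert part.n_inside == 0 and part.partial
        assert part.outside_mean == pytest.approx(summ.entropy_mean)
        assert part.outside_std == pytest.approx(summ.entropy_std)

    def test_hand_built_partition(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        ind = np.array([0, 0, 1, 1, 0, 0, 1, 0])
        es = EntropySeries(values=vals, timestamps=np.arange(1, 9.0), channel_id=0)
        part = event_partition(es, event_series(ind))
        assert (part.n_inside, part.n_outside) == (3, 5)
        assert part.inside_mean == pytest.approx(np.mean([0.3, 0.4, 0.7]))
        assert part.outside_mean == pytest.approx(np.mean([0.1, 0.2, 0.5, 0.6, 0.8]))
        assert not part.partial

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 1, 30)
        ind = (rng.uniform(size=30) < 0.3).astype(int)
        t = np.arange(1, 31.0)
        base = event_partition(
            EntropySeries(values=vals, timestamps=t, channel_id=0), event_series(ind)
        )
        perm = rng.permutation(30)
        # shuffle jointly, then re-sort by time: partition stats must not move
        shuffled = event_partition(
            EntropySeries(values=vals[perm], timestamps=t, channel_id=0),
            event_series(ind[perm]),
        )
        assert shuffled.inside_mean == pytest.approx(base.inside_mean)
        assert shuffled.outside_mean == pytest.approx(base.outside_mean)
        assert (shuffled.n_inside, shuffled.n_outside) == (base.n_inside, base.n_outside)


class TestPlantedBurstCoherence:
    def test_in_burst_entropy_lower_on_nearly_all_channels(self):
        """The generator strengthens phase locking inside bursts, so entropy
        partitioned by the (window-aligned) true burst intervals is lower
        inside than outside on >= 90% of channels over 10 seeds."""
        from sgcoflux.specificity import make_bins, specificity_map
        from sgcoflux.synthetic import CohortConfig, SpikeTrain, generate_session

        lower = total = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_channels=4,
                session_duration=600.0,
                event_rate_true=0.02,
                render_voltage=False,
            )
            sess, truth = generate_session(
                cfg, "control", "X", np.random.SeedSequence(entropy=31, spawn_key=(40, seed))
            )
            bins = make_bins(sess.lvp, 20)
            w = 15.0
            for ch, times in enumerate(truth.true_spikes):
                tr = SpikeTrain(times=times, channel_id=ch, duration=600.0)
                es = entropy_series(specificity_map(tr, sess.lvp, bins, w, 1.0))
                t = es.timestamps
                ind = np.zeros(t.size, np.int8)
                for a, b in truth.true_event_intervals:
                    # causal window (t-w, t] overlaps the burst's majority
                    ind |= ((t >= a + w / 3) & (t <= b + w / 3)).astype(np.int8)
                ev = EventSeries(
                    indicator=ind,
                    timestamps=t,
                    intervals=truth.true_event_intervals,
                    T=50.0,
                    C=0.5,
                    ER=0.0,
                    statistic="MEAN",
                )
                p = event_partition(es, ev)
                if not p.partial:
                    total += 1
                    lower += p.inside_mean < p.outside_mean
        assert total >= 30
        assert lower / total >= 0.9
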