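"""Rate windows, coactivity, cofluctuation, events and log-normal fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sgcoflux import synthetic as sy
from sgcoflux.errors import (
    InsufficientDataError,
    InsufficientVarianceError,
    InvalidInputError,
    InvalidParameterError,
)
from sgcoflux.events import (
    CoactivitySeries,
    CofluctuationSeries,
    RateSeries,
    coactivity_series,
    cofluctuation,
    detect_events,
    fit_lognormal,
    select_convergent_thresholds,
    sliding_rate,
)


def make_rates(values_per_channel, step=1.0, statistic="MEAN"):
    t = np.arange(len(values_per_channel[0])) * step + step
    return [
        RateSeries(
            values=np.asarray(v, float),
            timestamps=t,
            statistic=statistic,
            rate_bin=0.1,
            stat_window=step,
            step=step,
        )
        for v in values_per_channel
    ]


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestSlidingRate:
    def test_uniform_train_mean_is_exact(self):
        times = np.arange(0.05, 120.0, 0.1)  # 10 Hz deterministic
        tr = sy.SpikeTrain(times=times, channel_id=0, duration=120.0)
        rs = sliding_rate(tr, rate_bin=0.1, stat_window=10.0, step=1.0, statistic="MEAN")
        np.testing.assert_allclose(rs.values, 10.0, atol=1e-9)

    def test_constant_rate_std_is_zero(self):
        times = np.arange(0.05, 120.0, 0.1)
        tr = sy.SpikeTrain(times=times, channel_id=0, duration=120.0)
        rs = sliding_rate(tr, rate_bin=0.1, stat_window=10.0, step=1.0, statistic="STD")
        np.testing.assert_allclose(rs.values, 0.0, atol=1e-9)

    def test_empty_train_is_all_zero(self):
        tr = sy.SpikeTrain(times=np.array([]), channel_id=0, duration=120.0)
        for stat in ("MEAN", "STD"):
            rs = sliding_rate(tr, statistic=stat)
            assert np.all(rs.values == 0)

    def test_poisson_mean_within_three_se(self):
        rng = np.random.default_rng(8)
        rate, dur = 5.0, 200.0
        times = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        times = np.unique(times)
        tr = sy.SpikeTrain(times=times, channel_id=0, duration=dur)
        rs = sliding_rate(tr, rate_bin=0.1, stat_window=60.0, step=10.0, statistic="MEAN")
        se = np.sqrt(rate / 60.0)  # Poisson SE of the windowed mean rate
        assert np.all(np.abs(rs.values - rate) < 3 * se)

    def test_precondition_errors(self):
        tr = sy.SpikeTrain(times=np.array([1.0]), channel_id=0, duration=30.0)
        with pytest.raises(InvalidParameterError):
            sliding_rate(tr, rate_bin=2.0, stat_window=1.0)
        with pytest.raises(InvalidParameterError):
            sliding_rate(tr, stat_window=60.0)


class TestCoactivity:
    def test_four_channels_give_six_pairs(self):
        rng = np.random.default_rng(0)
        rates = make_rates(rng.normal(5, 1, size=(4, 50)))
        co = coactivity_series(rates, corr_window=10.0, step=1.0)
        assert len(co.pairs) == 6
        assert co.R.shape[1] == 6

    def test_duplicated_channel_has_unit_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, 50)
        co = coactivity_series(make_rates([x, x.copy(), rng.normal(5, 1, 50)]), 10.0, 1.0)
        pair0 = co.pairs.index((0, 1))
        defined = ~np.isnan(co.R[:, pair0])
        np.testing.assert_allclose(co.R[defined, pair0], 1.0, atol=1e-9)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(5, 40))
        w = 12
        co = coactivity_series(make_rates(X), corr_window=float(w), step=1.0)
        for k, t in enumerate(co.timestamps):
            j = int(round(t)) - 1  # sample index in the rate series
            for p, (a, b) in enumerate(co.pairs):
                ref = brute_pearson(X[a, j - w + 1 : j + 1], X[b, j - w + 1 : j + 1])
                assert co.R[k, p] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_window_is_undefined(self):
        x = np.ones(30)
        y = np.arange(30.0)
        co = coactivity_series(make_rates([x, y]), corr_window=10.0, step=1.0)
        assert np.isnan(co.R).all()

    def test_mismatched_timestamps_rejected(self):
        r1 = make_rates([np.arange(20.0)])[0]
        r2 = make_rates([np.arange(20.0)], step=2.0)[0]
        with pytest.raises(InvalidInputError):
            coactivity_series([r1, r2], 10.0, 1.0)

    def test_causality(self):
        """Perturbing rate samples after t never changes coactivity at or before t."""
        rng = np.random.default_rng(3)
        X = rng.normal(5, 1, size=(3, 60))
        co = coactivity_series(make_rates(X), corr_window=15.0, step=1.0)
        X2 = X.copy()
        X2[:, 40:] += 100.0
        co2 = coactivity_series(make_rates(X2), corr_window=15.0, step=1.0)
        before = co.timestamps <= 40.0  # rate sample at index 39 has t=40
        np.testing.assert_array_equal(co.R[before], co2.R[before])


def cof_series(values, C=0.5, step=1.0):
    return CofluctuationSeries(
        values=np.asarray(values, float),
        timestamps=np.arange(len(values)) * step + step,
        C=C,
        statistic="MEAN",
    )


class TestCofluctuation:
    def test_half_of_six_pairs(self):
        R = np.array([[0.9, 0.8, 0.7, 0.1, 0.0, -0.5]])
        co = CoactivitySeries(
            R=R,
            timestamps=np.array([10.0]),
            pairs=[(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
            corr_window=10.0,
            step=1.0,
            statistic="MEAN",
        )
        cf = cofluctuation(co, 0.6)
        assert cf.values[0] == pytest.approx(50.0)

    def test_all_zero_correlations(self):
        co = CoactivitySeries(
            R=np.zeros((4, 3)),
            timestamps=np.arange(4.0),
            pairs=[(0, 1), (0, 2), (1, 2)],
            corr_window=5.0,
            step=1.0,
            statistic="MEAN",
        )
        assert np.all(cofluctuation(co, 0.5).values == 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_loop_and_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.uniform(-1, 1, size=(20, 10))
        R[rng.uniform(size=R.shape) < 0.1] = np.nan
        co = CoactivitySeries(
            R=R,
            timestamps=np.arange(20.0),
            pairs=[(i, j) for i in range(5) for j in range(i + 1, 5)],
            corr_window=5.0,
            step=1.0,
            statistic="MEAN",
        )
        C = 0.3
        cf = cofluctuation(co, C)
        for t in range(20):
            n_def = n_above = 0
            for p in range(10):
                if not np.isnan(R[t, p]):
                    n_def += 1
                    n_above += R[t, p] > C
            if n_def == 0:
                assert np.isnan(cf.values[t])
            else:
                assert cf.values[t] == pytest.approx(100.0 * n_above / n_def)

    def test_monotone_nonincreasing_in_C(self):
        rng = np.random.default_rng(9)
        R = rng.uniform(-1, 1, size=(50, 6))
        co = CoactivitySeries(
            R=R,
            timestamps=np.arange(50.0),
            pairs=[(i, j) for i in range(4) for j in range(i + 1, 4)],
            corr_window=5.0,
            step=1.0,
            statistic="MEAN",
        )
        prev = None
        for C in np.arange(0.1, 0.95, 0.1):
            vals = cofluctuation(co, float(C)).values
            if prev is not None:
                assert np.all(vals <= prev + 1e-12)
            prev = vals


def brute_force_events(values, T):
    """State-machine oracle for event intervals over defined samples."""
    intervals = []
    state = None
    start = None
    t = np.arange(len(values)) + 1.0
    for k, v in enumerate(values):
        if np.isnan(v):
            continue
        above = v >= T
        if state is None:
            state = above
        elif above and not state:
            start = t[k]
            state = True
        elif not above and state:
            if start is not None:
                intervals.append((start, t[k]))
                start = None
            state = False
    if start is not None:
        defined_t = t[~np.isnan(np.asarray(values, float))]
        intervals.append((start, defined_t[-1]))
    return intervals


class TestDetectEvents:
    def test_hand_counted_events(self):
        cf = cof_series([0, 0.5, 30, 40, 5, 0.2, 50, 0.1])
        ev = detect_events(cf, 20.0)
        assert len(ev.intervals) == 2
        assert ev.ER == pytest.approx(2 / 8)
        np.testing.assert_array_equal(ev.indicator, [0, 0, 1, 1, 0, 0, 1, 0])

    def test_no_events_below_threshold(self):
        ev = detect_events(cof_series([1, 2, 3, 4]), 50.0)
        assert ev.intervals == []
        assert ev.ER == 0.0

    def test_initial_superthreshold_run_is_not_an_event(self):
        ev = detect_events(cof_series([80, 90, 10, 70, 5]), 50.0)
        assert len(ev.intervals) == 1
        assert ev.intervals[0][0] == pytest.approx(4.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_state_machine_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 100, 60)
        vals[rng.uniform(size=60) < 0.1] = np.nan
        ev = detect_events(cof_series(vals), 50.0)
        assert ev.intervals == brute_force_events(vals, 50.0)

    def test_event_duration_nonincreasing_in_T(self):
        """Total time inside events shrinks as T rises (superlevel sets nest).

        The event COUNT is not monotone in T — one long excursion splits into
        several shorter ones as the threshold rises through its interior dips
        — but the indicator time is, for a series that starts below threshold.
        """
        rng = np.random.default_rng(10)
        vals = rng.uniform(0, 100, 300)
        vals[0] = 0.0
        cf = cof_series(vals)
        prev = None
        for T in np.arange(10.0, 95.0, 10.0):
            dur = int(detect_events(cf, float(T)).indicator.sum())
            if prev is not None:
                assert dur <= prev
            prev = dur


class TestSelectConvergentThresholds:
    def _co_from_values(self, values):
        """Coactivity whose single pair replays `values` as correlations."""
        n = len(values)
        return CoactivitySeries(
            R=np.asarray(values, float).reshape(-1, 1),
            timestamps=np.arange(n) + 1.0,
            pairs=[(0, 1)],
            corr_window=5.0,
            step=1.0,
            statistic="MEAN",
        )

    def test_constant_surface_returns_lowest_thresholds(self):
        rng = np.random.default_rng(0)
        # single pair alternating strongly above/below any C: ER constant in (C, T)
        vals = np.tile([0.99, -0.99], 100)
        co = self._co_from_values(vals)
        sel = select_convergent_thresholds(
            co, C_grid=np.array([0.5, 0.6, 0.7]), T_grid=np.array([30.0, 50.0, 70.0])
        )
        assert sel.converged
        assert (sel.C, sel.T) == (0.5, 30.0)
        assert np.all(sel.er_surface > 0)

    def test_plateau_matches_exhaustive_search(self, locked_trains):
        trains, _ = locked_trains
        rates = [sliding_rate(tr, 0.1, 30.0, 1.0, "MEAN") for tr in trains]
        co = coactivity_series(rates, 30.0, 1.0)
        sel = select_convergent_thresholds(co, tol=0.2)
        er = sel.er_surface
        # recompute convergence exhaustively
        nC, nT = er.shape
        conv = np.zeros_like(er, dtype=bool)
        for i in range(nC):
            for j in range(nT):
                if er[i, j] <= 0:
                    continue
                ok = True
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    a, b = i + di, j + dj
                    if 0 <= a < nC and 0 <= b < nT:
                        ok &= abs(er[a, b] - er[i, j]) / er[i, j] <= 0.2
                conv[i, j] = ok
        np.testing.assert_array_equal(sel.convergent_mask, conv)
        if sel.converged:
            ci = list(sel.C_grid).index(sel.C)
            tj = list(sel.T_grid).index(sel.T)
            assert conv[ci, tj]


class TestFitLognormal:
    def test_recovers_standard_lognormal(self):
        rng = np.random.default_rng(12)
        vals = np.exp(rng.standard_normal(100_000))
        fit = fit_lognormal(cof_series(vals))
        assert fit.mu_fit == pytest.approx(0.0, abs=0.02)
        assert fit.sigma_fit == pytest.approx(1.0, abs=0.02)
        assert fit.frac_outside == pytest.approx(0.3173, abs=0.01)

    def test_too_few_positive_values(self):
        with pytest.raises(InsufficientDataError):
            fit_lognormal(cof_series(np.ones(50)))

    def test_constant_values_rejected(self):
        with pytest.raises(InsufficientVarianceError):
            fit_lognormal(cof_series(np.full(200, 7.0)))

    def test_zeros_and_nans_excluded(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([np.exp(rng.standard_normal(500)), np.zeros(100), [np.nan] * 50])
        fit = fit_lognormal(cof_series(vals))
        assert fit.n == 500


class TestThresholdRecovery:
    def test_selected_threshold_er_tracks_true_event_rate(self):
        """With strong burst gain, the ER at the convergent (C, T) stays within
        a factor of two of the generator's true event rate (median over seeds;
        individual seeds may suffer an occasional plateau collapse)."""
        from sgcoflux.pipeline import AnalysisParams, session_event_analysis
        from sgcoflux.synthetic import CohortConfig, generate_session

        ratios = []
        for seed in range(10):
            cfg = sy.CohortConfig(
                session_duration=1200.0, event_rate_true=0.005, render_voltage=False
            )
            _, truth = generate_session(
                cfg, "control", "X", np.random.SeedSequence(entropy=71, spawn_key=(50, seed))
            )
            trains = [
                sy.SpikeTrain(times=t, channel_id=c, duration=1200.0)
                for c, t in enumerate(truth.true_spikes)
            ]
            res = session_event_analysis(trains, AnalysisParams(statistics=("MEAN",)))
            true_er = len(truth.true_event_intervals) / 1200.0
            ratios.append(res["MEAN"]["events"].ER / true_er)
        ratios = np.array(ratios)
        assert 0.5 <= np.median(ratios) <= 2.0
        assert np.sum((ratios >= 0.5) & (ratios <= 2.0)) >= 8


class TestHeavyTailDiagnostic:
    def test_bursty_cohorts_fall_further_outside_lognormal_bands(self):
        """Sessions with localized bursts put more cofluctuation mass outside
        the fitted 68% log-normal band than burst-free sessions."""
        from sgcoflux.synthetic import CohortConfig, generate_session

        means = {}
        for name, event_rate in (("homogeneous", 1e-9), ("bursty", 0.01)):
            fo = []
            for seed in range(5):
                cfg = sy.CohortConfig(
                    session_duration=1200.0, render_voltage=False, event_rate_true=event_rate
                )
                _, truth = generate_session(
                    cfg, "control", "X", np.random.SeedSequence(entropy=888, spawn_key=(seed,))
                )
                trains = [
                    sy.SpikeTrain(times=t, channel_id=c, duration=1200.0)
                    for c, t in enumerate(truth.true_spikes)
                ]
                rates = [sliding_rate(tr) for tr in trains]
                cf = cofluctuation(coactivity_series(rates), 0.7)
                fo.append(fit_lognormal(cf).frac_outside)
            means[name] = np.mean(fo)
        assert means["bursty"] > means["homogeneous"]
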