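"""Measurement battery against hand-traced and analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import rivalsim.measures as ms
import rivalsim.synthetic as syn
from rivalsim.raster import SpikeRaster


def trace_from_labels(labels, window=50.0, counts=30):
    """PerceptTrace with prescribed window labels (A=+1, B=-1, 0=neither)."""
    labels = np.asarray(labels, dtype=np.int8)
    u_a = np.where(labels == 1, counts, np.where(labels == 0, counts // 2, 0))
    u_b = np.where(labels == -1, counts, np.where(labels == 0, counts // 2, 0))
    tot = u_a + u_b
    p = np.where(tot > 0, (u_a - u_b) / np.maximum(tot, 1), 0.0)
    return ms.PerceptTrace(window=window, t_start=0.0, u_a=u_a, u_b=u_b,
                           p=p, label=labels)


def raster_from_trains(trains, duration):
    ids = np.concatenate([np.full(len(t), i) for i, t in enumerate(trains)])
    times = np.concatenate([np.asarray(t, dtype=float) for t in trains])
    order = np.argsort(times, kind="stable")
    return SpikeRaster(ids=ids[order], times=times[order],
                       n_neurons=len(trains), duration=duration)


class TestPerceptTrace:
    def test_printed_formula_arithmetic(self):
        raster = raster_from_trains(
            [np.linspace(1, 49, 30), np.linspace(1, 49, 10)], 50.0)
        tr = ms.percept_trace(raster, [0], [1], window=50.0)
        assert tr.u_a[0] == 30 and tr.u_b[0] == 10
        assert tr.p[0] == pytest.approx(0.5)
        assert tr.label[0] == ms.POOL_A

    def test_tie_and_empty_windows_are_neither(self):
        raster = raster_from_trains(
            [[10.0, 20.0], [15.0, 25.0]], 150.0)  # equal counts in window 0
        tr = ms.percept_trace(raster, [0], [1], window=50.0)
        assert tr.label[0] == ms.NEITHER  # u_a == u_b > 0
        assert tr.label[2] == ms.NEITHER  # empty window
        # |P| exactly 1/3 is classified neither (strict inequalities)
        tr2 = trace_from_labels([0])
        tr2.p[0] = 1 / 3
        tr2.label[:] = 0
        assert tr2.label[0] == ms.NEITHER

    def test_requires_nonempty_pools(self):
        raster = raster_from_trains([[10.0]], 100.0)
        with pytest.raises(ValueError):
            ms.percept_trace(raster, [], [0])


class TestDominanceDurations:
    def test_hand_traced_filtering(self):
        """[A x10, neither x2, B x8] at 300 ms threshold: the sub-threshold
        gap is absorbed, so A reports 600 ms and B 400 ms."""
        tr = trace_from_labels([1] * 10 + [0] * 2 + [-1] * 8)
        stats = ms.dominance_durations(tr, 300.0)
        assert [e.label for e in stats.epochs] == [1, -1]
        assert [e.duration for e in stats.epochs] == [600.0, 400.0]
        # both epochs are censored (first/last) -> moments undefined
        assert not stats.defined

    def test_qualifying_neither_ends_epoch(self):
        """A 'neither' stretch at least as long as the threshold is itself a
        reported state change and terminates the dominance epoch."""
        tr = trace_from_labels([1] * 10 + [0] * 8 + [-1] * 8)
        stats = ms.dominance_durations(tr, 300.0)
        assert [e.duration for e in stats.epochs] == [500.0, 400.0]

    def test_all_one_percept_is_censored(self):
        tr = trace_from_labels([1] * 20)
        stats = ms.dominance_durations(tr, 300.0)
        assert len(stats.epochs) == 1
        assert stats.epochs[0].censored
        assert not stats.defined
        assert np.isnan(stats.cv_d)

    def test_zero_threshold_is_identity(self):
        """Threshold 0 on an alternating toy trace reports every labeled
        epoch unchanged."""
        tr = trace_from_labels([1] * 4 + [-1] * 3 + [1] * 5 + [-1] * 2)
        stats = ms.dominance_durations(tr, 0.0)
        assert [e.duration for e in stats.epochs] == [200.0, 150.0, 250.0, 100.0]
        assert stats.durations.tolist() == [150.0, 250.0]  # censored excluded

    def test_statistics_fields(self):
        rng = np.random.default_rng(0)
        labels = []
        for i in range(200):
            labels += [1 if i % 2 == 0 else -1] * int(rng.integers(7, 40))
        tr = trace_from_labels(labels)
        stats = ms.dominance_durations(tr, 300.0)
        assert stats.defined
        d = stats.durations
        assert stats.mean == pytest.approx(d.mean())
        assert stats.cv_d == pytest.approx(d.std(ddof=1) / d.mean())
        assert stats.predominance_a + stats.predominance_b == pytest.approx(1.0)
        assert stats.alternation_rate_hz > 0
        assert np.isfinite(stats.gamma_shape)


class TestDurationMoments:
    def test_constant_durations(self):
        mu, sd, cv, skew, ratio = ms.duration_moments([5.0] * 10)
        assert cv == 0.0 and np.isnan(skew)

    def test_gamma_shape4_moments(self):
        """Gamma(shape=4): CV = 1/2, skewness = 1, ratio = 2."""
        rng = np.random.default_rng(1)
        x = rng.gamma(4.0, 2.0, size=100_000)
        mu, sd, cv, skew, ratio = ms.duration_moments(x)
        assert cv == pytest.approx(0.5, abs=0.01)
        assert skew == pytest.approx(1.0, abs=0.05)
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_exponential_cv(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(3.0, size=100_000)
        _, _, cv, _, _ = ms.duration_moments(x)
        assert cv == pytest.approx(1.0, abs=0.02)

    def test_gamma_mle_recovery(self):
        """Gamma MLE recovers shape and scale within 5% on 1e4 draws."""
        rng = np.random.default_rng(3)
        x = rng.gamma(4.0, 500.0, size=10_000)
        shape, _, scale = sps.gamma.fit(x, floc=0)
        assert shape == pytest.approx(4.0, rel=0.05)
        assert scale == pytest.approx(500.0, rel=0.05)


class TestSigmaMuRegression:
    def test_noiseless_line_through_origin(self):
        mus = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        slope, p = ms.sigma_mu_regression(mus, 0.65 * mus)
        assert slope == pytest.approx(0.65, rel=1e-12)
        assert p < 1e-6

    def test_with_intercept_option(self):
        mus = np.array([1.0, 2.0, 3.0, 4.0])
        slope, _ = ms.sigma_mu_regression(mus, 0.5 * mus + 1.0,
                                          through_origin=False)
        assert slope == pytest.approx(0.5, rel=1e-9)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            ms.sigma_mu_regression([1.0, 2.0], [1.0, 2.0])


class TestStateMask:
    def test_alternating_masks_partition(self):
        tr = trace_from_labels([1] * 10 + [-1] * 10 + [1] * 10)
        mask = ms.state_mask(tr, 300.0)
        assert np.all(mask[:10] == 1)
        assert np.all(mask[10:20] == -1)
        assert not np.any((mask == 1) & (mask == -1))

    def test_all_one_percept(self):
        tr = trace_from_labels([1] * 12)
        mask = ms.state_mask(tr, 300.0)
        assert np.all(mask == 1)

    def test_subthreshold_events_excluded(self):
        """Windows disagreeing with the reported percept belong to neither
        state mask."""
        labels = [1] * 10 + [0, -1, 0] + [1] * 10 + [-1] * 10
        tr = trace_from_labels(labels)
        mask = ms.state_mask(tr, 300.0)
        assert np.all(mask[10:13] == 0)
        assert np.all(mask[13:23] == 1)

    def test_known_epoch_recovery(self):
        """On a synthetic two-pool raster with prescribed 1 s epochs the mask
        matches the construction."""
        raster, truth = syn.alternating_two_pool_raster(
            n_per_pool=20, dominant_rate_hz=40.0, suppressed_rate_hz=1.0,
            duration=20_000.0, seed=4, deterministic_epochs=1000.0)
        pool_a = np.arange(20)
        pool_b = np.arange(20, 40)
        tr = ms.percept_trace(raster, pool_a, pool_b, window=50.0)
        stats = ms.dominance_durations(tr, 300.0)
        assert np.allclose(stats.durations, 1000.0)
        mask = ms.state_mask(tr, 300.0)
        # window 25 sits in the second epoch (pool B dominant)
        assert mask[25] == -1


class TestSpikingStats:
    def full_interval(self, duration):
        return np.array([[0.0, duration]])

    def test_periodic_train_cv_zero(self):
        raster = raster_from_trains([np.arange(10.0, 5000.0, 20.0)], 5000.0)
        cv = ms.cv_isi(raster, [0], self.full_interval(5000.0))
        assert cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_one(self):
        raster = syn.poisson_raster(1, rate_hz=100.0, duration=110_000.0,
                                    seed=5)
        assert raster.n_events > 10_000
        cv = ms.cv_isi(raster, [0], self.full_interval(110_000.0))
        assert cv[0] == pytest.approx(1.0, abs=0.02)

    def test_isis_never_straddle_state_changes(self):
        """A neuron firing at 0.9 s and 1.1 s contributes no ISI when the
        state changes at 1.0 s."""
        raster = raster_from_trains(
            [[100.0, 900.0, 1100.0, 1900.0]], 2000.0)
        intervals = np.array([[0.0, 1000.0], [1000.0, 2000.0]])
        cv = ms.cv_isi(raster, [0], intervals, min_isis=1)
        isis_pooled = [800.0, 800.0]  # 100->900 and 1100->1900 only
        assert cv[0] == pytest.approx(
            np.std(isis_pooled, ddof=1) / np.mean(isis_pooled))

    def test_fano_poisson_and_periodic(self):
        poiss = syn.poisson_raster(30, rate_hz=50.0, duration=60_000.0, seed=6)
        fano = ms.fano_factor(poiss, np.arange(30),
                              self.full_interval(60_000.0))
        assert fano.mean() == pytest.approx(1.0, abs=0.05)
        per = syn.periodic_raster(10, rate_hz=50.0, duration=30_000.0, seed=7)
        fano_p = ms.fano_factor(per, np.arange(10),
                                self.full_interval(30_000.0))
        assert (fano_p < 1).all()

    def test_fano_excludes_silent_neurons(self):
        raster = raster_from_trains([np.arange(10.0, 9000.0, 100.0), []],
                                    10_000.0)
        fano = ms.fano_factor(raster, [0, 1], self.full_interval(10_000.0))
        assert 1 not in fano.index

    def test_rsc_identical_and_independent(self):
        train = np.sort(np.random.default_rng(8).uniform(0, 60_000.0, 3000))
        raster = raster_from_trains([train, train], 60_000.0)
        r = ms.spike_count_correlations(raster, [0, 1],
                                        self.full_interval(60_000.0),
                                        n_pairs=1, seed=0)
        assert r[0] == pytest.approx(1.0)
        poiss = syn.poisson_raster(40, rate_hz=30.0, duration=100_000.0, seed=9)
        rs_ = ms.spike_count_correlations(poiss, np.arange(40),
                                          self.full_interval(100_000.0),
                                          n_pairs=400, seed=1)
        # null correlation: mean within the 95% CI of 0 (1000 windows/pair)
        assert abs(rs_.mean()) < 0.07

    def test_rsc_excludes_zero_variance(self):
        train = np.sort(np.random.default_rng(10).uniform(0, 10_000.0, 500))
        raster = raster_from_trains([train, []], 10_000.0)
        r = ms.spike_count_correlations(raster, [0, 1],
                                        self.full_interval(10_000.0),
                                        n_pairs=1, seed=0)
        assert r.size == 0


class TestLeveltChecks:
    def test_monotone_durations_satisfy_fourth_proposition(self):
        scan = pd.DataFrame({"drive": [1, 2, 3, 4, 5],
                             "mean_duration": [5.0, 2.5, 1.7, 1.2, 1.0]})
        rep = ms.levelt_checks(symmetric_scan=scan)
        assert rep["levelt4"]["passed"]
        assert rep["levelt4"]["spearman_rho"] == pytest.approx(-1.0)

    def test_predominance_crossing(self):
        drive = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        pred_a = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
        scan = pd.DataFrame({
            "drive_a": drive, "predominance_a": pred_a,
            "predominance_b": 1 - pred_a,
            "alternation_rate": [0.5, 0.8, 1.0, 0.8, 0.5],
        })
        rep = ms.levelt_checks(pool_a_scan=scan, equidominance_base=5.0)
        assert rep["levelt2_classic"]["passed"]
        assert rep["levelt2_modified"]["passed"]
        assert rep["max_alternation_at_equidominance"]["passed"]

    def test_short_scan_refused(self):
        scan = pd.DataFrame({"drive": [1, 2, 3],
                             "mean_duration": [3.0, 2.0, 1.0]})
        with pytest.raises(ValueError):
            ms.levelt_checks(symmetric_scan=scan)
        with pytest.raises(ValueError):
            ms.levelt_checks()
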