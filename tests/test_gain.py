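"""Spike detection, burst metrics, cGI normalization and sigmoid fitting."""

import numpy as np
import pytest

from granulayer import gain, synth
from granulayer.gain import BurstMetrics, GainCurve, SigmoidFit
from granulayer.microcircuit import TraceSet


def _traces(trials, dt=0.05, stim=(20.0,)):
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    t = np.arange(trials.shape[1]) * dt
    return TraceSet(time_ms=t, data=trials, modality="voltage",
                    stim_times=np.asarray(stim))


def _trial_with_spikes(spike_times, n=4000, dt=0.05, v0=-65.0):
    t = np.arange(n) * dt
    v = np.full(n, v0)
    for ts in spike_times:
        v += np.where(np.abs(t - ts) < 0.5, 95.0 * (1 - np.abs(t - ts) / 0.5), 0.0)
    return v


class TestDetectSpikes:
    def test_subthreshold_trace_empty(self):
        t = np.arange(1000) * 0.05
        assert gain.detect_spikes(t, np.full(1000, -60.0)).size == 0

    def test_inserted_spikes_found(self):
        v = _trial_with_spikes([30.0, 60.0, 90.0])
        t = np.arange(v.size) * 0.05
        times = gain.detect_spikes(t, v)
        assert times.size == 3
        np.testing.assert_allclose(times, [30.0, 60.0, 90.0], atol=0.6)

    def test_doublet_merged_by_refractory(self):
        v = _trial_with_spikes([30.0, 30.5])
        t = np.arange(v.size) * 0.05
        assert gain.detect_spikes(t, v).size == 1


class TestBurstMetrics:
    def test_all_silent(self):
        ts = _traces([np.full(4000, -64.0), np.full(4000, -64.0)])
        m = gain.burst_metrics(ts)
        assert m.sc == 0.0 and m.sp == 0.0 and m.fssd is None
        assert m.amd == pytest.approx(0.0, abs=1e-9)

    def test_identical_latencies_zero_fssd(self):
        trials = [_trial_with_spikes([25.0]) for _ in range(10)]
        m = gain.burst_metrics(_traces(trials))
        assert m.sp == 1.0
        assert m.fssd == pytest.approx(0.0, abs=1e-9)

    def test_fssd_from_known_latencies(self):
        trials = [_trial_with_spikes([20.0 + lat]) for lat in (2.0, 3.0, 4.0)]
        trials.append(np.full(4000, -65.0))  # a silent trial
        m = gain.burst_metrics(_traces(trials))
        assert m.fssd == pytest.approx(1.0, abs=0.05)  # ddof=1 SD of {2,3,4}
        assert m.sp == pytest.approx(0.75)

    def test_amd_is_baseline_subtracted(self):
        v = np.full(4000, -65.0)
        v[500:] = -55.0
        m = gain.burst_metrics(_traces([v, v]))
        assert m.amd == pytest.approx(10.0, abs=1e-9)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            gain.burst_metrics(_traces([np.full(100, -65.0)]))


def _metric(f, sc=0.0, sp=0.0, fssd=None, amd=0.0):
    return BurstMetrics(frequency=f, sc=sc, sp=sp, fssd=fssd, amd=amd, n_trials=10)


class TestNormalizeAndCompound:
    def test_single_varying_metric_has_unit_range(self):
        ms = [_metric(10, amd=1.0), _metric(50, amd=3.0), _metric(200, amd=5.0)]
        curve = gain.normalize_and_compound(ms)
        assert curve.gains.max() - curve.gains.min() == pytest.approx(1.0)

    def test_all_optimal_reaches_four(self):
        ms = [
            _metric(10, sc=0.0, sp=0.0, fssd=5.0, amd=1.0),
            _metric(50, sc=1.0, sp=0.5, fssd=2.0, amd=4.0),
            _metric(200, sc=3.0, sp=1.0, fssd=0.2, amd=9.0),
        ]
        curve = gain.normalize_and_compound(ms)
        assert curve.gains[-1] == pytest.approx(4.0)
        assert np.all((curve.gains >= 0.0) & (curve.gains <= 4.0))

    def test_undefined_fssd_counts_as_worst(self):
        ms = [
            _metric(10, sc=0.0, sp=0.0, fssd=None, amd=1.0),
            _metric(50, sc=1.0, sp=0.5, fssd=2.0, amd=4.0),
            _metric(200, sc=3.0, sp=1.0, fssd=0.2, amd=9.0),
        ]
        curve = gain.normalize_and_compound(ms)
        # the first frequency gets precision 0, identical to the defined worst
        assert curve.gains[0] == pytest.approx(0.0)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gain.normalize_and_compound([_metric(10), _metric(50)])


class TestFitGainSigmoid:
    def test_exact_data_recovered(self):
        f = np.geomspace(10, 500, 12)
        g = gain.sigmoid(f, 1.0, 3.0, 50.0, 4.0)
        fit = gain.fit_gain_sigmoid(GainCurve(f, g))
        assert fit.A1 == pytest.approx(1.0, abs=1e-6)
        assert fit.A2 == pytest.approx(3.0, abs=1e-6)
        assert fit.fc == pytest.approx(50.0, abs=1e-4)
        assert fit.power == pytest.approx(4.0, abs=1e-4)

    def test_midpoint_identity(self):
        fit = SigmoidFit(A1=1.2, A2=2.8, fc=60.0, power=3.0)
        assert fit(60.0) == pytest.approx((1.2 + 2.8) / 2)

    def test_scale_equivariance(self):
        f = np.geomspace(10, 500, 10)
        rng = np.random.default_rng(2)
        g = gain.sigmoid(f, 1.0, 3.0, 40.0, 4.0) + rng.normal(0, 0.05, f.size)
        fit1 = gain.fit_gain_sigmoid(GainCurve(f, g))
        fit3 = gain.fit_gain_sigmoid(GainCurve(f, 3.0 * g))
        assert fit3.A1 == pytest.approx(3 * fit1.A1, rel=1e-3, abs=1e-3)
        assert fit3.A2 == pytest.approx(3 * fit1.A2, rel=1e-3)
        assert fit3.fc == pytest.approx(fit1.fc, rel=1e-3)
        assert fit3.power == pytest.approx(fit1.power, rel=1e-3)

    def test_monte_carlo_cutoff_recovery(self):
        """Median relative fc error < 10% over noisy synthetic curves."""
        f = np.geomspace(10, 500, 10)
        errs = []
        rng = np.random.default_rng(9)
        for k in range(200):
            fc_true = rng.uniform(25.0, 120.0)
            reps = synth.gen_gain_curve(1.03, 2.69, fc_true, 4.0, f,
                                        noise_sd=0.1, n_reps=1,
                                        seed=int(rng.integers(2**31)))
            fit = gain.fit_gain_sigmoid(GainCurve(f, reps[0]))
            errs.append(abs(fit.fc - fc_true) / fc_true)
        assert np.median(errs) < 0.10

    def test_high_pass_direction_preserved(self):
        f = np.geomspace(10, 500, 10)
        g = gain.sigmoid(f, 0.5, 3.5, 80.0, 3.0)
        fit = gain.fit_gain_sigmoid(GainCurve(f, g))
        assert fit.A2 > fit.A1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gain.fit_gain_sigmoid(GainCurve([10, 50, 100], [1, 2, 3]))


class TestGainSummary:
    def test_identical_fits_zero_change(self):
        fit = SigmoidFit(A1=1.0, A2=3.0, fc=50.0, power=4.0)
        s = gain.gain_summary(fit, fit)
        assert s["delta_fc_pct"] == 0.0
        assert s["delta_max_gain_pct"] == 0.0
        assert s["delta_relative_gain_pct"] == 0.0

    def test_relative_gain_arithmetic(self):
        fit = SigmoidFit(A1=1.0, A2=3.0, fc=50.0, power=4.0)
        s = gain.gain_summary(fit, fit)
        assert s["relative_gain_pre"] == pytest.approx(2.0)

    def test_cutoff_shift_percent(self):
        pre = SigmoidFit(A1=1.0, A2=3.0, fc=105.0, power=4.0)
        post = SigmoidFit(A1=1.0, A2=3.0, fc=76.0, power=4.0)
        s = gain.gain_summary(pre, post)
        assert s["delta_fc_pct"] == pytest.approx(-27.6, abs=0.05)

    def test_nonpositive_gmin_flagged(self):
        pre = SigmoidFit(A1=-0.5, A2=3.0, fc=50.0, power=4.0)
        s = gain.gain_summary(pre, pre)
        assert s["relative_gain_pre"] is None
        assert s["delta_relative_gain_pct"] is None


class TestCutoffHistogram:
    def test_single_bin(self):
        fits = [SigmoidFit(A1=1, A2=3, fc=fc, power=4) for fc in (25, 30, 45)]
        counts, edges = gain.cutoff_histogram(fits)
        assert counts[1] == 3 and counts.sum() == 3

    def test_edge_value_goes_right(self):
        fits = [SigmoidFit(A1=1, A2=3, fc=50.0, power=4)]
        counts, edges = gain.cutoff_histogram(fits)
        assert counts[2] == 1  # [50, 100) bin

    def test_counts_sum_to_n_fits(self):
        rng = np.random.default_rng(3)
        fits = [SigmoidFit(A1=1, A2=3, fc=float(rng.uniform(5, 400)), power=4)
                for _ in range(25)]
        counts, _ = gain.cutoff_histogram(fits)
        assert counts.sum() == 25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gain.cutoff_histogram([])
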