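"""Bead-trace analysis: filtering, rates, pauses, survival, reconstruction."""

import math

import numpy as np
import pytest

from topoloop import clamp, synth, traces
from topoloop.traces import ActivityRecord, BeadTrace, RateSeries


def make_records(durations_s, censored=None, rate=3.0):
    censored = censored or [False] * len(durations_s)
    return [
        ActivityRecord(
            active_duration=d,
            turns_relaxed=rate * d,
            first_pause_time=None if c else d,
            censored=c,
        )
        for d, c in zip(durations_s, censored)
    ]


class TestSlidingFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.25)
        np.testing.assert_allclose(traces.sliding_filter(x, 5.0), x)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(101)
        x[50] = 7.0
        f = traces.sliding_filter(x, 5 * 0.025)  # 5-sample window
        np.testing.assert_allclose(f[48:53], 7.0 / 5.0)

    def test_single_sample_window_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        np.testing.assert_allclose(traces.sliding_filter(x, 0.025), x)

    def test_linear_ramp_preserved_everywhere(self):
        x = 2.0 * np.arange(400)
        np.testing.assert_allclose(traces.sliding_filter(x, 1.0), x)

    def test_window_below_sample_interval_raises(self):
        with pytest.raises(ValueError):
            traces.sliding_filter(np.zeros(10), 0.01, dt=0.025)


class TestClampRate:
    def _trace(self, magnet, dt=0.025, annotations=None):
        t = np.arange(magnet.size) * dt
        return BeadTrace(
            time=t,
            extension=np.full_like(t, 1000.0),
            magnet_turns=magnet,
            force=0.5,
            annotations=annotations
            if annotations is not None
            else [{"kind": "clamp_on", "time": 0.0}],
        )

    def test_linear_magnet_decrease_reads_constant_rate(self):
        t = np.arange(0, 120, 0.025)
        tr = self._trace(-3.0 * t)
        rs = traces.clamp_rate(tr)
        np.testing.assert_allclose(rs.rate[100:-100], 3.0, atol=1e-9)

    def test_stationary_magnets_give_zero_rate(self):
        tr = self._trace(np.zeros(4000))
        rs = traces.clamp_rate(tr)
        np.testing.assert_allclose(rs.rate, 0.0, atol=1e-12)

    def test_unclamped_trace_is_a_usage_error(self):
        tr = self._trace(np.zeros(4000), annotations=[])
        with pytest.raises(ValueError, match="clamp"):
            traces.clamp_rate(tr)

    def test_stepped_poisson_trace_mean_rate(self):
        # -2-turn steps at Poisson times, mean rate r: filtered mean within 5%
        r_true = 3.0
        dt = 0.025
        n = int(600 / dt)
        means = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            steps = rng.random(n) < (r_true / 2.0) * dt
            magnet = -2.0 * np.cumsum(steps)
            rs = traces.clamp_rate(self._trace(magnet))
            means.append(np.mean(rs.rate))
        assert np.mean(means) == pytest.approx(r_true, rel=0.05)


class TestDetectActivity:
    def test_continuously_active_trace_is_censored(self):
        t = np.arange(0, 1800, 0.025)
        rec = traces.detect_activity(RateSeries(t, np.full_like(t, 3.0)))
        assert rec.censored and rec.first_pause_time is None
        assert rec.active_duration == pytest.approx(1800.0, abs=0.1)
        assert rec.turns_relaxed == pytest.approx(3.0 * 1800.0, rel=0.01)

    def test_pause_at_430_seconds_detected(self):
        t = np.arange(0, 900, 0.025)
        rate = np.where((t > 430) & (t < 480), 0.0, 3.0)
        rec = traces.detect_activity(RateSeries(t, rate))
        assert not rec.censored
        assert rec.first_pause_time == pytest.approx(430.0, abs=0.1)

    def test_short_gap_is_not_a_pause(self):
        t = np.arange(0, 600, 0.025)
        rate = np.where((t > 300) & (t < 320), 0.0, 3.0)
        rec = traces.detect_activity(RateSeries(t, rate))
        assert rec.censored


class TestSurvival:
    def test_curve_is_monotone_and_bounded_with_proportion_se(self):
        rng = np.random.default_rng(1)
        recs = make_records(rng.exponential(500.0, size=50))
        curve, _ = traces.survival_and_fit(recs, "time")
        p = curve.active_fraction
        assert np.all(np.diff(p) <= 1e-12)
        assert np.all((p >= 0) & (p <= 1))
        i = np.argmin(np.abs(p - 0.5))
        assert curve.se[i] == pytest.approx(
            math.sqrt(p[i] * (1 - p[i]) / curve.n), rel=0.2
        )
        assert curve.se[0] == 0.0  # p = 1 has zero proportion SE

    def test_exponential_recovery(self):
        recs = synth.simulate_activity_records(400, 9 * 60.0, 3.0, 3600.0, seed=3)
        _, fit = traces.survival_and_fit(recs, "time")
        assert fit.mean == pytest.approx(9.0, rel=0.1)

    def test_all_censored_flags_lower_bound(self):
        recs = make_records([1800.0] * 10, censored=[True] * 10)
        curve, fit = traces.survival_and_fit(recs, "time")
        assert fit.lower_bound
        np.testing.assert_allclose(curve.active_fraction, 1.0)

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            traces.survival_and_fit(make_records([1.0, 2.0]))

    def test_mle_variant_agrees_with_lsq_on_synthetic_data(self):
        recs = synth.simulate_activity_records(300, 8.9 * 60, 3.0, 1800.0, seed=7)
        _, lsq = traces.survival_and_fit(recs, "time")
        mle = traces.exponential_mle(recs, "time")
        assert mle.censoring_aware
        assert abs(mle.mean - lsq.mean) < 2.0 * (lsq.uncertainty + mle.uncertainty)


class TestRewindReconstruction:
    def test_fully_relaxed_state_recovers_zero(self):
        assert traces.rewind_reconstruction(35.0, 35.0, 0.0, 0.875) == 0.0

    def test_worked_example(self):
        assert traces.rewind_reconstruction(32.0, 35.0, 3.0, 0.875) == pytest.approx(
            2.625
        )

    def test_reconstruction_matches_generator_ground_truth(self, naked_spec, naked_cal):
        # enzyme off: dLk before the rewind equals dLk after minus added turns
        enzyme = synth.EnzymeModel(lifetime_mean_s=1e9, pause_rate_per_s=0.0)
        prot = [
            clamp.ProtocolStep("wait", duration=1.0),
            clamp.ProtocolStep("wind", turns=35.0, rate=40.0),
            clamp.ProtocolStep("wait", duration=2.0),
        ]
        trace, log = synth.simulate_topo_trace(
            naked_spec, enzyme, prot, synth.NoiseModel(extension_sd=0.0), seed=1,
            rate_table=synth.parametric_rate_table(0.5, k_sat=1e-12),
        )
        wind = trace.events("wind")[0]
        dlk_pre = traces.prebuckled_state_after_rewind(
            trace, wind, naked_cal, rate_buckled=0.0
        )
        assert dlk_pre == pytest.approx(0.0, abs=1e-6)

    def test_noisy_reconstruction_within_one_turn(self, naked_spec, naked_cal):
        enzyme = synth.EnzymeModel(lifetime_mean_s=1e9, pause_rate_per_s=0.0)
        prot = [
            clamp.ProtocolStep("wait", duration=1.0),
            clamp.ProtocolStep("wind", turns=35.0, rate=40.0),
            clamp.ProtocolStep("wait", duration=2.0),
        ]
        for seed in range(5):
            trace, log = synth.simulate_topo_trace(
                naked_spec, enzyme, prot, synth.NoiseModel(extension_sd=15.0),
                seed=seed, rate_table=synth.parametric_rate_table(0.5, k_sat=1e-12),
            )
            wind = trace.events("wind")[0]
            dlk_pre = traces.prebuckled_state_after_rewind(
                trace, wind, naked_cal, rate_buckled=0.0
            )
            assert abs(dlk_pre) < 1.0


class TestBuckledRate:
    def test_noiseless_linear_segment(self, naked_cal):
        t = np.arange(0, 30, 0.025)
        ext = naked_cal.ext(120.0 - 3.4 * t)
        assert traces.buckled_rate_linear(t, ext, naked_cal, "right") == pytest.approx(
            3.4, rel=1e-6
        )

    def test_flat_segment_gives_zero(self, naked_cal):
        t = np.arange(0, 30, 0.025)
        ext = np.full_like(t, float(naked_cal.ext(100.0)))
        assert traces.buckled_rate_linear(t, ext, naked_cal, "right") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_noisy_rate_within_ten_percent(self, naked_cal):
        t = np.arange(0, 30, 0.025)
        clean = naked_cal.ext(120.0 - 3.0 * t)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rate = traces.buckled_rate_linear(
                t, clean + 10.0 * rng.standard_normal(t.size), naked_cal, "right"
            )
            assert rate == pytest.approx(3.0, rel=0.1)


class TestDirectTimecourse:
    def _relaxation_traces(self, spec, n, noise, seed0):
        enzyme = synth.EnzymeModel(lifetime_mean_s=1e9, pause_rate_per_s=0.0)
        prot = [
            clamp.ProtocolStep("wind", turns=60.0),
            clamp.ProtocolStep("wait", duration=40.0),
        ]
        out = []
        for s in range(n):
            tr, log = synth.simulate_topo_trace(
                spec, enzyme, prot, synth.NoiseModel(extension_sd=noise),
                seed=seed0 + s,
            )
            out.append((tr, log))
        return out

    def test_identical_traces_average_to_single_trace(self, naked_spec, naked_cal):
        pairs = self._relaxation_traces(naked_spec, 1, 0.0, 5)
        tr, _ = pairs[0]
        t1, s1, _ = traces.direct_prebuckled_timecourse([tr], naked_cal, naked_spec.lk0)
        t3, s3, _ = traces.direct_prebuckled_timecourse(
            [tr, tr, tr], naked_cal, naked_spec.lk0
        )
        np.testing.assert_allclose(s3, np.interp(t3, t1, s1), atol=1e-12)

    def test_recovers_generator_supercoiling_state(self, naked_spec, naked_cal):
        pairs = self._relaxation_traces(naked_spec, 1, 0.0, 6)
        tr, log = pairs[0]
        t, sig, _ = traces.direct_prebuckled_timecourse([tr], naked_cal, naked_spec.lk0)
        # ground truth dLk at the shifted times
        e = traces.sliding_filter(tr.extension, 5.0, tr.dt)
        i0 = traces.buckling_crossing_index(e, naked_cal.buckling_extensions[1])
        truth = np.interp(t + tr.time[i0], tr.time, log["dlk"]) / naked_spec.lk0
        # agreement within the smoothing scale: 2-turn steps plus the 5 s
        # filter acting where the state still changes at ~3 turns/s
        assert np.max(np.abs(sig - truth)) < 5.0 / naked_spec.lk0
        assert np.mean(np.abs(sig - truth)) < 1.5 / naked_spec.lk0

    def test_direct_and_indirect_methods_agree(self, naked_spec, naked_cal):
        """The rewind-reconstruction and the direct extension conversion give
        the same pre-buckled supercoiling state on one synthetic ensemble."""
        enzyme = synth.EnzymeModel(lifetime_mean_s=1e9, pause_rate_per_s=0.0)
        wait = 8.0
        prot = [
            clamp.ProtocolStep("wind", turns=60.0),
            clamp.ProtocolStep("wait", duration=40.0 + wait),
            clamp.ProtocolStep("wind", turns=35.0, rate=40.0),
            clamp.ProtocolStep("wait", duration=2.0),
        ]
        direct_vals, indirect_vals = [], []
        for s in range(8):
            tr, log = synth.simulate_topo_trace(
                naked_spec, enzyme, prot, synth.NoiseModel(extension_sd=10.0),
                seed=40 + s,
            )
            rewind = tr.events("wind")[1]
            # the direct conversion applies to the relaxation phase only
            k_end = int(np.searchsorted(tr.time, rewind["time"]))
            crop = traces.BeadTrace(
                tr.time[:k_end], tr.extension[:k_end], tr.magnet_turns[:k_end],
                tr.force,
            )
            t, sig, _ = traces.direct_prebuckled_timecourse(
                [crop], naked_cal, naked_spec.lk0
            )
            # the direct curve's last point is the state just before the
            # rewind; the indirect method reconstructs the same state
            dlk_pre = traces.prebuckled_state_after_rewind(
                tr, rewind, naked_cal, rate_buckled=3.4 * 0.96
            )
            direct_vals.append(float(sig[-1]) * naked_spec.lk0)
            indirect_vals.append(dlk_pre)
        assert direct_vals
        # joint uncertainty: 2-turn passage steps, Poisson timing of the
        # buckled-state correction, and extension noise
        for d, i in zip(direct_vals, indirect_vals):
            assert abs(d - i) < 8.0
        assert abs(np.mean(direct_vals) - np.mean(indirect_vals)) < 3.0


class TestPoissonWindow:
    def test_zero_probability_stays_zero(self):
        assert traces.poisson_window_probability(0.0, 1800.0, 30.0) == 0.0

    def test_contamination_window_arithmetic(self):
        p = traces.poisson_window_probability(0.17, 1800.0, 30.0)
        assert p == pytest.approx(0.0031, abs=1e-4)

    def test_monte_carlo_poisson_oracle(self):
        p_long = 0.17
        lam = -math.log(1.0 - p_long) / 1800.0
        rng = np.random.default_rng(9)
        n = 1_000_000
        frac = np.mean(rng.poisson(lam * 30.0, size=n) >= 1)
        p = traces.poisson_window_probability(p_long, 1800.0, 30.0)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * sd

    def test_certain_event_raises(self):
        with pytest.raises(ValueError):
            traces.poisson_window_probability(1.0, 1800.0, 30.0)


class TestTraceIO:
    def test_roundtrip(self, tmp_path, naked_spec):
        enzyme = synth.EnzymeModel()
        tr, _ = synth.simulate_topo_trace(
            naked_spec, enzyme,
            [clamp.ProtocolStep("wind", turns=10.0),
             clamp.ProtocolStep("wait", duration=2.0)],
            synth.NoiseModel(), seed=0,
        )
        path = tmp_path / "trace.tsv"
        traces.write_trace(tr, path)
        back = traces.read_trace(path)
        np.testing.assert_allclose(back.time, tr.time, atol=1e-6)
        np.testing.assert_allclose(back.extension, tr.extension, atol=1e-5)
        assert back.force == tr.force
        assert back.events("wind")
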