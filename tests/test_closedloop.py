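"""Online burst detection, pulse scheduling, block quantification and the
half-block-delay extrapolation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from relaymea import (
    BlockCurve,
    ClosedLoopConfig,
    SimulationConfig,
    analyze_raster,
    block_vs_delay_curve,
    exclude_cultures,
    extrapolate_half_block_delay,
    generate_closed_loop_session,
    generate_culture,
    generate_stimulation_sweep,
    online_burst_detector,
    quantify_block,
    schedule_pulses,
)
from relaymea.bursts import Burst, PropagationRecord


def _records(n_prop, n_total):
    out = []
    for i in range(n_total):
        lead = Burst("left", float(i * 10), float(i * 10 + 0.2), 10, 5, 50)
        if i < n_prop:
            fol = Burst("right", float(i * 10 + 0.15), float(i * 10 + 0.4), 10, 5, 50)
            out.append(PropagationRecord(lead, fol, 150.0))
        else:
            out.append(PropagationRecord(lead))
    return out


def offline_trigger_oracle(counts, cfg, window_s):
    """Independent offline re-implementation of the trigger rule."""
    hist_len = max(2, int(round(cfg.history_s / window_s)))
    quiet = []
    triggers = []
    last = -np.inf
    for i, c in enumerate(counts):
        t = (i + 1) * window_s
        if (
            len(quiet) >= hist_len
            and c >= cfg.min_count
            and t - last >= cfg.lockout_s
        ):
            sd = np.std(quiet[-hist_len:])
            if sd > 0 and c > cfg.threshold_sd * sd:
                triggers.append(t)
                last = t
        if c < cfg.min_count:
            quiet.append(c)
    return triggers


class TestOnlineDetector:
    def test_flat_stream_no_triggers(self):
        cfg = ClosedLoopConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert online_burst_detector(np.zeros(2000, dtype=int), cfg).size == 0

    def test_single_burst_triggered_within_one_window(self, rng):
        cfg = ClosedLoopConfig()
        counts = rng.poisson(0.05, 3000)
        onset_bin = 1500
        counts[onset_bin : onset_bin + 20] += 8
        trig = online_burst_detector(counts, cfg)
        assert trig.size == 1
        onset_t = onset_bin * cfg.detection_window_ms * 1e-3
        assert onset_t < trig[0] <= onset_t + cfg.detection_window_ms * 1e-3 + 1e-9

    def test_causality_trigger_never_precedes_activity(self, rng):
        cfg = ClosedLoopConfig(lockout_s=0.5)
        counts = rng.poisson(0.05, 6000)
        burst_bins = [1000, 2500, 4000, 5500]
        for b in burst_bins:
            counts[b : b + 15] += 10
        w = cfg.detection_window_ms * 1e-3
        trig = online_burst_detector(counts, cfg)
        assert trig.size == len(burst_bins)
        for t, b in zip(trig, burst_bins):
            assert t > b * w  # trigger strictly after burst-onset bin start

    @pytest.mark.parametrize("seed", [5, 6])
    def test_agrees_with_offline_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ClosedLoopConfig(lockout_s=1.0)
        counts = rng.poisson(0.05, 5000)
        for b in rng.choice(4500, 12, replace=False):
            counts[b : b + 10] += rng.poisson(6.0, 10)
        w = cfg.detection_window_ms * 1e-3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = online_burst_detector(counts, cfg)
        expected = offline_trigger_oracle(counts, cfg, w)
        assert np.allclose(got, expected)

    def test_zero_variance_history_warns_and_suppresses(self):
        cfg = ClosedLoopConfig()
        counts = np.zeros(400, dtype=int)
        counts[300] = 10
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            trig = online_burst_detector(counts, cfg)
        assert trig.size == 0


class TestSchedulePulses:
    def test_lockout_drops_second_trigger(self):
        cfg = ClosedLoopConfig(pulse_duration_s=1.0, lockout_s=5.0)
        pulses = schedule_pulses([0.0, 2.0], cfg)
        assert len(pulses) == 1
        assert pulses[0].onset == pytest.approx(0.0)

    def test_empty_triggers(self):
        assert schedule_pulses([], ClosedLoopConfig()) == []

    def test_spaced_triggers_all_fire_at_configured_delay(self):
        cfg = ClosedLoopConfig(pulse_delay_ms=100.0, pulse_duration_s=1.0, lockout_s=5.0)
        pulses = schedule_pulses([0.0, 8.0, 16.0], cfg)
        assert len(pulses) == 3
        assert [p.onset for p in pulses] == pytest.approx([0.1, 8.1, 16.1])
        assert all(p.offset - p.onset == pytest.approx(1.0) for p in pulses)


class TestQuantifyBlock:
    @pytest.mark.parametrize(
        "light,ctrl,expected",
        [((0, 10), (10, 10), 1.0), ((3, 10), (10, 10), 0.7), ((8, 10), (8, 10), 0.0)],
    )
    def test_known_fractions(self, light, ctrl, expected):
        res = quantify_block(_records(*light), _records(*ctrl))
        assert res.fraction_blocked == pytest.approx(expected)

    def test_zero_control_rate_is_error(self):
        with pytest.raises(ValueError, match="control propagation"):
            quantify_block(_records(0, 10), _records(0, 10))

    def test_empty_condition_is_error(self):
        with pytest.raises(ValueError, match="at least one leading"):
            quantify_block([], _records(5, 10))


class TestBlockCurve:
    def test_known_fractions_per_delay(self):
        trials = pd.DataFrame(
            {
                "pulse_delay_ms": [0.0] * 10 + [300.0] * 10,
                "propagated": [False] * 10 + [True] * 10,
            }
        )
        curve = block_vs_delay_curve(trials, control_propagation=1.0)
        assert curve.pulse_delays_ms.tolist() == [0.0, 300.0]
        assert curve.fraction_blocked.tolist() == [1.0, 0.0]
        assert curve.n_trials.tolist() == [10, 10]

    def test_single_delay_rejected(self):
        trials = pd.DataFrame({"pulse_delay_ms": [0.0] * 5, "propagated": [False] * 5})
        with pytest.raises(ValueError, match="two distinct"):
            block_vs_delay_curve(trials, control_propagation=1.0)

    def test_unsorted_input_is_sorted(self):
        trials = pd.DataFrame(
            {"pulse_delay_ms": [200.0, 0.0, 200.0, 0.0], "propagated": [True, False] * 2}
        )
        curve = block_vs_delay_curve(trials, control_propagation=1.0)
        assert np.all(np.diff(curve.pulse_delays_ms) > 0)


class TestHalfBlockDelay:
    def test_linear_interpolation(self):
        curve = BlockCurve([0.0, 200.0], [1.0, 0.0], [10, 10])
        assert extrapolate_half_block_delay(curve) == pytest.approx(100.0)

    def test_exact_hit(self):
        curve = BlockCurve([0.0, 100.0], [1.0, 0.5], [10, 10])
        assert extrapolate_half_block_delay(curve) == pytest.approx(100.0)

    def test_noisy_curve_is_isotonized_first(self):
        curve = BlockCurve(
            [0.0, 50.0, 100.0, 150.0, 200.0],
            [0.9, 1.0, 0.55, 0.1, 0.2],
            [20] * 5,
        )
        d = extrapolate_half_block_delay(curve)
        assert 100.0 < d < 150.0

    @pytest.mark.parametrize(
        "fractions,side", [([0.4, 0.3, 0.1], "below"), ([0.95, 0.9, 0.8], "above")]
    )
    def test_non_crossing_curve_names_the_side(self, fractions, side):
        curve = BlockCurve([0.0, 100.0, 200.0], fractions, [10] * 3)
        with pytest.raises(ValueError, match=side):
            extrapolate_half_block_delay(curve)


class TestExcludeCultures:
    def test_threshold_rule(self):
        kept, discarded = exclude_cultures({"a": 70.0, "b": 49.0, "c": 90.0})
        assert kept == ["a", "c"]
        assert discarded == {"b": "low_synchronization"}

    def test_exactly_fifty_percent_is_kept(self):
        kept, discarded = exclude_cultures({"a": 50.0})
        assert kept == ["a"] and discarded == {}

    def test_unreliable_detection_flag(self):
        kept, discarded = exclude_cultures({"a": 90.0}, unreliable_detection=["a"])
        assert kept == [] and discarded == {"a": "unreliable_online_detection"}

    def test_empty_input(self):
        assert exclude_cultures({}) == ([], {})


class TestClosedLoopSimulation:
    def test_pulse_causality(self):
        cfg = SimulationConfig(duration_s=600.0, seed=31)
        loop = ClosedLoopConfig(pulse_delay_ms=50.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pulses, truth = generate_closed_loop_session(cfg, loop)
        onsets = truth.bursts["t_on"].to_numpy()
        for p in pulses:
            trig = p.onset - loop.pulse_delay_ms * 1e-3
            prior = onsets[onsets <= trig]
            assert prior.size > 0  # every pulse traces back to a burst
            assert trig - prior.max() < 1.0  # trigger shortly after its burst

    def test_pulses_after_follower_onset_never_block(self):
        """Light delivered past the induction time must not reduce
        propagation (it only silences the relay after its job is done)."""
        cfg = SimulationConfig(seed=32)
        loop = ClosedLoopConfig(pulse_delay_ms=500.0)  # > mu_d + 3 sigma
        trials = generate_stimulation_sweep(cfg, loop, [500.0, 600.0], n_per_delay=150)
        light = trials[trials.condition == "light"]
        ctrl = trials[trials.condition == "control"]
        assert not light.blocked.any()
        # propagation statistically unchanged: same Bernoulli(p)
        assert abs(light.propagated.mean() - ctrl.propagated.mean()) < 0.15

    def test_opsin_negative_graft_is_unaffected_by_light(self):
        cfg = SimulationConfig(duration_s=900.0, seed=33)
        loop = ClosedLoopConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raster_l, pulses, truth_l = generate_closed_loop_session(
                cfg, loop, opsin=False
            )
        raster_c, truth_c = generate_culture(cfg)
        assert len(pulses) > 0  # light was delivered...
        assert (
            truth_l.bursts["propagated"] == truth_c.bursts["propagated"]
        ).all()  # ...but changed nothing
        assert np.array_equal(raster_l.times, raster_c.times)

    @pytest.mark.parametrize("mu_d", [100.0, 150.0, 200.0])
    def test_half_block_delay_tracks_propagation_delay(self, mu_d):
        cfg = SimulationConfig(
            seed=34,
            delay_mean_ms=mu_d,
            delay_sd_ms=55.0,
            relay_delay_mean_ms=111.0 * mu_d / 170.0,
            relay_delay_sd_ms=20.0 * mu_d / 170.0,
            propagation_p=1.0,
        )
        loop = ClosedLoopConfig()
        delays = np.arange(0.0, 320.0, 20.0)
        n = 200
        trials = generate_stimulation_sweep(cfg, loop, delays, n_per_delay=n)
        light = trials[trials.condition == "light"]
        ctrl_rate = trials[trials.condition == "control"].propagated.mean()
        curve = block_vs_delay_curve(light, control_propagation=ctrl_rate)
        est = extrapolate_half_block_delay(curve)
        # 2x the binomial standard error of the curve crossing at the median
        slope = 0.3989 / cfg.delay_sd_ms
        tol = 2 * np.sqrt(0.25 / n) / slope
        assert abs(est - mu_d) <= tol
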