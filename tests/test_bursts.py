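"""Network-activity binning, burst detection, cross-slice pairing and the
synchronization / delay / group statistics."""

import numpy as np
import pytest
from scipy import stats

from relaymea import (
    SimulationConfig,
    analyze_raster,
    compare_groups,
    compute_network_activity,
    compute_propagation_delays,
    compute_synchronization,
    detect_bursts,
    generate_culture,
    pair_bursts,
)
from relaymea.bursts import Burst, NetworkActivityTrace, PropagationRecord

from conftest import make_raster


def _burst(label, onset, offset=None, first_bin=5):
    return Burst(
        slice_label=label,
        onset=onset,
        offset=offset if offset is not None else onset + 0.2,
        peak_rate=10,
        n_active_electrodes=5,
        total_events=50,
        first_bin_count=first_bin,
    )


class TestNetworkActivity:
    def test_empty_raster_gives_zero_traces(self, layout):
        raster = make_raster(layout, [], duration=1.0)
        traces = compute_network_activity(raster)
        assert all(tr.counts.sum() == 0 for tr in traces.values())

    def test_hand_binning(self, layout):
        left_ids = layout.ids_for_slice("left")
        e = int(left_ids[0])
        raster = make_raster(layout, [(e, 0.005), (e, 0.012), (e, 0.019)], duration=0.02)
        traces = compute_network_activity(raster, bin_width_ms=10.0)
        assert traces["left"].counts.tolist() == [1, 2]
        assert traces["right"].counts.sum() == 0

    def test_count_conservation(self, layout, rng):
        ids = rng.choice(layout.electrode_ids, 500)
        times = rng.uniform(0, 30.0, 500)
        raster = make_raster(layout, list(zip(ids, times)), duration=30.0)
        traces = compute_network_activity(raster)
        sel = {
            label: set(layout.ids_for_slice(label)) for label in ("left", "right")
        }
        for label in ("left", "right"):
            n_sel = sum(int(i) in sel[label] for i in ids)
            assert traces[label].counts.sum() == n_sel

    def test_unknown_electrode_rejected(self, small_layout, layout):
        raster = make_raster(layout, [(int(layout.electrode_ids[-1]), 1.0)], duration=5.0)
        with pytest.raises(ValueError, match="absent from layout"):
            compute_network_activity(raster, layout=small_layout)


class TestDetectBursts:
    def test_zero_trace_no_bursts(self, layout):
        raster = make_raster(layout, [], duration=10.0)
        trace = NetworkActivityTrace("left", 10.0, np.zeros(1000, dtype=int))
        assert detect_bursts(trace, raster) == []

    def test_generator_bursts_recovered_with_accurate_onsets(self):
        cfg = SimulationConfig(duration_s=300.0, seed=11, propagation_p=0.0)
        raster, truth = generate_culture(cfg)
        res = analyze_raster(raster)
        detected = sorted(
            res["bursts"]["left"] + res["bursts"]["right"], key=lambda b: b.onset
        )
        true_onsets = truth.bursts["t_on"].to_numpy()
        assert len(detected) == len(true_onsets)
        for b, t in zip(detected, true_onsets):
            assert abs(b.onset - t) <= 0.010  # within one bin

    def test_short_gap_merged_into_one_burst(self, layout):
        left = int(layout.ids_for_slice("left")[0])
        events = []
        for k in range(5):  # envelope A: 0-50 ms
            for e in layout.ids_for_slice("left")[:6]:
                events.append((int(e), 0.005 + 0.01 * k))
        for k in range(5):  # envelope B: 110-160 ms (gap 60 ms < merge_gap)
            for e in layout.ids_for_slice("left")[:6]:
                events.append((int(e), 0.115 + 0.01 * k))
        raster = make_raster(layout, events, duration=2.0)
        traces = compute_network_activity(raster)
        bursts = detect_bursts(traces["left"], raster, merge_gap_ms=100.0)
        assert len(bursts) == 1
        bursts2 = detect_bursts(traces["left"], raster, merge_gap_ms=20.0, min_silent_ms=50.0)
        assert len(bursts2) == 2

    def test_min_electrode_filter(self, layout):
        # strong activity on only 2 electrodes is not a population burst
        ids = layout.ids_for_slice("left")[:2]
        events = [(int(e), 0.005 + 0.001 * k) for e in ids for k in range(30)]
        raster = make_raster(layout, events, duration=2.0)
        traces = compute_network_activity(raster)
        assert detect_bursts(traces["left"], raster, min_electrodes=4) == []
        assert len(detect_bursts(traces["left"], raster, min_electrodes=2)) == 1

    def test_time_range_mismatch_rejected(self, layout):
        raster = make_raster(layout, [], duration=10.0)
        trace = NetworkActivityTrace("left", 10.0, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="time range"):
            detect_bursts(trace, raster)


class TestPairBursts:
    def test_hand_matching(self):
        left = [_burst("left", 1.0), _burst("left", 5.0)]
        right = [_burst("right", 1.1), _burst("right", 9.0)]
        records = pair_bursts(left, right, max_delay_ms=500.0)
        assert len(records) == 3
        by_onset = {r.leading.onset: r for r in records}
        assert by_onset[1.0].propagated
        assert by_onset[1.0].delay_ms == pytest.approx(100.0)
        assert not by_onset[5.0].propagated
        assert not by_onset[9.0].propagated
        assert by_onset[9.0].leading.slice_label == "right"

    def test_single_slice_all_unpropagated(self):
        left = [_burst("left", t) for t in (1.0, 5.0, 9.0)]
        records = pair_bursts(left, [], max_delay_ms=500.0)
        assert len(records) == 3
        assert not any(r.propagated for r in records)

    def test_boundary_delay_counts_as_propagated(self):
        left = [_burst("left", 1.0)]
        right = [_burst("right", 1.5)]
        records = pair_bursts(left, right, max_delay_ms=500.0)
        assert records[0].propagated
        assert records[0].delay_ms == pytest.approx(500.0)

    def test_each_burst_in_at_most_one_record(self):
        left = [_burst("left", 1.0), _burst("left", 1.2)]
        right = [_burst("right", 1.3)]
        records = pair_bursts(left, right, max_delay_ms=500.0)
        followers = [r.follower for r in records if r.propagated]
        assert len(followers) == 1  # the right burst claimed once
        assert sum(1 for r in records) == 2

    def test_tie_broken_by_first_bin_count(self):
        left = [_burst("left", 1.0, first_bin=10)]
        right = [_burst("right", 1.0, first_bin=3)]
        records = pair_bursts(left, right, max_delay_ms=500.0)
        # simultaneous onsets: neither can be the other's follower
        assert len(records) == 2
        assert records[0].leading.slice_label == "left"


class TestSynchronization:
    def test_percentage_arithmetic(self):
        records = [
            PropagationRecord(_burst("left", i), _burst("right", i + 0.1), 100.0)
            for i in range(8)
        ] + [PropagationRecord(_burst("left", 20.0 + i)) for i in range(2)]
        s = compute_synchronization(records)
        assert s.percent_propagated == pytest.approx(80.0)
        assert s.n_leading_bursts == 10 and s.n_propagated == 8

    @pytest.mark.parametrize("propagate,expected", [(True, 100.0), (False, 0.0)])
    def test_extremes(self, propagate, expected):
        records = [
            PropagationRecord(
                _burst("left", i),
                _burst("right", i + 0.1) if propagate else None,
                100.0 if propagate else None,
            )
            for i in range(5)
        ]
        assert compute_synchronization(records).percent_propagated == expected

    def test_no_leading_bursts_is_error(self):
        with pytest.raises(ValueError, match="no leading bursts"):
            compute_synchronization([])


class TestDelays:
    def test_summary_of_known_delays(self):
        records = [
            PropagationRecord(_burst("left", i), _burst("right", i + d / 1e3), d)
            for i, d in enumerate((100.0, 120.0, 140.0))
        ]
        s = compute_propagation_delays(records)
        assert s.mean_ms == pytest.approx(120.0)
        assert s.max_ms == pytest.approx(140.0)
        assert s.sem_ms == pytest.approx(20.0 / np.sqrt(3))

    def test_single_record_has_no_sem(self):
        records = [PropagationRecord(_burst("left", 0.0), _burst("right", 0.1), 100.0)]
        assert compute_propagation_delays(records).sem_ms is None

    def test_no_propagated_records_is_error(self):
        with pytest.raises(ValueError, match="no propagated"):
            compute_propagation_delays([PropagationRecord(_burst("left", 0.0))])

    def test_recovers_generated_delay_mean(self):
        cfg = SimulationConfig(duration_s=1500.0, seed=21, propagation_p=1.0)
        raster, truth = generate_culture(cfg)
        res = analyze_raster(raster)
        d = res["delays"]
        n = d.delays_ms.size
        assert n >= 80
        sem = cfg.delay_sd_ms / np.sqrt(n)
        assert abs(d.mean_ms - cfg.delay_mean_ms) <= 2 * sem


class TestCompareGroups:
    def test_identical_groups_give_h0_p1(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = compare_groups(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        # fully degenerate values are handled, not an error
        res2 = compare_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert (res2.h_statistic, res2.p_value) == (0.0, 1.0)

    def test_matches_hand_rank_computation(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
        # brute-force H from ranks (no ties): H = 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1)
        pooled = sorted(v for vals in groups.values() for v in vals)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        n_tot = len(pooled)
        h = 12.0 / (n_tot * (n_tot + 1)) * sum(
            len(v) * (np.mean([ranks[x] for x in v])) ** 2 for v in groups.values()
        ) - 3 * (n_tot + 1)
        res = compare_groups(groups)
        assert res.h_statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(1 - stats.chi2.cdf(h, df=2))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two groups"):
            compare_groups({"a": [1.0, 2.0]})

    def test_type_i_error_near_nominal_level(self):
        """Under exchangeable null data the 0.05-level rejection rate stays
        inside the binomial confidence band over 1000 simulations."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            data = rng.normal(size=(3, 8))
            res = compare_groups({f"g{i}": data[i] for i in range(3)})
            rejections += res.p_value < 0.05
        rate = rejections / n_sim
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= ci + 0.01  # chi2 approximation slack at n=8
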