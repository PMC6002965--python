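"""Episode detection: the 20-min threshold/completion rules, gap
merging, day/night assignment, exposure normalisation, brute-force
oracle equivalence and injected-ground-truth recovery."""

import dataclasses
from datetime import datetime

import numpy as np
import pytest

from hypocgm.episodes import (
    THRESHOLDS,
    analyze_subject,
    day_night_split,
    detect_episodes,
    summarize,
)
from hypocgm.errors import InputError
from hypocgm.simulate import generate_trace
from hypocgm.types import GlucoseTrace

from conftest import make_trace, quiet_config
from oracles import brute_force_episodes


def trace_from_pattern(below_pattern, low=3.5, high=8.0, start_hour=12):
    """1 = sample at/below 4.0, 0 = above; 5-min grid."""
    vals = np.where(np.asarray(below_pattern) > 0, low, high).astype(float)
    return make_trace(vals, start=datetime(2017, 1, 2, start_hour, 0))


class TestDetectEpisodes:
    def test_thirty_minutes_below_is_one_episode(self):
        tr = trace_from_pattern([0] * 5 + [1] * 6 + [0] * 5)
        [ep] = detect_episodes(tr, 4.0)
        assert ep.duration_min == 30.0
        assert ep.nadir == 3.5

    def test_fifteen_minutes_below_is_no_episode(self):
        tr = trace_from_pattern([0] * 5 + [1] * 3 + [0] * 5)
        assert detect_episodes(tr, 4.0) == []

    def test_gap_merge_hand_trace(self):
        # 25 min below, 15 min above, 25 min below -> one 50-min episode
        tr = trace_from_pattern([0] * 4 + [1] * 5 + [0] * 3 + [1] * 5 + [0] * 4)
        [ep] = detect_episodes(tr, 4.0)
        assert ep.duration_min == 50.0  # merged-gap time excluded

    def test_gap_of_exactly_twenty_minutes_does_not_complete(self):
        tr = trace_from_pattern([1] * 5 + [0] * 4 + [1] * 5 + [0] * 6)
        [ep] = detect_episodes(tr, 4.0)
        assert ep.duration_min == 50.0

    def test_gap_over_twenty_minutes_completes(self):
        tr = trace_from_pattern([1] * 5 + [0] * 5 + [1] * 5 + [0] * 6)
        eps = detect_episodes(tr, 4.0)
        assert [ep.duration_min for ep in eps] == [25.0, 25.0]

    def test_sample_at_threshold_counts(self):
        tr = trace_from_pattern([1] * 6, low=4.0)
        [ep] = detect_episodes(tr, 4.0)
        assert ep.duration_min == 30.0 and ep.nadir == 4.0

    def test_gapped_segment_rejected(self):
        vals = np.full(20, 3.0)
        vals[3] = np.nan
        with pytest.raises(InputError):
            detect_episodes(make_trace(vals), 4.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(InputError):
            detect_episodes(trace_from_pattern([1] * 6), 0.0)

    def test_episodes_disjoint_and_long_enough(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = np.clip(5 + np.cumsum(rng.normal(0, 0.8, 200)), 1.2, 30)
            eps = detect_episodes(make_trace(vals), 4.0)
            for ep in eps:
                assert ep.duration_min >= 20.0
            for a, b in zip(eps[:-1], eps[1:]):
                assert a.end <= b.start

    def test_duration_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            vals = np.clip(5 + np.cumsum(rng.normal(0, 0.8, 250)), 1.2, 30)
            tr = make_trace(vals)
            durs = {
                thr: sum(ep.duration_min for ep in detect_episodes(tr, thr))
                for thr in THRESHOLDS
            }
            assert durs[2.2] <= durs[3.0] <= durs[4.0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(5, 201))
            vals = np.clip(
                rng.normal(5.0, 2.0) + np.cumsum(rng.normal(0, 0.7, n)), 1.2, 30
            )
            tr = make_trace(vals)
            got = detect_episodes(tr, 4.0)
            want = brute_force_episodes(vals, 4.0, 5.0)
            assert len(got) == len(want)
            for ep, (i0, i1, dur) in zip(got, want):
                assert ep.duration_min == pytest.approx(dur)


class TestDayNight:
    def test_start_just_before_eight_is_night(self):
        tr = trace_from_pattern([1] * 6 + [0] * 10, start_hour=7)
        [ep] = detect_episodes(tr, 4.0)
        tr2 = GlucoseTrace(
            "s1", datetime(2017, 1, 2, 7, 55), 5.0, tr.values
        )
        [ep2] = detect_episodes(tr2, 4.0)
        assert ep.period == "night"  # starts 07:00
        assert ep2.period == "night"  # starts 07:55

    def test_start_at_eight_is_day_midnight_is_night(self):
        tr_day = trace_from_pattern([1] * 6 + [0] * 10, start_hour=8)
        assert detect_episodes(tr_day, 4.0)[0].period == "day"
        tr_night = trace_from_pattern([1] * 6 + [0] * 10, start_hour=0)
        assert detect_episodes(tr_night, 4.0)[0].period == "night"

    def test_split_counts(self):
        tr = trace_from_pattern(
            [1] * 6 + [0] * 10 + [1] * 6 + [0] * 10, start_hour=7
        )
        eps = detect_episodes(tr, 4.0)
        counts = day_night_split(eps)
        assert counts["night"] == 1 and counts["day"] == 1


class TestSummarize:
    def test_unit_exposure(self):
        tr = trace_from_pattern(
            [1] * 10 + [0] * 10 + [1] * 10 + [0] * 5, low=3.2
        )
        eps = detect_episodes(tr, 4.0)
        s = summarize("s1", {4.0: eps}, exposure_hours=168.0)
        assert s.by_threshold[4.0].rate_per_week == pytest.approx(2.0)
        assert s.by_threshold[4.0].duration_min_per_week == pytest.approx(100.0)

    def test_linear_scaling(self):
        tr = trace_from_pattern([1] * 6 + [0] * 6)
        eps = detect_episodes(tr, 4.0)
        s = summarize("s1", {4.0: eps}, exposure_hours=84.0)  # 3.5 days
        assert s.by_threshold[4.0].rate_per_week == pytest.approx(2.0)

    def test_zero_exposure_rejected(self):
        with pytest.raises(InputError):
            summarize("s1", {4.0: []}, exposure_hours=0.0)

    def test_duration_rate_inequality(self):
        # duration/week >= 20 min x rate for every subject by construction
        rng = np.random.default_rng(3)
        vals = np.clip(6 + np.cumsum(rng.normal(0, 0.7, 2000)), 1.2, 30)
        s = analyze_subject(make_trace(vals))
        for ts in s.by_threshold.values():
            assert ts.duration_min_per_week >= 20.0 * ts.rate_per_week - 1e-9
            assert ts.day_count + ts.night_count == ts.n_episodes


class TestGroundTruthRecovery:
    def test_noise_free_injected_events_recovered_exactly(self, subject):
        cfg = quiet_config(baseline=9.0, rate=5.5, days=7.0)
        for seed in range(6):
            tr, events = generate_trace(subject, cfg, seed, with_events=True)
            detected = detect_episodes(tr, 4.0)
            assert len(detected) == len(events)
            # deep events are exactly the ones recovered at 3.0
            deep = [e for e in events if e.nadir <= 3.0]
            det3 = detect_episodes(tr, 3.0)
            assert len(det3) == len(deep)
            total_detected = sum(ep.duration_min for ep in detected)
            total_truth = sum(e.realized_below_min for e in events)
            assert total_detected == pytest.approx(total_truth)

    def test_high_group_deep_events_only_at_night(self, subject):
        # night-restricted deep excursions + daytime-safe background mean
        # zero daytime episodes below 3 mmol/l
        import dataclasses as dc

        from hypocgm.config import ExcursionParams, GeneratorConfig, SmbgParams
        from hypocgm.config import default_cgm_config

        cfg = default_cgm_config(0)
        high = cfg.group("high")
        cfg = dc.replace(cfg, groups=(dc.replace(high, label="low"),))
        for seed in range(8):
            tr = generate_trace(subject, cfg, seed)
            for ep in detect_episodes(tr, 3.0):
                assert ep.period == "night"
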