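"""Generator contracts: determinism, closed-form moments, Poisson event
rates, night restriction, SMBG and questionnaire draws, cohort shapes."""

import dataclasses

import numpy as np
import pytest

from hypocgm.clarke import score_clarke
from hypocgm.config import (
    ExcursionParams,
    QuestionnaireParams,
    default_cgm_config,
    default_questionnaire_config,
)
from hypocgm.errors import ConfigError, InputError
from hypocgm.simulate import (
    _nearest_category,
    generate_cohort,
    generate_questionnaire,
    generate_smbg,
    generate_trace,
    inject_excursions,
)
from conftest import make_trace, quiet_config


class TestGenerateTrace:
    def test_noise_free_trace_is_flat_at_baseline(self, subject):
        cfg = quiet_config(baseline=10.2)
        tr = generate_trace(subject, cfg, seed=1)
        assert tr.n_samples == 4 * 288
        assert np.allclose(tr.values, 10.2, atol=1e-3)

    def test_sinusoid_sd_matches_closed_form(self, subject):
        # SD of a pure sinusoid of amplitude A tends to A/sqrt(2); the
        # expected value is also computed brute-force over one period.
        A = 2.0
        cfg = quiet_config(baseline=15.0, amplitude=A, days=6.0)
        tr = generate_trace(subject, cfg, seed=1)
        brute = np.std(tr.values[:288], ddof=0)  # one full period
        assert brute == pytest.approx(A / np.sqrt(2), rel=1e-3)
        assert np.std(tr.values, ddof=1) == pytest.approx(A / np.sqrt(2), rel=1e-2)

    def test_same_seed_identical_different_seed_differs(self, subject):
        cfg = quiet_config(ou_sd=2.0, rate=3.0)
        a = generate_trace(subject, cfg, seed=7)
        b = generate_trace(subject, cfg, seed=7)
        c = generate_trace(subject, cfg, seed=8)
        assert np.array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_negative_seed_rejected(self, subject):
        with pytest.raises(InputError):
            generate_trace(subject, quiet_config(), seed=-1)

    def test_unknown_group_rejected(self, subject):
        cfg = quiet_config()
        bad = dataclasses.replace(subject, group="nope")
        with pytest.raises(ConfigError):
            generate_trace(bad, cfg, seed=1)

    def test_stationary_sd_closed_form_with_excursions_disabled(self, subject):
        # var = OU variance + A^2/2 when the counter-regulatory floor is
        # not engaged (baseline well above it).
        cfg = quiet_config(baseline=12.0, ou_sd=1.0, amplitude=1.5, days=14.0)
        sds = [
            np.std(generate_trace(subject, cfg, seed=s).values, ddof=1)
            for s in range(12)
        ]
        expected = np.sqrt(1.0**2 + 1.5**2 / 2)
        assert np.mean(sds) == pytest.approx(expected, rel=0.03)


class TestInjectExcursions:
    def test_zero_rate_leaves_trace_unchanged(self):
        tr = make_trace(np.full(1000, 9.0))
        out, events = inject_excursions(tr, ExcursionParams(rate_per_week=0.0), 1)
        assert events == []
        assert np.array_equal(out.values, tr.values)

    def test_gapped_trace_rejected(self):
        vals = np.full(600, 9.0)
        vals[5] = np.nan
        with pytest.raises(InputError):
            inject_excursions(make_trace(vals), ExcursionParams(), 1)

    def test_saturating_process_rejected(self):
        tr = make_trace(np.full(2016, 9.0))
        params = ExcursionParams(rate_per_week=40.0, duration_mean_min=200.0)
        with pytest.raises(ConfigError):
            inject_excursions(tr, params, 1)

    def test_poisson_rate_recovered(self):
        # 4-week noise-free traces; sample mean event rate must sit within
        # 2 Monte-Carlo SEs of the configured rate.
        rate = 5.5
        weeks = 4.0
        n_subj = 250
        tr = make_trace(np.full(int(weeks * 7 * 288), 10.0))
        counts = [
            len(inject_excursions(tr, ExcursionParams(rate_per_week=rate), s)[1])
            for s in range(n_subj)
        ]
        mean_rate = np.mean(counts) / weeks
        se = np.sqrt(rate / (weeks * n_subj))
        assert abs(mean_rate - rate) < 2 * se

    def test_night_only_deep_events_confined_to_night(self):
        params = ExcursionParams(rate_per_week=6.0, night_prob_deep=1.0)
        tr = make_trace(np.full(14 * 288, 10.0))
        for seed in range(5):
            _, events = inject_excursions(tr, params, seed)
            deep = [e for e in events if e.nadir <= 3.0]
            assert deep, "expected at least one deep event"
            for e in deep:
                sh = e.start.hour + e.start.minute / 60
                eh = e.end.hour + e.end.minute / 60
                assert sh < 8.0 and eh <= 8.0

    def test_events_disjoint_and_separated(self):
        params = ExcursionParams(rate_per_week=8.0)
        tr = make_trace(np.full(14 * 288, 10.0))
        _, events = inject_excursions(tr, params, 3)
        events.sort(key=lambda e: e.start_index)
        for a, b in zip(events[:-1], events[1:]):
            gap_min = (b.start_index - a.end_index) * 5.0
            assert gap_min > 20.0

    def test_realized_duration_tracks_target(self):
        tr = make_trace(np.full(14 * 288, 10.0))
        _, events = inject_excursions(tr, ExcursionParams(rate_per_week=5.0), 11)
        for e in events:
            assert e.realized_below_min == pytest.approx(e.target_below_min, abs=11)


class TestGenerateSmbg:
    def test_zero_cv_reproduces_sensor_exactly(self, subject):
        cfg = quiet_config(ou_sd=2.0, smbg_cv=0.0)
        tr = generate_trace(subject, cfg, seed=2)
        readings = generate_smbg(tr, cfg, seed=3)
        for r in readings:
            idx = round((r.time - tr.start).total_seconds() / 60 / 5)
            assert r.glucose_mmol_l == pytest.approx(tr.values[idx], abs=1e-12)

    def test_reading_counts(self, subject):
        cfg = quiet_config(days=4.0)
        tr = generate_trace(subject, cfg, seed=1)
        assert len(generate_smbg(tr, cfg, seed=1)) == 16

        cfg0 = dataclasses.replace(
            cfg, smbg=dataclasses.replace(cfg.smbg, per_day=0)
        )
        assert generate_smbg(tr, cfg0, seed=1) == []

    def test_negative_readings_per_day_rejected(self, subject):
        cfg = quiet_config()
        tr = generate_trace(subject, cfg, seed=1)
        bad = dataclasses.replace(cfg, smbg=dataclasses.replace(cfg.smbg, per_day=-1))
        with pytest.raises(ConfigError):
            generate_smbg(tr, bad, seed=1)


class TestGenerateQuestionnaire:
    def test_zero_rate_gives_none_category(self, subject):
        cfg = quiet_config()
        g = dataclasses.replace(
            cfg.groups[0],
            questionnaire=QuestionnaireParams(
                q5_mean_per_month=0.0, q6_mean_per_month=0.0,
                item_probs=(0.0,) * 7,
            ),
        )
        cfg = dataclasses.replace(cfg, groups=(g,))
        resp = generate_questionnaire(subject, cfg, seed=4)
        assert resp.q5_category == "none"
        assert resp.q6_category == "none"

    def test_count_ten_maps_to_two_three_per_week(self):
        # 2-3/week recodes to 2.5 x 4 = 10, an exact hit
        assert _nearest_category(10) == "2-3 per week"
        assert _nearest_category(0) == "none"
        assert _nearest_category(1) == "none"  # tie 0 vs 2 -> lower category
        assert _nearest_category(25) == "almost daily"

    def test_saturated_items_score_seven(self, subject):
        cfg = quiet_config()
        g = dataclasses.replace(
            cfg.groups[0],
            questionnaire=QuestionnaireParams(item_probs=(1.0,) * 7),
        )
        cfg = dataclasses.replace(cfg, groups=(g,))
        resp = generate_questionnaire(subject, cfg, seed=4)
        res = score_clarke(resp)
        assert res.score == 7 and res.reduced_awareness


class TestGenerateCohort:
    def test_cgm_default_sizes(self):
        cohort = generate_cohort(default_cgm_config(seed=5))
        assert len(cohort.subjects) == 34
        groups = [s.group for s in cohort.subjects]
        assert groups.count("low") == 17 and groups.count("high") == 17
        assert len(cohort.traces) == 34 and len(cohort.smbg) == 34

    def test_questionnaire_default_sizes(self):
        cfg = default_questionnaire_config(seed=5)
        cohort = generate_cohort(cfg)
        groups = [s.group for s in cohort.subjects]
        assert groups.count("low") == 35 and groups.count("high") == 221
        assert cohort.traces == {}
        assert len(cohort.clarke) == 256

    def test_same_master_seed_byte_identical_files(self, tmp_path):
        cfg = default_questionnaire_config(seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg).write(d1)
        generate_cohort(cfg).write(d2)
        for name in ("subjects.csv", "clarke.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_cpeptide_consistent_with_group_thresholds(self):
        cohort = generate_cohort(default_cgm_config(seed=2))
        for s in cohort.subjects:
            if s.group == "low":
                assert s.cpeptide_pmol_l < 200
            else:
                assert s.cpeptide_pmol_l > 600
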