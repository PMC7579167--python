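from __future__ import annotations

import dataclasses
import filecmp
import math
from pathlib import Path

import numpy as np
import pytest

from stressmap import (
    ConfigError,
    MosRuleConfig,
    ScenarioConfig,
    StressorSite,
    detect_mos,
    evaluate_detection,
    generate_campaign,
    generate_participant,
    preprocess,
    write_campaign,
)


def onsets_s(events, trace):
    t0 = trace.start_time.timestamp()
    return [e.onset_time.timestamp() - t0 for e in events]


class TestGeneration:
    def test_closed_loop_noise_free(self):
        """5 stressor passages, p=1, zero noise: detector recovers all 5."""
        cfg = ScenarioConfig.default_walk(n_sites=5, seed=42)
        p = generate_participant(cfg)
        assert len(p.truth) == 5
        events = detect_mos(preprocess(p.trace))
        precision, recall = evaluate_detection(
            onsets_s(events, p.trace), [e.onset_s for e in p.truth])
        assert precision == 1.0 and recall == 1.0

    def test_no_events_when_probability_zero(self):
        cfg = ScenarioConfig.default_walk(n_sites=5, seed=1)
        cfg = dataclasses.replace(cfg, stressor_sites=tuple(
            dataclasses.replace(s, event_probability=0.0)
            for s in cfg.stressor_sites))
        p = generate_participant(cfg)
        assert p.truth == []
        assert detect_mos(preprocess(p.trace)) == []

    def test_reduction_factor_exact_in_annotations(self):
        pre = ScenarioConfig.default_walk(n_sites=50, seed=2)
        post = dataclasses.replace(pre, reduction_factor=0.8)
        n_pre = len(generate_participant(pre).truth)
        n_post = len(generate_participant(post).truth)
        assert (n_pre, n_post) == (50, 40)
        assert n_post / n_pre == pytest.approx(0.8)

    def test_route_too_short_rejected(self):
        cfg = ScenarioConfig(
            route=((13.04, 47.80), (13.0401, 47.80)),  # ~7.5 m
            walk_duration_s=600.0,
            stressor_sites=(StressorSite(13.04, 47.8),),
        )
        with pytest.raises(ConfigError, match="shorter"):
            generate_participant(cfg)

    def test_diary_entries_negative_at_sites(self):
        cfg = ScenarioConfig.default_walk(n_sites=10, seed=3,
                                          diary_report_probability=1.0)
        p = generate_participant(cfg)
        assert len(p.diary) == 10
        assert all(e.valence == "negative" for e in p.diary)
        assert all(not e.needs_georef for e in p.diary)

    def test_truth_located_on_route(self):
        cfg = ScenarioConfig.default_walk(n_sites=4, seed=4)
        p = generate_participant(cfg)
        for ev in p.truth:
            # event location within the track's bounding box
            assert p.track.lon.min() - 1e-6 <= ev.lon <= p.track.lon.max() + 1e-6
            assert p.track.lat.min() - 1e-4 <= ev.lat <= p.track.lat.max() + 1e-4


class TestTemplateSatisfiesRule:
    def test_planted_events_satisfy_all_clauses_on_raw_signal(self):
        """Rule clauses hold on the generated (unfiltered) signal itself."""
        cfg = ScenarioConfig.default_walk(n_sites=5, seed=0,
                                          tonic_drift_amp_us=0.0)
        rule = MosRuleConfig()
        p = generate_participant(cfg)
        fs = p.trace.fs
        w = int(round(rule.gsr_rise_window_s * fs))
        lag = int(round(rule.st_lag_s * fs))
        search = int(round(rule.st_search_window_s * fs))
        for ev in p.truth:
            t = int(round(ev.onset_s * fs))
            g = p.trace.gsr[t:t + w + 1]
            steps = np.diff(g)
            assert np.all(steps >= -rule.monotonicity_tolerance_us)
            delta = g[-1] - g[0]
            angle = math.degrees(math.atan(delta / rule.gsr_rise_window_s))
            # amplitude chosen so the raw slope clears the 10 degree gate wide
            assert angle >= rule.min_slope_deg + 10.0
            st_win = p.trace.st[t + lag: t + lag + search + 1]
            i_max = int(np.argmax(st_win))
            assert i_max < len(st_win) - 1
            i_min = i_max + 1 + int(np.argmin(st_win[i_max + 1:]))
            assert st_win[i_max] - st_win[i_min] > 0

    def test_filtered_slope_margin(self):
        """After band-pass filtering the planted slope still clears the gate."""
        cfg = ScenarioConfig.default_walk(n_sites=5, seed=0)
        p = generate_participant(cfg)
        events = detect_mos(preprocess(p.trace))
        assert len(events) == 5
        assert min(e.gsr_slope_deg for e in events) >= 12.0


class TestDeterminism:
    def test_identical_seeds_byte_identical_files(self, tmp_path):
        cfg = ScenarioConfig.default_walk(n_sites=5, seed=9,
                                          gsr_noise_sd_us=0.05,
                                          diary_report_probability=0.5,
                                          n_participants=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_campaign(generate_campaign(cfg), d1)
        write_campaign(generate_campaign(cfg), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_different_seeds_differ(self):
        p1 = generate_participant(ScenarioConfig.default_walk(
            n_sites=5, seed=1, gsr_noise_sd_us=0.05))
        p2 = generate_participant(ScenarioConfig.default_walk(
            n_sites=5, seed=2, gsr_noise_sd_us=0.05))
        assert not np.array_equal(p1.trace.gsr, p2.trace.gsr)
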