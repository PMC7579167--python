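from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressmap import ContractError, MosRuleConfig, TooShortError, detect_mos, evaluate_detection
from conftest import FS, T0, make_filtered
from helpers import reference_detect_onsets


def template_trace(rise_start_s=10.0, rise_s=5.0, amp_us=1.0,
                   st_max_s=13.5, st_end_s=20.0, st_drop=0.2,
                   duration_s=120.0, fs=FS):
    """Phasic rise + delayed ST drop, built exactly to the rule's geometry."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    g = np.clip((t - rise_start_s) / rise_s, 0.0, 1.0) * amp_us
    stc = np.full_like(t, 33.0)
    falling = (t > st_max_s) & (t <= st_end_s)
    stc[falling] = 33.0 - st_drop * (t[falling] - st_max_s) / (st_end_s - st_max_s)
    stc[t > st_end_s] = 33.0 - st_drop
    return make_filtered(g, stc, fs=fs)


class TestRuleClauses:
    def test_flat_trace_has_no_events(self):
        trace = make_filtered(np.zeros(480), np.full(480, 33.0))
        assert detect_mos(trace) == []

    def test_planted_template_fires_once(self):
        """1 µS rise over 5 s (11.3°) with delayed ST max->min: one event."""
        trace = template_trace(amp_us=1.0)
        events = detect_mos(trace)
        assert len(events) == 1
        onset_s = events[0].onset_time.timestamp() - T0.timestamp()
        # windows straddling the flat-to-rise corner also satisfy every
        # clause, so the merged (earliest) onset sits just before the
        # geometric rise start; it must match the independent oracle exactly
        ref = reference_detect_onsets(trace.gsr_phasic, trace.st_smooth,
                                      FS, MosRuleConfig())
        assert len(ref) == 1
        assert onset_s == pytest.approx(ref[0] / FS)
        assert abs(onset_s - 10.0) <= 1.0
        assert events[0].gsr_slope_deg >= 10.0
        assert events[0].st_max_time < events[0].st_min_time

    def test_shallow_slope_rejected(self):
        """0.5 µS over 5 s is a 5.7° slope, below the 10° gate."""
        trace = template_trace(amp_us=0.5)
        assert detect_mos(trace) == []

    def test_missing_st_drop_rejected(self):
        trace = template_trace(amp_us=1.0, st_drop=0.0)
        assert detect_mos(trace) == []

    def test_st_min_drop_threshold(self):
        trace = template_trace(amp_us=1.0, st_drop=0.2)
        assert detect_mos(trace, MosRuleConfig(st_min_drop_degc=0.1))
        assert detect_mos(trace, MosRuleConfig(st_min_drop_degc=0.5)) == []

    def test_unfiltered_trace_rejected(self):
        from stressmap import PhysioTrace

        raw = PhysioTrace(participant_id="p", start_time=T0, fs=FS,
                          gsr=np.zeros(480), st=np.full(480, 33.0))
        with pytest.raises(ContractError):
            detect_mos(raw)

    def test_too_short_trace_rejected(self):
        trace = make_filtered(np.zeros(20), np.full(20, 33.0))
        with pytest.raises(TooShortError):
            detect_mos(trace)


class TestAgainstReferenceImplementation:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_straight_line_oracle_on_random_traces(self, seed):
        """Smoothed random walks: merged onsets equal the oracle's everywhere."""
        rng = np.random.default_rng(seed)
        n = 400
        g = np.cumsum(rng.normal(0, 0.2, n))
        stc = 33.0 + np.cumsum(rng.normal(0, 0.02, n))
        trace = make_filtered(g, stc)
        events = detect_mos(trace)
        got = [round((e.onset_time.timestamp() - T0.timestamp()) * FS) for e in events]
        assert got == reference_detect_onsets(g, stc, FS, MosRuleConfig())


class TestDetectorProperties:
    def test_shift_equivariance(self):
        trace = template_trace(amp_us=1.0)
        k = 32  # 8 s
        g2 = np.concatenate([np.zeros(k), trace.gsr_phasic])[:len(trace.gsr_phasic) + k]
        st2 = np.concatenate([np.full(k, 33.0), trace.st_smooth])
        shifted = make_filtered(g2, st2)
        e1 = detect_mos(trace)
        e2 = detect_mos(shifted)
        assert len(e1) == len(e2) == 1
        dt = e2[0].onset_time.timestamp() - e1[0].onset_time.timestamp()
        assert dt == pytest.approx(k / FS)

    def test_monotone_sensitivity_in_slope_gate(self):
        rng = np.random.default_rng(3)
        g = np.cumsum(rng.normal(0, 0.3, 600))
        stc = 33.0 + np.cumsum(rng.normal(0, 0.03, 600))
        trace = make_filtered(g, stc)
        counts = [len(detect_mos(trace, MosRuleConfig(min_slope_deg=d)))
                  for d in (0.0, 5.0, 10.0, 20.0, 40.0)]
        assert counts == sorted(counts, reverse=True)


class TestEvaluateDetection:
    @pytest.mark.parametrize("events,truth,expected", [
        ([10, 60], [10, 60], (1.0, 1.0)),
        ([10], [10, 60], (1.0, 0.5)),
        ([10, 12], [10], (0.5, 1.0)),  # second event left unmatched
        ([], [10], (1.0, 0.0)),
        ([10], [], (0.0, 1.0)),
    ])
    def test_greedy_matching(self, events, truth, expected):
        assert evaluate_detection(events, truth) == expected

    def test_tolerance_bound(self):
        assert evaluate_detection([16], [10], match_tol_s=5.0) == (0.0, 0.0)
        assert evaluate_detection([15], [10], match_tol_s=5.0) == (1.0, 1.0)
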