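"""Rule-based moment-of-stress (MOS) detection.

A moment of stress is flagged when three clauses hold simultaneously on the
filtered channels:

1. **Sustained rise** — the phasic GSR is non-decreasing (up to a small
   per-step tolerance) over a 5 s window starting at the candidate onset,
   with a strictly positive net change.
2. **Slope gate** — the rise is steep enough: the angle of the µS-versus-
   seconds line, ``atan((delta_gsr/delta_t) / slope_scale) * 180/pi``, must
   reach ``min_slope_deg`` (default 10°). The angle of a conductance/time
   line depends on the axis scaling, so the scale (µS per second mapped to
   a 45° line) is an explicit, configurable knob, default 1.
3. **Delayed thermal response** — within a search window opening 3 s after
   the onset, smoothed skin temperature shows a local maximum followed by a
   local minimum (peripheral vasoconstriction produces a delayed ST drop).

A single physiological event satisfies the sliding rule at many adjacent
onsets; firings closer together than a refractory interval are merged into
one event, keeping the earliest onset and the steepest slope seen in the
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, ContractError, TooShortError
from .types import FilteredTrace, MosEvent, sort_events


@dataclass(frozen=True)
class MosRuleConfig:
    gsr_rise_window_s: float = 5.0
    st_lag_s: float = 3.0
    min_slope_deg: float = 10.0
    st_search_window_s: float = 10.0
    monotonicity_tolerance_us: float = 0.005
    st_min_drop_degc: float = 0.0  # 0 = any strict decrease
    merge_refractory_s: float = 5.0
    slope_scale_us_per_s: float = 1.0

    def validate(self) -> None:
        for name in ("gsr_rise_window_s", "st_lag_s", "st_search_window_s",
                     "merge_refractory_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.min_slope_deg < 90):
            raise ConfigError("min_slope_deg must be in [0, 90)")
        if self.slope_scale_us_per_s <= 0:
            raise ConfigError("slope_scale_us_per_s must be positive")

    @property
    def min_duration_s(self) -> float:
        return self.gsr_rise_window_s + self.st_lag_s + self.st_search_window_s


def _window_max_then_min(st: np.ndarray) -> tuple[int, int] | None:
    """Earliest maximum, then earliest subsequent minimum, inside a window.

    Ties on plateaus resolve to the earliest sample. Returns ``None`` when no
    sample follows the maximum.
    """
    if len(st) < 2:
        return None
    i_max = int(np.argmax(st))  # argmax takes the first of equal values
    tail = st[i_max + 1:]
    if len(tail) == 0:
        return None
    i_min = i_max + 1 + int(np.argmin(tail))
    return i_max, i_min


def detect_mos(trace: FilteredTrace, cfg: MosRuleConfig | None = None) -> list[MosEvent]:
    """Run the stress rule over a filtered trace; events sorted by onset."""
    cfg = cfg or MosRuleConfig()
    cfg.validate()
    if not isinstance(trace, FilteredTrace):
        raise ContractError("detect_mos requires a FilteredTrace (run preprocess first)")
    if trace.duration_s < cfg.min_duration_s:
        raise TooShortError(
            f"trace of {trace.duration_s:.1f}s shorter than the "
            f"{cfg.min_duration_s:.1f}s the rule template needs"
        )

    fs = trace.fs
    g = trace.gsr_phasic
    st = trace.st_smooth
    n = len(g)
    w = int(round(cfg.gsr_rise_window_s * fs))
    lag = int(round(cfg.st_lag_s * fs))
    search = int(round(cfg.st_search_window_s * fs))

    # clause 1: near-monotone non-decrease over every window of w steps
    steps = np.diff(g)
    ok_step = steps >= -cfg.monotonicity_tolerance_us
    # mono[t] == True iff all steps t .. t+w-1 are acceptable
    csum = np.concatenate(([0], np.cumsum(ok_step.astype(np.int64))))
    n_onsets = n - w  # candidate onsets 0 .. n-w-1 (window needs sample t+w)
    if n_onsets <= 0:
        return []
    mono = (csum[w:w + n_onsets] - csum[:n_onsets]) == w

    # clauses 1b + 2: positive net change and slope angle gate
    delta = g[w:w + n_onsets] - g[:n_onsets]
    slope = delta / cfg.gsr_rise_window_s
    angle = np.degrees(np.arctan(slope / cfg.slope_scale_us_per_s))
    gates = mono & (delta > 0) & (angle >= cfg.min_slope_deg)

    firings: list[tuple[int, float, float, int, int]] = []
    for t in np.flatnonzero(gates):
        i0 = t + lag
        i1 = min(n, i0 + search + 1)
        if i0 >= n - 1:
            continue
        ext = _window_max_then_min(st[i0:i1])
        if ext is None:
            continue
        i_max, i_min = ext
        drop = st[i0 + i_max] - st[i0 + i_min]
        if drop <= 0 or drop < cfg.st_min_drop_degc:
            continue
        firings.append((int(t), float(angle[t]), float(delta[t]),
                        i0 + i_max, i0 + i_min))

    # merge firings closer than the refractory interval
    events: list[MosEvent] = []
    refractory = int(round(cfg.merge_refractory_s * fs))
    cluster: list[tuple[int, float, float, int, int]] = []

    def flush() -> None:
        if not cluster:
            return
        onset = cluster[0][0]  # earliest onset
        best = max(cluster, key=lambda f: f[1])  # steepest slope
        _, slope_deg, delta_us, imax, imin = best
        events.append(MosEvent(
            participant_id=trace.participant_id,
            onset_time=trace.time_at(onset),
            window_end_time=trace.time_at(onset + w),
            gsr_slope_deg=slope_deg,
            gsr_delta_us=delta_us,
            st_max_time=trace.time_at(imax),
            st_min_time=trace.time_at(imin),
        ))

    for f in firings:
        if cluster and f[0] - cluster[-1][0] >= refractory:
            flush()
            cluster = []
        cluster.append(f)
    flush()
    return sort_events(events)


def evaluate_detection(
    event_onsets_s: Sequence[float],
    truth_onsets_s: Sequence[float],
    match_tol_s: float = 5.0,
) -> tuple[float, float]:
    """Precision and recall by greedy one-to-one nearest-onset matching.

    Events are scanned in time order; each is matched to the nearest still
    unmatched true onset within ``match_tol_s``. Empty sets follow the usual
    conventions (precision of no events = 1, recall of no truth = 1).
    """
    events = sorted(float(t) for t in event_onsets_s)
    truth = sorted(float(t) for t in truth_onsets_s)
    if list(truth) != sorted(truth):
        raise ContractError("truth onsets must be sorted")
    unmatched = list(truth)
    tp = 0
    for e in events:
        if not unmatched:
            break
        i = int(np.argmin([abs(e - t) for t in unmatched]))
        if abs(e - unmatched[i]) <= match_tol_s:
            unmatched.pop(i)
            tp += 1
    precision = tp / len(events) if events else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
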