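"""Independent reference implementations used as oracles in the tests.

Everything here is written as plain nested loops, directly from the rule
definitions, and is deliberately kept independent of the package's
vectorised code paths.
"""

from __future__ import annotations

import math


def reference_detect_onsets(g, st, fs, cfg) -> list[int]:
    """Straight-line re-implementation of the stress rule; merged onset indices."""
    w = int(round(cfg.gsr_rise_window_s * fs))
    lag = int(round(cfg.st_lag_s * fs))
    sw = int(round(cfg.st_search_window_s * fs))
    onsets = []
    for t in range(len(g) - w):
        ok = True
        for i in range(t, t + w):
            if g[i + 1] - g[i] < -cfg.monotonicity_tolerance_us:
                ok = False
                break
        if not ok:
            continue
        delta = g[t + w] - g[t]
        if delta <= 0:
            continue
        angle = math.degrees(math.atan(
            (delta / cfg.gsr_rise_window_s) / cfg.slope_scale_us_per_s))
        if angle < cfg.min_slope_deg:
            continue
        i0 = t + lag
        i1 = min(len(st), i0 + sw + 1)
        win = list(st[i0:i1])
        if len(win) < 2:
            continue
        imax = 0
        for j in range(1, len(win)):
            if win[j] > win[imax]:
                imax = j
        if imax == len(win) - 1:
            continue
        imin = imax + 1
        for j in range(imax + 1, len(win)):
            if win[j] < win[imin]:
                imin = j
        drop = win[imax] - win[imin]
        if drop <= 0 or drop < cfg.st_min_drop_degc:
            continue
        onsets.append(t)
    merged = []
    refr = int(round(cfg.merge_refractory_s * fs))
    cluster: list[int] = []
    for t in onsets:
        if cluster and t - cluster[-1] >= refr:
            merged.append(cluster[0])
            cluster = []
        cluster.append(t)
    if cluster:
        merged.append(cluster[0])
    return merged


def gi_star_oracle(x, w) -> list[float]:
    """Brute-force double-loop evaluation of the Gi* z formula."""
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(max(sum(v * v for v in x) / n - xbar**2, 0.0))
    z = []
    for i in range(n):
        wsum = sum(w[i][j] for j in range(n))
        s1 = sum(w[i][j] ** 2 for j in range(n))
        num = sum(w[i][j] * x[j] for j in range(n)) - xbar * wsum
        den_sq = (n * s1 - wsum**2) / (n - 1)
        if s == 0 or den_sq <= 0:
            z.append(0.0)
        else:
            z.append(num / (s * math.sqrt(den_sq)))
    return z
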