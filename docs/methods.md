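# Methods

This note documents the signal-processing and spatial-statistics choices in
`stressmap`, the units and defaults of every tunable parameter, and the scope
of the built-in synthetic-data generator. It is the reference for anyone who
wants to audit a number the package produces.

## 1. Measurement model

Each participant contributes three streams:

- **Physiology** — galvanic skin response (GSR, microsiemens) and skin
  temperature (ST, degrees Celsius), sampled at a common rate `fs`
  (default 4 Hz, the rate of common wrist-worn research devices).
- **Location** — a GPS track (GPX 1.1 or GeoJSON) of timestamped fixes.
- **Diary** — optional self-reports with a closed emotion vocabulary
  (`happiness`, `anger/disgust`, `sadness`, `fear`), a closed trigger
  vocabulary, and an intensity on a 1–5 scale.

All timestamps are required to be timezone-aware and are normalised to UTC on
ingest. Naive timestamps are accepted only when the caller supplies an
explicit UTC offset.

A *moment of stress* (MOS) is modelled as a phasic GSR rise accompanied, after
a short physiological lag, by a transient skin-temperature drop — the
standard sympathetic-arousal signature.

## 2. Preprocessing

GSR is band-passed with two zero-phase order-2 Butterworth filters
(`scipy.signal.filtfilt`):

- **Low-pass at 0.5 Hz** removes sensor noise above the physiological band.
- **High-pass at 0.05 Hz** removes the tonic (baseline) skin-conductance
  level, leaving the phasic component the detector operates on.

ST gets the low-pass only; its tonic level is meaningful for the max→min
drop test.

Because `filtfilt` applies the filter forward and backward, the effective
steady-state gain at frequency `f` is the *squared* single-pass magnitude
`|H(e^{j2πf/fs})|²`, evaluated with `scipy.signal.freqz`. This is what
`preprocess.zero_phase_gain` returns, and what the acceptance tests verify
against lock-in measurements on sine probes (agreement within 1 %; DC residual
after the high-pass below 1e-6 µS). Note the commonly quoted analog formula
`1/√(1+(f/fc)^(2n))` is *not* the right prediction here, both because of the
forward–backward pass and because of the bilinear-transform frequency warping
at these sample rates.

Traces shorter than 3× the filter pad length (a few dozen samples at 4 Hz)
are rejected with `TooShortError` rather than silently producing edge
artefacts.

## 3. MOS detection rule

A candidate window starts at sample `t` and spans `gsr_rise_window_s`
(default 5 s) of the phasic GSR. Three clauses must all hold:

1. **Non-decrease** — every successive sample step is ≥
   `-monotonicity_tolerance_us` (default 0.005 µS, absorbing float noise).
2. **Slope gate** — the rise expressed as an angle,
   `atan((Δ µS / window s) / slope_scale_us_per_s)` in degrees, is at least
   `min_slope_deg` (default 10°). With the default scale of 1 µS/s per unit
   slope, 10° corresponds to ≈ 0.176 µS/s, i.e. ≈ 0.88 µS over the 5 s
   window.
3. **ST drop** — in the window `[t + st_lag_s, t + st_lag_s +
   st_search_window_s]` (defaults 3 s and 10 s), the ST trace attains a local
   maximum strictly before a lower later minimum (earliest maximum, then the
   minimum after it), with drop depth > `st_min_drop_degc` (default 0, i.e.
   any strictly positive drop).

Overlapping candidate windows are physiologically one event: candidates
closer than `merge_refractory_s` (default 5 s) are merged, keeping the
**earliest onset** and reporting the **steepest slope** among the merged
members. A consequence worth knowing: for a rise that starts at time T, the
window beginning slightly before T can already satisfy all three clauses, so
the reported onset typically sits up to ~0.5 s before the geometric corner of
the rise. The tests pin this behaviour against an independent straight-line
reference implementation.

Detector quality is summarised by greedy one-to-one nearest-onset matching
against ground truth with a 5 s tolerance (`evaluate_detection`), giving
precision and recall.

## 4. Georeferencing

Event and diary timestamps are located on the GPS track by linear
interpolation between the bracketing fixes. Confidence is reported as
`exact` (timestamp coincides with a fix), `interpolated` (bracketing gap ≤
`max_gap_s`, default 10 s), or `low` (wider gap). Timestamps outside the
track's time span stay unlocated but are retained.

## 5. Projection and gridding

Points are projected to the UTM zone of the data's centroid. Since the
environment carries no projection library, the transverse Mercator mapping is
implemented directly with the 6th-order Krüger series (WGS84 ellipsoid,
scale 0.9996, standard false easting/northing). The tests verify the
northing on the central meridian against a numerically integrated meridian
arc (`scipy.integrate.quad`) to 1e-6 m and round-trip accuracy to ~1e-11
degrees, which is far below GPS noise.

The grid uses square cells (default `cell_size_m` = 25 m, a scale that
matches street-level walking variation) with **half-open membership**
`[x0, x0 + s)`: a point on a shared edge belongs to the right/upper cell, and
every point lands in exactly one cell or the overflow counter. Count
conservation is exact and tested.

Cell values are **rates** `x_i = n_MOS / n_measurements`, which normalises
away unequal dwell time. Cells with fewer than `min_support`
(default 10) measurement samples are excluded from inference; rates there are
undefined (NaN).

## 6. Hot-spot statistic

Cells are scored with the Getis–Ord Gi* statistic under a binary,
self-inclusive distance-band weight matrix (band = 2 × cell size by default,
so an interior cell has 13 neighbours including itself):

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S · sqrt[(n S1_i − W_i²)/(n−1)])

with `W_i = Σ_j w_ij`, `S1_i = Σ_j w_ij²`, and `S = sqrt(Σx²/n − x̄²)`.
Degenerate cases are defined explicitly: a uniform field (S = 0) scores 0
everywhere, and a cell whose neighbourhood covers the whole study area
(denominator ≤ 0) scores 0. Fewer than two included cells raise
`InsufficientCellsError`. The vectorised implementation is tested against a
brute-force double-loop oracle to 1e-9 on hundreds of random grids.

Classification uses the usual two-sided normal thresholds: |z| ≥ 1.645, 1.96,
2.576 for 90 / 95 / 99 % confidence, labelled `hot90…hot99` and
`cold90…cold99`, else `neutral`.

**Difference maps** compare the sensor-derived rate surface with the
diary-derived one: each surface is min–max normalised over its included
cells, then subtracted (sensor − diary), so +1 means "sensor-only hotspot"
and −1 "diary-only hotspot".

**Pre/post comparison** reports the percent change `(post − pre)/pre · 100`,
either on raw event counts or on exposure-normalised rates
(`mode="exposure_rate"`), overall and per zone (zones are polygons; a cell
belongs to a zone if the zone covers its centroid). A zero pre-campaign
baseline raises `UndefinedChangeError` rather than returning ±∞.

## 7. Synthetic campaign generator

`synthgen` exists to close the loop: it plants events whose ground truth is
known exactly, so detector precision/recall and pre/post recovery can be
measured rather than asserted.

- The walker moves at constant speed (default 1.4 m/s) along a route polyline;
  GPS fixes are emitted at 1 Hz. Stressor sites sit **on** the projected
  route polyline, so every site produces a passage.
- A passage plants a template event: a **linear GSR rise** over
  `rise_duration_s` (5 s) of amplitude `rise_amplitude_us` (3 µS), followed by
  an **exponential decay** with `decay_tau_s` = 4 s; and, `st_lag_s` = 3 s
  later, an ST drop of `st_drop_degc` = 0.5 °C with linear recovery.
- The 3 µS amplitude is deliberately above the ≈ 0.88 µS gate minimum: the
  0.05 Hz high-pass attenuates the net rise of a 5 s ramp by roughly 35–40 %,
  and the amplitude leaves the filtered slope comfortably above the 10° gate
  (the tests require ≥ 12° margin after filtering).
- Noise (Gaussian, per channel) and a slow sinusoidal tonic drift are added
  *after* the templates, so the truth annotations are exact.
- **Interventions** are modelled by `reduction_factor r`: event k (0-based,
  in site order) is kept iff `floor((k+1)·r) − floor(k·r) = 1`. This
  Bresenham-style thinning is deterministic and hits the ratio exactly for
  rational `r` (e.g. r = 0.8 keeps exactly 40 of 50), so the planted
  pre/post change is −20 % by construction, not in expectation.
- All randomness derives from `numpy.random.default_rng([seed,
  participant_index])`; identical configurations produce **byte-identical**
  output files.

Scope limits: the generator produces idealised physiology (no motion
artefacts, electrode losses, or habituation), straight-line default routes,
and noiseless GPS unless configured otherwise. It is a test harness for the
pipeline's logic, not a physiological simulator.

## 8. Default problem sizes

The acceptance quantities (see `scripts/acceptance.py`) are computed at sizes
chosen to be statistically meaningful yet fast: 50 planted events per
detector run, 200 random 8×8 grids for the Gi* oracle comparison, 6 sine
probes for the filter response, 20 seed pairs for the pre/post recovery, and
5000 points for count conservation. The full script runs in a few seconds.
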