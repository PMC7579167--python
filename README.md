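# stressmap

Map where people get stressed in a city from wearable physiology.

Given galvanic skin response (GSR) and skin temperature recorded during
walks, plus GPS tracks and optional emotion diaries, `stressmap`:

1. band-passes the GSR with zero-phase Butterworth filters (low-pass 0.5 Hz,
   high-pass 0.05 Hz for tonic removal),
2. detects **moments of stress** with a transparent three-clause rule
   (5 s non-decreasing phasic GSR rise, slope ≥ 10°, followed 3 s later by a
   skin-temperature max→min drop),
3. georeferences each event onto the GPS track with confidence labels,
4. rasterizes event **rates** (events per measurement sample) onto a 25 m
   UTM grid and scores cells with the **Getis–Ord Gi\*** statistic to produce
   hot/cold-spot layers (GeoJSON + CSV + PNG),
5. compares campaigns (pre/post an intervention) as percent change in raw
   counts or exposure-normalised rates, overall and per zone.

A deterministic synthetic-campaign generator with planted ground truth closes
the loop, so detector precision/recall and pre/post recovery are *measured*,
not assumed. See `docs/methods.md` for the full model and every parameter.

## Worked example

A 30-minute simulated walk passes five planted stressors
(`examples/01_detect_stress_moments.py`):

```python
from stressmap import ScenarioConfig, detect_mos, generate_participant, preprocess

cfg = ScenarioConfig.default_walk(n_sites=5, seed=42)
participant = generate_participant(cfg)
events = detect_mos(preprocess(participant.trace))
```

prints

```
detected 5 moments of stress:
 onset (s)  slope (deg)  GSR rise (uS)  truth (s)
     59.75         21.7           1.99       60.0
     89.75         21.6           1.98       90.0
    119.75         21.6           1.98      120.0
    149.75         21.6           1.98      150.0
    179.75         21.6           1.98      180.0
```

All five planted events are recovered (the onset sits a fraction of a second
before the geometric rise corner — see `docs/methods.md` §3 for why).

A pre/post comparison with a 20 % intervention
(`examples/03_pre_post_comparison.py`):

```
 pre: 50 planted, 50 detected, 1590 s exposure
post: 40 planted, 40 detected, 1590 s exposure

change in detected moments of stress: -20.0%
change in events per second of exposure: -20.0%
```

And a clustered-stressor campaign rendered as a hot-spot map
(`examples/02_hotspot_map.py`):

```
grid: 56 x 1 cells of 25 m (UTM33N)
included cells (>= 10 measurements): 56
neutral    42
hot95      14
```

`examples/04_filter_response.py` prints the predicted vs measured filter
gains (they agree to four decimals at every probe frequency).

## Command line

```bash
stressmap simulate --out campaign/ --seed 42          # synthetic campaign
stressmap detect --participant-dir campaign/p000 --out det/
stressmap hotspots --campaign-dir campaign/ --out hs/
stressmap compare --pre pre/ --post post/ --out cmp/  # writes change.json
```

Each subcommand accepts `--config file.ini` (sections `[scenario]`, `[io]`,
`[preprocess]`, `[mos]`, `[hotspots]`) and writes a `manifest.json` with the
command, parameters, seed and package version, so any run can be reproduced
exactly.

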