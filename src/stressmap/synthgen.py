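"""Synthetic walking-campaign generator.

Produces complete, annotated campaigns — GPS tracks along a route,
physiological traces with planted stress responses, and probabilistic diary
reports — so every pipeline stage can be exercised end-to-end without field
data.

The planted stress response follows the detection-rule template: a linear
conductance rise over 5 s (steep enough to clear the 10° slope gate by a
wide margin at the default amplitude) followed by an exponential decay
(tau = 4 s), and a skin-temperature plateau with a linear drop starting 3 s
after onset. GSR noise is white Gaussian added *before* filtering, so the
low-pass stage is exercised meaningfully; a slow sinusoidal tonic drift
exercises the high-pass stage.

Events are planted when the simulated walker passes a stressor site; a
``reduction_factor`` < 1 (for pre-post scenarios) thins the planted events
deterministically so the post/pre planted-event rate ratio is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError
from .types import DiaryEntry, GeoTrack, PhysioTrace, NEGATIVE_EMOTIONS, TRIGGERS
from .utm import UtmCrs
from . import io_ingest

BASE_START = datetime(2018, 9, 5, 9, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class StressorSite:
    lon: float
    lat: float
    radius_m: float = 20.0
    event_probability: float = 1.0
    site_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.event_probability <= 1.0):
            raise ConfigError("event_probability must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic campaign."""

    seed: int = 0
    n_participants: int = 1
    walk_duration_s: float = 1800.0
    walk_speed_mps: float = 1.4          # typical adult walking speed
    route: tuple[tuple[float, float], ...] = ()   # lon/lat polyline
    stressor_sites: tuple[StressorSite, ...] = ()
    fs: float = 4.0
    gps_fix_interval_s: float = 1.0
    gps_noise_m: float = 0.0
    baseline_gsr_us: float = 2.0
    gsr_noise_sd_us: float = 0.0
    tonic_drift_amp_us: float = 0.5      # slow baseline wander, removed by the high-pass
    tonic_drift_period_s: float = 600.0
    baseline_st_degc: float = 33.0
    st_noise_sd_degc: float = 0.0
    rise_duration_s: float = 5.0
    rise_amplitude_us: float = 3.0
    decay_tau_s: float = 4.0
    st_lag_s: float = 3.0
    st_drop_degc: float = 0.5
    st_drop_duration_s: float = 5.0
    st_recovery_s: float = 15.0
    diary_report_probability: float = 0.5
    reduction_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.diary_report_probability <= 1.0):
            raise ConfigError("diary_report_probability must be in [0, 1]")
        if not (0.0 < self.reduction_factor <= 1.0):
            raise ConfigError("reduction_factor must be in (0, 1]")
        if self.walk_speed_mps <= 0 or self.walk_duration_s <= 0:
            raise ConfigError("walk speed and duration must be positive")

    @classmethod
    def default_walk(
        cls,
        n_sites: int,
        site_spacing_s: float = 30.0,
        seed: int = 0,
        origin: tuple[float, float] = (13.04, 47.80),
        **overrides,
    ) -> "ScenarioConfig":
        """A straight street walk with ``n_sites`` stressors every
        ``site_spacing_s`` seconds of walking; duration sized to fit them."""
        speed = float(overrides.pop("walk_speed_mps", 1.4))
        warmup_s = 30.0
        tail_s = 60.0
        duration = warmup_s + n_sites * site_spacing_s + tail_s
        length_m = duration * speed + 10.0
        lon0, lat0 = origin
        # eastward straight segment of the required metric length
        crs = UtmCrs.for_points([lon0], [lat0])
        x0, y0 = crs.project(lon0, lat0)
        lon1, lat1 = crs.unproject(x0 + length_m, y0)
        route = ((lon0, lat0), (float(lon1), float(lat1)))
        # place sites along the route exactly as the walker traverses it
        rx, ry = crs.project(np.array([route[0][0], route[1][0]]),
                             np.array([route[0][1], route[1][1]]))
        seg = float(np.hypot(rx[1] - rx[0], ry[1] - ry[0]))
        sites = []
        for i in range(n_sites):
            d = (warmup_s + (i + 1) * site_spacing_s) * speed
            frac = d / seg
            lon, lat = crs.unproject(rx[0] + frac * (rx[1] - rx[0]),
                                     ry[0] + frac * (ry[1] - ry[0]))
            sites.append(StressorSite(lon=float(lon), lat=float(lat),
                                      radius_m=20.0, event_probability=1.0,
                                      site_id=f"site{i:03d}"))
        return cls(seed=seed, walk_duration_s=duration, walk_speed_mps=speed,
                   route=route, stressor_sites=tuple(sites), **overrides)


@dataclass
class TruthEvent:
    """Ground-truth annotation for one planted stress response."""

    onset_time: datetime
    onset_s: float           # seconds from trace start
    site_id: str
    lon: float
    lat: float


@dataclass
class ParticipantCampaign:
    trace: PhysioTrace
    track: GeoTrack
    diary: list[DiaryEntry]
    truth: list[TruthEvent]


def _route_geometry(cfg: ScenarioConfig):
    route = np.asarray(cfg.route, dtype=float)
    if route.ndim != 2 or len(route) < 2:
        raise ConfigError("route must be a polyline of >= 2 lon/lat points")
    crs = UtmCrs.for_points(route[:, 0], route[:, 1])
    x, y = crs.project(route[:, 0], route[:, 1])
    seg = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2)
    cumdist = np.concatenate(([0.0], np.cumsum(seg)))
    total = float(cumdist[-1])
    needed = cfg.walk_duration_s * cfg.walk_speed_mps
    if total < needed:
        raise ConfigError(
            f"route of {total:.0f} m shorter than walk distance {needed:.0f} m"
        )
    return crs, x, y, cumdist


def _position_at(dist, x, y, cumdist):
    px = np.interp(dist, cumdist, x)
    py = np.interp(dist, cumdist, y)
    return px, py


def _event_template_gsr(u: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    rise, amp, tau = cfg.rise_duration_s, cfg.rise_amplitude_us, cfg.decay_tau_s
    out = np.zeros_like(u)
    rising = (u >= 0) & (u < rise)
    out[rising] = amp * u[rising] / rise
    decaying = u >= rise
    out[decaying] = amp * np.exp(-(u[decaying] - rise) / tau)
    return out


def _event_template_st(u: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    lag, drop, dur, rec = (cfg.st_lag_s, cfg.st_drop_degc,
                           cfg.st_drop_duration_s, cfg.st_recovery_s)
    out = np.zeros_like(u)
    falling = (u >= lag) & (u < lag + dur)
    out[falling] = -drop * (u[falling] - lag) / dur
    recovering = (u >= lag + dur) & (u < lag + dur + rec)
    out[recovering] = -drop * (1 - (u[recovering] - lag - dur) / rec)
    return out


def _thin_deterministic(indices: Sequence[int], factor: float) -> list[int]:
    """Keep a fraction ``factor`` of events, evenly spread (Bresenham walk)."""
    kept = []
    for k, idx in enumerate(indices):
        if math.floor((k + 1) * factor) - math.floor(k * factor) == 1:
            kept.append(idx)
    return kept


def generate_participant(
    cfg: ScenarioConfig, participant_idx: int = 0
) -> ParticipantCampaign:
    """One participant's session: trace, track, diary, and ground truth."""
    rng = np.random.default_rng([cfg.seed, participant_idx])
    pid = f"p{participant_idx:03d}"
    start = BASE_START + timedelta(hours=participant_idx)
    crs, rx, ry, cumdist = _route_geometry(cfg)

    # --- GPS track -----------------------------------------------------------
    fix_t = np.arange(0.0, cfg.walk_duration_s + 1e-9, cfg.gps_fix_interval_s)
    fix_d = fix_t * cfg.walk_speed_mps
    fx, fy = _position_at(fix_d, rx, ry, cumdist)
    if cfg.gps_noise_m > 0:
        fx = fx + rng.normal(0, cfg.gps_noise_m, len(fx))
        fy = fy + rng.normal(0, cfg.gps_noise_m, len(fy))
    lon, lat = crs.unproject(fx, fy)
    track = GeoTrack(
        participant_id=pid,
        times=start.timestamp() + fix_t,
        lon=lon,
        lat=lat,
    )

    # --- stressor passages and planted events --------------------------------
    passages = []  # (passage_time_s, site)
    for site in cfg.stressor_sites:
        sx, sy = crs.project(site.lon, site.lat)
        d = np.sqrt((fx - sx) ** 2 + (fy - sy) ** 2)
        i = int(np.argmin(d))
        if d[i] <= site.radius_m:
            passages.append((float(fix_t[i]), site))
    passages.sort(key=lambda p: p[0])

    template_span = (cfg.rise_duration_s + cfg.st_lag_s
                     + cfg.st_drop_duration_s + cfg.st_recovery_s)
    candidates = []
    for t_pass, site in passages:
        if t_pass + template_span > cfg.walk_duration_s:
            continue
        if rng.random() <= site.event_probability:
            candidates.append((t_pass, site))
    kept = _thin_deterministic(range(len(candidates)), cfg.reduction_factor)
    planted = [candidates[i] for i in kept]

    # --- physiological trace --------------------------------------------------
    n = int(round(cfg.walk_duration_s * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs
    gsr = np.full(n, cfg.baseline_gsr_us)
    if cfg.tonic_drift_amp_us:
        gsr = gsr + cfg.tonic_drift_amp_us * np.sin(
            2 * np.pi * t / cfg.tonic_drift_period_s
        )
    st = np.full(n, cfg.baseline_st_degc)
    truth = []
    for onset_s, site in planted:
        u = t - onset_s
        gsr = gsr + _event_template_gsr(u, cfg)
        st = st + _event_template_st(u, cfg)
        elon, elat = crs.unproject(*_position_at(onset_s * cfg.walk_speed_mps,
                                                 rx, ry, cumdist))
        truth.append(TruthEvent(
            onset_time=start + timedelta(seconds=onset_s),
            onset_s=onset_s,
            site_id=site.site_id,
            lon=float(elon),
            lat=float(elat),
        ))
    if cfg.gsr_noise_sd_us > 0:
        gsr = gsr + rng.normal(0, cfg.gsr_noise_sd_us, n)
    if cfg.st_noise_sd_degc > 0:
        st = st + rng.normal(0, cfg.st_noise_sd_degc, n)
    trace = PhysioTrace(participant_id=pid, start_time=start, fs=cfg.fs,
                        gsr=gsr, st=st)

    # --- diary entries ---------------------------------------------------------
    diary = []
    for t_pass, site in passages:
        if rng.random() <= cfg.diary_report_probability:
            emotion = NEGATIVE_EMOTIONS[rng.integers(len(NEGATIVE_EMOTIONS))]
            trigger = TRIGGERS[rng.integers(len(TRIGGERS))]
            diary.append(DiaryEntry(
                participant_id=pid,
                timestamp=start + timedelta(seconds=t_pass),
                emotion=str(emotion),
                trigger=str(trigger),
                intensity=int(rng.integers(1, 6)),
                lon=site.lon,
                lat=site.lat,
            ))
    return ParticipantCampaign(trace=trace, track=track, diary=diary, truth=truth)


def generate_campaign(cfg: ScenarioConfig) -> list[ParticipantCampaign]:
    """All participants of a scenario; reproducible given the seed."""
    return [generate_participant(cfg, i) for i in range(cfg.n_participants)]


def write_campaign(campaign: list[ParticipantCampaign], directory: str | Path) -> Path:
    """Write a campaign in the same formats the ingest module reads."""
    directory = Path(directory)
    for p in campaign:
        pdir = directory / p.trace.participant_id
        pdir.mkdir(parents=True, exist_ok=True)
        io_ingest.write_physio(p.trace, pdir)
        io_ingest.write_track_gpx(p.track, pdir / "track.gpx")
        io_ingest.write_diary_csv(p.diary, pdir / "diary.csv")
        truth = [{
            "onset_time": ev.onset_time.isoformat(),
            "onset_s": ev.onset_s,
            "site_id": ev.site_id,
            "lon": ev.lon,
            "lat": ev.lat,
        } for ev in p.truth]
        (pdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return directory
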