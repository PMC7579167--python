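"""Time-based georeferencing against a GPS track.

Every data source in the pipeline carries an absolute timestamp, which is
the common key: a detected stress moment or a coordinate-less diary entry is
placed on the map by interpolating the participant's GPS track at its time.
Interpolation is linear in geographic coordinates — adequate at walking-scale
fix spacing — and positional uncertainty is surfaced through a confidence
flag rather than corrected: ``exact`` (time coincides with a fix),
``interpolated`` (between fixes at most ``max_gap_s`` apart) or ``low``
(bracketing fixes further apart than that).
"""

from __future__ import annotations

from dataclasses import replace
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import ContractError
from .types import DiaryEntry, GeoTrack, MosEvent, ensure_utc


def locate(
    time: datetime | float,
    track: GeoTrack,
    max_gap_s: float = 10.0,
) -> Optional[tuple[float, float, str]]:
    """Position at an instant, or ``None`` when the time lies outside the track."""
    if len(track) < 2:
        raise ContractError("track needs at least 2 fixes for interpolation")
    t = ensure_utc(time).timestamp() if isinstance(time, datetime) else float(time)
    times = track.times
    if t < times[0] or t > times[-1]:
        return None
    i = int(np.searchsorted(times, t))
    if i < len(times) and times[i] == t:
        return float(track.lon[i]), float(track.lat[i]), "exact"
    # strictly between fixes i-1 and i
    t0, t1 = times[i - 1], times[i]
    frac = (t - t0) / (t1 - t0)
    lon = track.lon[i - 1] + frac * (track.lon[i] - track.lon[i - 1])
    lat = track.lat[i - 1] + frac * (track.lat[i] - track.lat[i - 1])
    confidence = "interpolated" if (t1 - t0) <= max_gap_s else "low"
    return float(lon), float(lat), confidence


def locate_many(
    times_s: np.ndarray, track: GeoTrack, max_gap_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`locate` for epoch-second arrays.

    Returns ``(lon, lat, ok)``; positions are NaN where ``ok`` is False
    (outside the track span).
    """
    if len(track) < 2:
        raise ContractError("track needs at least 2 fixes for interpolation")
    t = np.asarray(times_s, dtype=float)
    ok = (t >= track.times[0]) & (t <= track.times[-1])
    lon = np.interp(t, track.times, track.lon)
    lat = np.interp(t, track.times, track.lat)
    lon[~ok] = np.nan
    lat[~ok] = np.nan
    return lon, lat, ok


def georeference_events(
    events: Iterable[MosEvent], track: GeoTrack, max_gap_s: float = 10.0
) -> list[MosEvent]:
    """Attach a location to each event; unlocatable events are kept, unlocated."""
    out = []
    for ev in events:
        hit = locate(ev.onset_time, track, max_gap_s)
        out.append(ev if hit is None else ev.with_location(*hit))
    return out


def georeference_diary(
    entries: Iterable[DiaryEntry], track: GeoTrack, max_gap_s: float = 10.0
) -> list[DiaryEntry]:
    """Resolve coordinates for entries flagged needs-georef; others pass through."""
    out = []
    for entry in entries:
        if not entry.needs_georef:
            out.append(entry)
            continue
        hit = locate(entry.timestamp, track, max_gap_s)
        if hit is None:
            out.append(entry)
        else:
            lon, lat, _ = hit
            out.append(replace(entry, lon=lon, lat=lat))
    return out
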