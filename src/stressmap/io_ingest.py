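"""Readers and writers for the field-campaign formats.

Supported inputs:

* **Empatica-style CSV** (``e4`` dialect) — one file per channel (``EDA.csv``,
  ``TEMP.csv``): line 1 is the UNIX start time, line 2 the sampling rate in
  Hz, remaining lines one sample each. ``read_physio`` accepts the directory
  holding the pair.
* **Generic timestamped CSV** — columns ``timestamp`` (ISO 8601 or epoch
  seconds), ``gsr`` (µS), ``st`` (°C).
* **GPX 1.1** tracks and **GeoJSON** (RFC 7946) tracks/diaries.
* **Diary CSV** — ``participant_id, timestamp, emotion, trigger, intensity``
  plus optional ``lon, lat``.

All timestamps are normalised to UTC on ingest; naive local times require an
explicit ``utc_offset_hours``. Both physiological channels are resampled to a
common uniform grid (default 4 Hz, the wristband's native EDA rate) by linear
interpolation, because the detection-rule windows are defined in seconds and
need a uniform time base. Acquisition gaps up to 2 s are linearly
interpolated and flagged; longer gaps split the recording into independently
processed segments so the rule template never straddles unmeasured spans.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, UnusableTrackError, ValidationError
from .types import DiaryEntry, GeoTrack, MosEvent, PhysioTrace

logger = logging.getLogger(__name__)

DEFAULT_FS = 4.0
MAX_INTERP_GAP_S = 2.0

_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


# ---------------------------------------------------------------------------
# timestamps

def _parse_timestamp(value, utc_offset_hours: float | None = None) -> datetime:
    """Parse an ISO-8601 string or epoch-seconds number into aware UTC."""
    if isinstance(value, (int, float)) or (
        isinstance(value, str) and value.replace(".", "", 1).lstrip("-").isdigit()
    ):
        return datetime.fromtimestamp(float(value), tz=timezone.utc)
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        if utc_offset_hours is None:
            raise ValidationError(
                f"naive timestamp {value!r}: declare utc_offset_hours explicitly"
            )
        ts = ts.replace(tzinfo=timezone.utc)
        ts = ts - pd.Timedelta(hours=utc_offset_hours)
    return ts.astimezone(timezone.utc)


# ---------------------------------------------------------------------------
# physiological traces

def _read_e4_channel(path: Path) -> tuple[float, float, np.ndarray]:
    """Parse one Empatica-style channel file -> (start_epoch, fs, values)."""
    try:
        lines = path.read_text().strip().splitlines()
        start = float(lines[0].split(",")[0])
        fs = float(lines[1].split(",")[0])
        values = np.array([float(v) for v in lines[2:]], dtype=float)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed Empatica-style header/body: {exc}") from exc
    if fs <= 0:
        raise FormatError(f"{path}: non-positive sampling rate {fs}")
    return start, fs, values


def _resample(values: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return values
    duration = (len(values) - 1) / fs_in
    t_in = np.arange(len(values)) / fs_in
    t_out = np.arange(0.0, duration + 0.5 / fs_out, 1.0 / fs_out)
    return np.interp(t_out, t_in, values)


def read_physio(
    path: str | Path,
    dialect: str = "e4",
    fs: float = DEFAULT_FS,
    participant_id: Optional[str] = None,
    utc_offset_hours: float | None = None,
) -> PhysioTrace:
    """Read one session's GSR+ST recording onto a uniform ``fs`` grid.

    For the ``e4`` dialect ``path`` is a directory containing ``EDA.csv`` and
    ``TEMP.csv``. For ``generic`` it is a single CSV; recordings with gaps
    longer than 2 s must go through :func:`read_physio_segments`.
    """
    path = Path(path)
    if dialect == "e4":
        return _read_physio_e4(path, fs, participant_id)
    if dialect == "generic":
        segments = read_physio_segments(
            path, dialect="generic", fs=fs, participant_id=participant_id,
            utc_offset_hours=utc_offset_hours,
        )
        if len(segments) != 1:
            raise ValidationError(
                f"{path}: recording splits into {len(segments)} segments at gaps "
                f"> {MAX_INTERP_GAP_S}s; use read_physio_segments"
            )
        return segments[0]
    raise FormatError(f"unknown physio dialect {dialect!r}")


def _read_physio_e4(path: Path, fs: float, participant_id: Optional[str]) -> PhysioTrace:
    eda_path, temp_path = path / "EDA.csv", path / "TEMP.csv"
    for p in (eda_path, temp_path):
        if not p.exists():
            raise FormatError(f"expected Empatica-style channel file {p}")
    start_g, fs_g, gsr = _read_e4_channel(eda_path)
    start_t, fs_t, st = _read_e4_channel(temp_path)
    if abs(start_g - start_t) > 1.0 / min(fs_g, fs_t):
        raise ValidationError(
            f"channel start times differ by {abs(start_g - start_t):.3f}s"
        )
    gsr = _resample(gsr, fs_g, fs)
    st = _resample(st, fs_t, fs)
    m = min(len(gsr), len(st))
    return PhysioTrace(
        participant_id=participant_id or path.name,
        start_time=datetime.fromtimestamp(start_g, tz=timezone.utc),
        fs=fs,
        gsr=gsr[:m],
        st=st[:m],
    )


def read_physio_segments(
    path: str | Path,
    dialect: str = "generic",
    fs: float = DEFAULT_FS,
    participant_id: Optional[str] = None,
    utc_offset_hours: float | None = None,
    max_interp_gap_s: float = MAX_INTERP_GAP_S,
) -> list[PhysioTrace]:
    """Generic-CSV reader returning one trace per contiguous segment."""
    path = Path(path)
    if dialect != "generic":
        return [read_physio(path, dialect=dialect, fs=fs, participant_id=participant_id)]
    df = pd.read_csv(path)
    required = {"timestamp", "gsr", "st"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: generic dialect needs columns {sorted(required)}")
    for col in ("gsr", "st"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: missing {col} value at row {int(bad[0]) + 2}"
            )
    times = np.array([
        _parse_timestamp(v, utc_offset_hours).timestamp() for v in df["timestamp"]
    ])
    if np.any(np.diff(times) <= 0):
        row = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise ValidationError(f"{path}: non-monotonic timestamps at row {row}")

    pid = participant_id or (
        str(df["participant_id"].iloc[0]) if "participant_id" in df.columns else path.stem
    )
    gsr = df["gsr"].to_numpy(dtype=float)
    st = df["st"].to_numpy(dtype=float)

    # split on long gaps, interpolate short ones onto the uniform grid
    gap_after = np.flatnonzero(np.diff(times) > max_interp_gap_s)
    bounds = np.concatenate(([0], gap_after + 1, [len(times)]))
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        seg = _segment_to_grid(pid, times[a:b], gsr[a:b], st[a:b], fs)
        segments.append(seg)
    if not segments:
        raise ValidationError(f"{path}: no segment with >= 2 samples")
    return segments


def _segment_to_grid(pid, times, gsr, st, fs) -> PhysioTrace:
    t0, t1 = times[0], times[-1]
    grid = np.arange(t0, t1 + 0.5 / fs, 1.0 / fs)
    gsr_u = np.interp(grid, times, gsr)
    st_u = np.interp(grid, times, st)
    # flag grid samples farther than one native step from any observed sample
    idx = np.searchsorted(times, grid).clip(1, len(times) - 1)
    nearest = np.minimum(np.abs(grid - times[idx - 1]), np.abs(times[idx] - grid))
    interpolated = nearest > 1.0 / fs
    return PhysioTrace(
        participant_id=pid,
        start_time=datetime.fromtimestamp(t0, tz=timezone.utc),
        fs=fs,
        gsr=gsr_u,
        st=st_u,
        interpolated=interpolated,
    )


def write_physio(trace: PhysioTrace, directory: str | Path) -> Path:
    """Write a trace as an Empatica-style channel pair; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    start = trace.start_time.timestamp()
    for name, values in (("EDA.csv", trace.gsr), ("TEMP.csv", trace.st)):
        with open(directory / name, "w") as fh:
            fh.write(f"{start:.6f}\n{trace.fs:.6f}\n")
            fh.writelines(f"{v:.6f}\n" for v in values)
    return directory


# ---------------------------------------------------------------------------
# GPS tracks

def read_track(path: str | Path, participant_id: Optional[str] = None) -> GeoTrack:
    """Read a GPX 1.1 or GeoJSON track with per-point times."""
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        fixes = _read_gpx(path)
    else:
        fixes = _read_geojson_track(path)
    if not fixes:
        raise UnusableTrackError(f"{path}: no timed points found")
    # collapse duplicate-time fixes to the last occurrence
    dedup: dict[float, tuple[float, float]] = {}
    for t, lon, lat in fixes:
        if t in dedup:
            logger.warning("%s: duplicate fix time %s collapsed to last", path, t)
        dedup[t] = (lon, lat)
    items = sorted(dedup.items())
    times = np.array([t for t, _ in items])
    lon = np.array([p[0] for _, p in items])
    lat = np.array([p[1] for _, p in items])
    if len(times) < 2:
        raise UnusableTrackError(f"{path}: need >= 2 fixes, got {len(times)}")
    return GeoTrack(participant_id=participant_id or path.stem,
                    times=times, lon=lon, lat=lat)


def _read_gpx(path: Path) -> list[tuple[float, float, float]]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: invalid XML: {exc}") from exc
    ns = _GPX_NS if root.tag.startswith("{") else ""
    fixes = []
    for trkpt in root.iter(f"{ns}trkpt"):
        time_el = trkpt.find(f"{ns}time")
        if time_el is None or not time_el.text:
            continue
        t = _parse_timestamp(time_el.text).timestamp()
        fixes.append((t, float(trkpt.get("lon")), float(trkpt.get("lat"))))
    if not fixes and any(True for _ in root.iter(f"{ns}trkpt")):
        raise UnusableTrackError(f"{path}: trackpoints carry no <time> elements")
    return fixes


def _read_geojson_track(path: Path) -> list[tuple[float, float, float]]:
    data = json.loads(Path(path).read_text())
    features = data.get("features", [data] if data.get("type") == "Feature" else [])
    fixes: list[tuple[float, float, float]] = []
    for feat in features:
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") == "Point":
            if "time" not in props:
                raise UnusableTrackError(f"{path}: Point feature without 'time' property")
            lon, lat = geom["coordinates"][:2]
            fixes.append((_parse_timestamp(props["time"]).timestamp(), lon, lat))
        elif geom.get("type") in ("LineString", "MultiPoint"):
            times = props.get("times")
            coords = geom["coordinates"]
            if not times or len(times) != len(coords):
                raise UnusableTrackError(
                    f"{path}: {geom['type']} needs a 'times' property matching its points"
                )
            for t, (lon, lat, *_rest) in zip(times, coords):
                fixes.append((_parse_timestamp(t).timestamp(), lon, lat))
    return fixes


def write_track_gpx(track: GeoTrack, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="stressmap" '
        'xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    for t, lon, lat in zip(track.times, track.lon, track.lat):
        iso = datetime.fromtimestamp(t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%fZ")
        lines.append(f'<trkpt lat="{lat:.8f}" lon="{lon:.8f}"><time>{iso}</time></trkpt>')
    lines += ["</trkseg></trk>", "</gpx>"]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# diary entries

_DIARY_COLUMNS = ("participant_id", "timestamp", "emotion", "trigger", "intensity")


def read_diary(
    path: str | Path,
    intensity_scale: tuple[int, int] = (1, 5),
    utc_offset_hours: float | None = None,
) -> list[DiaryEntry]:
    """Read diary entries from CSV or GeoJSON; vocabulary is validated."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_diary_geojson(path, intensity_scale)
    df = pd.read_csv(path)
    missing = set(_DIARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: diary CSV missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        lon = row.get("lon")
        lat = row.get("lat")
        has_coords = lon is not None and not pd.isna(lon)
        entries.append(DiaryEntry(
            participant_id=str(row["participant_id"]),
            timestamp=_parse_timestamp(row["timestamp"], utc_offset_hours),
            emotion=str(row["emotion"]),
            trigger=str(row["trigger"]),
            intensity=int(row["intensity"]),
            lon=float(lon) if has_coords else None,
            lat=float(lat) if has_coords else None,
            intensity_scale=intensity_scale,
        ))
    return entries


def _read_diary_geojson(path: Path, intensity_scale) -> list[DiaryEntry]:
    data = json.loads(path.read_text())
    entries = []
    for feat in data.get("features", []):
        props = feat.get("properties") or {}
        geom = feat.get("geometry")
        lon = lat = None
        if geom and geom.get("type") == "Point":
            lon, lat = geom["coordinates"][:2]
        entries.append(DiaryEntry(
            participant_id=str(props["participant_id"]),
            timestamp=_parse_timestamp(props["timestamp"]),
            emotion=props["emotion"],
            trigger=props["trigger"],
            intensity=int(props["intensity"]),
            lon=lon,
            lat=lat,
            intensity_scale=intensity_scale,
        ))
    return entries


def write_diary_csv(entries: Sequence[DiaryEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_DIARY_COLUMNS) + ["lon", "lat"])
        for e in entries:
            writer.writerow([
                e.participant_id,
                e.timestamp.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00"),
                e.emotion,
                e.trigger,
                e.intensity,
                "" if e.lon is None else f"{e.lon:.8f}",
                "" if e.lat is None else f"{e.lat:.8f}",
            ])
    return path


# ---------------------------------------------------------------------------
# event export

def events_to_dataframe(events: Iterable[MosEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "participant_id": e.participant_id,
            "onset_time": e.onset_time.isoformat(),
            "window_end_time": e.window_end_time.isoformat(),
            "gsr_slope_deg": e.gsr_slope_deg,
            "gsr_delta_us": e.gsr_delta_us,
            "st_max_time": e.st_max_time.isoformat(),
            "st_min_time": e.st_min_time.isoformat(),
            "lon": e.lon,
            "lat": e.lat,
            "georef_confidence": e.georef_confidence,
        })
    return pd.DataFrame(rows)


def write_events_csv(events: Iterable[MosEvent], path: str | Path) -> Path:
    path = Path(path)
    events_to_dataframe(events).to_csv(path, index=False)
    return path


def events_to_geojson(events: Iterable[MosEvent]) -> dict:
    """Located events as a GeoJSON FeatureCollection of Points."""
    features = []
    for e in events:
        if not e.located:
            continue
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [e.lon, e.lat]},
            "properties": {
                "participant_id": e.participant_id,
                "onset_time": e.onset_time.isoformat(),
                "window_end_time": e.window_end_time.isoformat(),
                "gsr_slope_deg": e.gsr_slope_deg,
                "gsr_delta_us": e.gsr_delta_us,
                "st_max_time": e.st_max_time.isoformat(),
                "st_min_time": e.st_min_time.isoformat(),
                "georef_confidence": e.georef_confidence,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_events_geojson(events: Iterable[MosEvent], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(events_to_geojson(events), indent=1))
    return path
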