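"""Core domain types.

The pipeline couples three georeferenced data sources on a shared absolute
(UTC) time axis: uniformly sampled wearable physiology (skin conductance in
microsiemens and skin temperature in degrees Celsius), a GPS track, and
momentary self-reports ("diary entries") of perceived emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError

#: Closed vocabulary of emotion qualities a diary entry may carry.
EMOTIONS = ("happiness", "anger/disgust", "sadness", "fear")

#: Closed vocabulary of trigger (context/cause) categories.
TRIGGERS = (
    "cars",
    "bicycles",
    "green space",
    "people",
    "sights",
    "cityscape",
    "weather",
    "intersections",
)

#: Emotions counted as negative valence when splitting diary entries for maps.
NEGATIVE_EMOTIONS = ("anger/disgust", "sadness", "fear")
POSITIVE_EMOTIONS = ("happiness",)

#: Plausibility gates for raw samples. Out-of-range samples are flagged,
#: never dropped: a wrong-unit channel (e.g. conductance in nS) shows up as
#: a fully flagged trace rather than silently corrupt rates downstream.
ST_PLAUSIBLE_RANGE_C = (15.0, 45.0)
#: Conductance below 0 is physically impossible; above 100 µS it is far
#: outside the wearable-EDA range and almost certainly a unit error (nS).
GSR_PLAUSIBLE_RANGE_US = (0.0, 100.0)


def ensure_utc(ts: datetime) -> datetime:
    """Return ``ts`` as an aware UTC datetime; naive input is rejected."""
    if ts.tzinfo is None:
        raise ValidationError(f"naive timestamp {ts!r}; all times must be UTC-aware")
    return ts.astimezone(timezone.utc)


@dataclass
class PhysioTrace:
    """Uniformly sampled GSR + skin-temperature series for one session.

    Sample *i* is taken at ``start_time + i / fs``. ``quality_gsr`` /
    ``quality_st`` flag samples outside the plausibility gates and
    ``interpolated`` flags samples filled over short acquisition gaps.
    """

    participant_id: str
    start_time: datetime
    fs: float
    gsr: np.ndarray
    st: np.ndarray
    quality_gsr: np.ndarray = field(default=None)  # type: ignore[assignment]
    quality_st: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start_time = ensure_utc(self.start_time)
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        self.gsr = np.asarray(self.gsr, dtype=float)
        self.st = np.asarray(self.st, dtype=float)
        if self.gsr.shape != self.st.shape or self.gsr.ndim != 1:
            raise ValidationError(
                f"gsr and st must be 1-D and equally long, got {self.gsr.shape} vs {self.st.shape}"
            )
        if self.quality_gsr is None:
            glo, ghi = GSR_PLAUSIBLE_RANGE_US
            self.quality_gsr = (self.gsr >= glo) & (self.gsr <= ghi)
        if self.quality_st is None:
            lo, hi = ST_PLAUSIBLE_RANGE_C
            self.quality_st = (self.st >= lo) & (self.st <= hi)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.gsr), dtype=bool)

    def __len__(self) -> int:
        return len(self.gsr)

    @property
    def duration_s(self) -> float:
        return len(self.gsr) / self.fs

    def times(self) -> np.ndarray:
        """Seconds since epoch for each sample (strictly increasing)."""
        t0 = self.start_time.timestamp()
        return t0 + np.arange(len(self.gsr)) / self.fs

    def time_at(self, index: float) -> datetime:
        return datetime.fromtimestamp(
            self.start_time.timestamp() + index / self.fs, tz=timezone.utc
        )


@dataclass
class FilteredTrace(PhysioTrace):
    """A :class:`PhysioTrace` with derived filtered channels.

    ``gsr_phasic`` is the conductance after low-pass (technical noise) then
    high-pass (tonic baseline removal); ``st_smooth`` is low-passed skin
    temperature on the same time base.
    """

    gsr_phasic: np.ndarray = field(default=None)  # type: ignore[assignment]
    st_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.gsr_phasic is None or self.st_smooth is None:
            raise ValidationError("FilteredTrace requires gsr_phasic and st_smooth")
        self.gsr_phasic = np.asarray(self.gsr_phasic, dtype=float)
        self.st_smooth = np.asarray(self.st_smooth, dtype=float)
        if len(self.gsr_phasic) != len(self.gsr) or len(self.st_smooth) != len(self.gsr):
            raise ValidationError("filtered channels must match the parent time base")


@dataclass
class GeoTrack:
    """Timestamped GPS fixes for one session.

    ``times`` are seconds since the Unix epoch (UTC); ``lon``/``lat`` in
    degrees; ``accuracy_m`` optional horizontal accuracy.
    """

    participant_id: str
    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    accuracy_m: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.times) == len(self.lon) == len(self.lat)):
            raise ValidationError("track arrays must be equally long")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("track timestamps must be strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValidationError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DiaryEntry:
    """One momentary self-report: emotion quality, trigger, intensity.

    Entries without coordinates carry ``needs_georef=True`` and are resolved
    against the participant's GPS track later.
    """

    participant_id: str
    timestamp: datetime
    emotion: str
    trigger: str
    intensity: int
    lon: Optional[float] = None
    lat: Optional[float] = None
    intensity_scale: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        self.timestamp = ensure_utc(self.timestamp)
        if self.emotion not in EMOTIONS:
            raise ValidationError(
                f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}"
            )
        if self.trigger not in TRIGGERS:
            raise ValidationError(
                f"unknown trigger {self.trigger!r}; expected one of {TRIGGERS}"
            )
        lo, hi = self.intensity_scale
        if not (lo <= int(self.intensity) <= hi):
            raise ValidationError(
                f"intensity {self.intensity} outside scale [{lo}, {hi}]"
            )
        self.intensity = int(self.intensity)
        if (self.lon is None) != (self.lat is None):
            raise ValidationError("lon and lat must be given together or not at all")

    @property
    def needs_georef(self) -> bool:
        return self.lon is None

    @property
    def valence(self) -> str:
        return "positive" if self.emotion in POSITIVE_EMOTIONS else "negative"


@dataclass
class MosEvent:
    """One detected moment of stress (MOS).

    The rule fires on a sustained conductance rise with sufficient slope,
    followed (after a fixed lag) by a skin-temperature maximum and subsequent
    minimum. Times are UTC; ``location`` is set by georeferencing.
    """

    participant_id: str
    onset_time: datetime
    window_end_time: datetime
    gsr_slope_deg: float
    gsr_delta_us: float
    st_max_time: datetime
    st_min_time: datetime
    lon: Optional[float] = None
    lat: Optional[float] = None
    georef_confidence: Optional[str] = None  # exact | interpolated | low

    def __post_init__(self) -> None:
        self.onset_time = ensure_utc(self.onset_time)
        self.window_end_time = ensure_utc(self.window_end_time)
        self.st_max_time = ensure_utc(self.st_max_time)
        self.st_min_time = ensure_utc(self.st_min_time)
        if not self.onset_time < self.window_end_time:
            raise ValidationError("onset_time must precede window_end_time")
        if not self.st_max_time < self.st_min_time:
            raise ValidationError("st_max_time must precede st_min_time")

    @property
    def located(self) -> bool:
        return self.lon is not None

    def with_location(self, lon: float, lat: float, confidence: str) -> "MosEvent":
        return replace(self, lon=lon, lat=lat, georef_confidence=confidence)


def sort_events(events: Sequence[MosEvent]) -> list[MosEvent]:
    return sorted(events, key=lambda e: e.onset_time)
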