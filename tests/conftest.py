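from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from stressmap import FilteredTrace, GeoTrack

T0 = datetime(2018, 9, 5, 9, 0, tzinfo=timezone.utc)
FS = 4.0


def make_filtered(gsr_phasic, st_smooth, fs: float = FS,
                  participant_id: str = "p000") -> FilteredTrace:
    """Build a FilteredTrace directly from already 'filtered' channels."""
    gsr_phasic = np.asarray(gsr_phasic, dtype=float)
    st_smooth = np.asarray(st_smooth, dtype=float)
    return FilteredTrace(
        participant_id=participant_id,
        start_time=T0,
        fs=fs,
        gsr=gsr_phasic.copy(),
        st=st_smooth.copy(),
        gsr_phasic=gsr_phasic,
        st_smooth=st_smooth,
    )


@pytest.fixture
def straight_track() -> GeoTrack:
    """10 fixes, 10 s apart, walking east along a straight segment."""
    t0 = T0.timestamp()
    times = t0 + np.arange(10) * 10.0
    lon = 13.0400 + np.arange(10) * 0.0010
    lat = 47.8000 + np.arange(10) * 0.0010
    return GeoTrack(participant_id="p000", times=times, lon=lon, lat=lat)
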