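"""Signal conditioning for wearable GSR / skin-temperature channels.

Two zero-phase Butterworth stages separate the event-related signal from
nuisance components:

* a low-pass at 0.5 Hz removes high-frequency technical noise (sensor
  artefacts, quantisation chatter);
* a high-pass at 0.05 Hz removes the tonic conductance component, each
  participant's slowly drifting baseline, leaving the phasic channel the
  stress rule inspects.

Both stages run forward-backward (:func:`scipy.signal.filtfilt`) so event
timing is not shifted: a zero-phase filter leaves the temporal location of
rises and drops intact, which matters because detection and georeferencing
are time-critical. Skin temperature receives the low-pass only — the rule
looks at ST extrema in absolute terms, so its baseline must be preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .exceptions import ConfigError, TooShortError
from .types import FilteredTrace, PhysioTrace


@dataclass(frozen=True)
class PreprocessConfig:
    lowpass_cutoff_hz: float = 0.5
    highpass_cutoff_hz: float = 0.05
    filter_order: int = 2
    filter_family: str = "butterworth"

    def validate(self, fs: float) -> None:
        if not (0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz < fs / 2):
            raise ConfigError(
                "need 0 < highpass_cutoff_hz < lowpass_cutoff_hz < fs/2, got "
                f"hp={self.highpass_cutoff_hz}, lp={self.lowpass_cutoff_hz}, fs={fs}"
            )
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.filter_family.lower() != "butterworth":
            raise ConfigError(f"unsupported filter family {self.filter_family!r}")


def _design(cutoff_hz: float, fs: float, order: int, btype: str):
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs)


def _apply_zero_phase(b, a, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    # filtfilt needs padding room; require 3x the default pad length
    padlen = 3 * max(len(a), len(b))
    if len(x) <= 3 * padlen:
        raise TooShortError(
            f"series of {len(x)} samples is too short for zero-phase filtering "
            f"(need > {3 * padlen})"
        )
    return signal.filtfilt(b, a, x, padlen=padlen)


def lowpass(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase low-pass; output has the same length and time base as input."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    b, a = _design(cfg.lowpass_cutoff_hz, fs, cfg.filter_order, "lowpass")
    return _apply_zero_phase(b, a, x)


def highpass_tonic_removal(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase high-pass removing the tonic (baseline) component."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    b, a = _design(cfg.highpass_cutoff_hz, fs, cfg.filter_order, "highpass")
    return _apply_zero_phase(b, a, x)


def zero_phase_gain(cutoff_hz: float, fs: float, order: int, btype: str,
                    freq_hz: np.ndarray | float) -> np.ndarray:
    """Exact steady-state magnitude response of the zero-phase filter.

    Forward-backward filtering applies the digital filter twice, so the
    effective gain at frequency f is |H(e^{j 2 pi f / fs})|^2.
    """
    b, a = _design(cutoff_hz, fs, order, btype)
    w = 2 * np.pi * np.atleast_1d(np.asarray(freq_hz, dtype=float)) / fs
    _, h = signal.freqz(b, a, worN=w)
    return np.abs(h) ** 2


def preprocess(trace: PhysioTrace, cfg: PreprocessConfig | None = None) -> FilteredTrace:
    """Derive the phasic GSR and smoothed ST channels from a raw trace."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(trace.fs)
    gsr_denoised = lowpass(trace.gsr, trace.fs, cfg)
    gsr_phasic = highpass_tonic_removal(gsr_denoised, trace.fs, cfg)
    st_smooth = lowpass(trace.st, trace.fs, cfg)
    return FilteredTrace(
        participant_id=trace.participant_id,
        start_time=trace.start_time,
        fs=trace.fs,
        gsr=trace.gsr,
        st=trace.st,
        quality_gsr=trace.quality_gsr,
        quality_st=trace.quality_st,
        interpolated=trace.interpolated,
        gsr_phasic=gsr_phasic,
        st_smooth=st_smooth,
    )
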