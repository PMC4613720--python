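"""Signal conditioning: anti-alias low-pass filtering and decimation.

The neck sensor samples at 2205 Hz, which heavily oversamples heart sounds
(their energy at the suprasternal notch sits below ~25 Hz).  The pipeline
therefore low-pass filters at 100 Hz and decimates by 10, yielding the
220.5 Hz signal every later stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class RawRecording:
    """A sampled single-channel acoustic recording.

    Parameters
    ----------
    samples : array-like of float
        Amplitude samples (normalized amplitude or ADC counts).
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class ConditionedSignal:
    """Band-limited, decimated signal (nominally 220.5 Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def lowpass_filter(rec: RawRecording, cutoff_hz: float = 100.0,
                   order: int = 8) -> RawRecording:
    """Anti-alias low-pass filter (8th-order Butterworth, zero-phase).

    The filter is applied forward-backward so heart-sound event times are
    not phase-shifted; downstream classification depends on event timing,
    and offline processing permits non-causal filtering.  ``order`` is the
    design order of the underlying Butterworth section.
    """
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rec.fs / 2} Hz)")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return RawRecording(filtered, rec.fs, rec.start_time)


def downsample(rec: RawRecording, factor: int = 10) -> ConditionedSignal:
    """Decimate an (already band-limited) recording by ``factor``.

    Keeps every ``factor``-th sample starting at index 0, so output sample
    ``k`` equals input sample ``k * factor`` and the output length is
    ``ceil(n / factor)``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsample factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    return ConditionedSignal(rec.samples[::factor].copy(), rec.fs / factor)


def condition(rec: RawRecording, cutoff_hz: float = 100.0, order: int = 8,
              factor: int = 10) -> ConditionedSignal:
    """Low-pass filter then decimate: the standard front end."""
    return downsample(lowpass_filter(rec, cutoff_hz, order), factor)
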