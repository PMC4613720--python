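"""Heartbeat merging and windowed heart-rate computation.

Each labelled S1 anchors one heartbeat; an S2 following it belongs to the
same beat and contributes no event of its own, and DK segments are ignored.
Heart rate over a window is the number of inter-beat intervals whose both
endpoints fall inside the window, divided by the window length:

    hr = intervals / time(s) * 60     [bpm]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .segmenter import S1, PeakSegment

#: windows flagged as anything but "ok" carry no trustworthy estimate
FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_IMPLAUSIBLE = "implausible"

#: sanity cap for reported rates (flagged, never clipped)
HR_SANITY_MAX = 300.0


@dataclass
class BeatSeries:
    """Strictly increasing heartbeat times (seconds), anchored at S1."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass
class HRSeries:
    """Per-window heart-rate estimates (NaN where a window had < 2 beats)."""

    window_start: np.ndarray
    hr: np.ndarray
    flag: list[str]
    window_len: float = 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start_s": self.window_start,
            "hr_bpm": self.hr,
            "flag": self.flag,
        })


def merge_beats(segments: list[PeakSegment]) -> BeatSeries:
    """Collapse labelled segments into one event per heartbeat.

    Every S1 yields a beat at its segment time; S2s are absorbed into the
    preceding S1 (or dropped when orphaned) and DKs are ignored, so the
    result is simply the ordered S1 times.
    """
    return BeatSeries(np.array([s.st for s in segments if s.label == S1]))


def compute_hr(beats: BeatSeries, window_len: float = 60.0,
               hop: Optional[float] = None, t_start: float = 0.0,
               t_end: Optional[float] = None) -> HRSeries:
    """Windowed heart rate from a beat series.

    Windows tile (default) or slide from ``t_start``; a window with fewer
    than two beats yields NaN flagged ``"missing"`` rather than zero.
    ``t_end`` defaults to the last beat time; only windows fully inside
    ``[t_start, t_end]`` are evaluated.
    """
    if not window_len > 0:
        raise ValueError("window length must be positive")
    hop = window_len if hop is None else hop
    if not hop > 0:
        raise ValueError("hop must be positive")
    bt = beats.beat_times
    if t_end is None:
        t_end = float(bt[-1]) if bt.size else t_start
    starts, rates, flags = [], [], []
    w = t_start
    while w + window_len <= t_end + 1e-9:
        # closed window: a beat on the boundary can terminate an interval
        # in one window and start one in the next
        inside = bt[(bt >= w) & (bt <= w + window_len)]
        starts.append(w)
        if inside.size < 2:
            rates.append(np.nan)
            flags.append(FLAG_MISSING)
        else:
            hr = (inside.size - 1) / window_len * 60.0
            rates.append(hr)
            flags.append(FLAG_OK if hr <= HR_SANITY_MAX else FLAG_IMPLAUSIBLE)
        w += hop
    return HRSeries(np.array(starts), np.array(rates), flags, window_len)
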