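"""Reading recordings and writing pipeline outputs.

Input formats: WAV (PCM 16-bit or float, rate from the header) and
single-column CSV with a ``sample`` header (rate must be supplied).
Integer WAV samples are mapped to [-1, 1) by the PCM full scale; integer
CSV samples are treated as raw 10-bit ADC counts and divided by 2^9.
All downstream constants are scale-free, so normalization only fixes a
convenient unit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .heartrate import BeatSeries, HRSeries
from .preprocess import RawRecording
from .segmenter import PeakSegment

PathLike = Union[str, Path]


def read_recording(path: PathLike, fs: Optional[float] = None) -> RawRecording:
    """Load a recording from WAV or CSV.

    ``fs`` is required for CSV and overrides the WAV header if given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("multi-channel audio is not supported")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(2 ** (8 * data.dtype.itemsize - 1))
        else:
            data = data.astype(float)
        return RawRecording(data, fs if fs is not None else float(rate))
    if path.suffix.lower() == ".csv":
        if fs is None:
            raise ValueError("sampling rate is required for CSV input")
        df = pd.read_csv(path)
        if "sample" not in df.columns:
            raise ValueError("CSV input needs a 'sample' column")
        col = df["sample"]
        data = col.to_numpy(dtype=float)
        if pd.api.types.is_integer_dtype(col):
            data = data / 2.0 ** 9  # raw 10-bit ADC counts
        return RawRecording(data, fs)
    raise ValueError(f"unsupported input format: {path.suffix!r}")


def write_recording_wav(path: PathLike, rec: RawRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    scaled = np.clip(rec.samples, -1.0, 1.0 - 2.0 ** -15)
    wavfile.write(Path(path), int(round(rec.fs)),
                  np.round(scaled * 2 ** 15).astype(np.int16))


def write_beats_csv(path: PathLike, beats: BeatSeries) -> None:
    pd.DataFrame({"beat_time_s": beats.beat_times}).to_csv(path, index=False)


def write_hr_csv(path: PathLike, hr: HRSeries) -> None:
    hr.to_frame().to_csv(path, index=False)


def read_hr_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"window_start_s", "hr_bpm"} - set(df.columns)
    if missing:
        raise ValueError(f"HR CSV {path} lacks columns: {sorted(missing)}")
    return df


def read_reference_csv(path: PathLike) -> pd.DataFrame:
    """Reference series: columns ``time_s`` and ``hr_bpm`` (any rate)."""
    df = pd.read_csv(path)
    missing = {"time_s", "hr_bpm"} - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV {path} lacks columns: {sorted(missing)}")
    return df


def write_segments_csv(path: PathLike, segments: list[PeakSegment]) -> None:
    pd.DataFrame(
        [(s.t_start, s.t_end, s.st, s.peakamp, s.label) for s in segments],
        columns=["t_start", "t_end", "st", "peakamp", "label"],
    ).to_csv(path, index=False)


def write_classification_log(path: PathLike, log: list[dict]) -> None:
    """One JSON object per classification decision (JSON lines)."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")


def write_envelope_csv(path: PathLike, env) -> None:
    t = np.arange(env.samples.size) / env.fs
    pd.DataFrame({"time_s": t, "envelope": env.samples}).to_csv(path, index=False)


def write_truth_csv(path: PathLike, truth) -> None:
    n = max(truth.beat_times.size, truth.s2_times.size)
    df = pd.DataFrame({
        "beat_time_s": np.pad(truth.beat_times.astype(float),
                              (0, n - truth.beat_times.size),
                              constant_values=np.nan),
        "s2_time_s": np.pad(truth.s2_times.astype(float),
                            (0, n - truth.s2_times.size),
                            constant_values=np.nan),
    })
    df.to_csv(path, index=False)


def write_artefacts_csv(path: PathLike, truth) -> None:
    pd.DataFrame(truth.artefact_intervals,
                 columns=["start_s", "end_s"]).to_csv(path, index=False)
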