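"""Evaluation of estimated heart rate against a reference series.

The reference (a pulse oximeter or PSG pulse channel, typically sampled at
1 or 4 Hz) is averaged over each 60 s estimation window, then paired with
the algorithm's window estimates.  Three summaries characterize agreement:

* the percentage of windows within a relative error margin (default 10%
  of the reference),
* bias and sample SD of the per-window difference (estimate - reference),
* quartiles of the difference distribution.

Windows where the algorithm reported no rate are excluded from all
denominators and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HRComparison:
    """Aligned (estimate, reference) pairs per window."""

    pairs: pd.DataFrame          # columns: window_start_s, est_bpm, ref_bpm
    n_unmatched: int = 0         # estimate windows without reference cover
    n_missing: int = 0           # windows where the estimate was missing

    @property
    def differences(self) -> np.ndarray:
        return (self.pairs["est_bpm"] - self.pairs["ref_bpm"]).to_numpy()

    def __len__(self) -> int:
        return len(self.pairs)


def align_windows(est: pd.DataFrame, ref_times: np.ndarray,
                  ref_bpm: np.ndarray, window_len: float = 60.0,
                  ) -> HRComparison:
    """Average a dense reference series over each estimation window.

    ``est`` needs columns ``window_start_s`` and ``hr_bpm`` (NaN = missing).
    Reference samples with timestamps in ``[start, start + window_len)``
    are averaged; windows without any reference sample are dropped and
    counted as unmatched.
    """
    ref_times = np.asarray(ref_times, dtype=float)
    ref_bpm = np.asarray(ref_bpm, dtype=float)
    rows, n_unmatched, n_missing = [], 0, 0
    for start, hr in zip(est["window_start_s"], est["hr_bpm"]):
        if np.isnan(hr):
            n_missing += 1
            continue
        sel = (ref_times >= start) & (ref_times < start + window_len)
        if not np.any(sel):
            n_unmatched += 1
            continue
        rows.append((start, hr, float(np.mean(ref_bpm[sel]))))
    pairs = pd.DataFrame(rows, columns=["window_start_s", "est_bpm", "ref_bpm"])
    return HRComparison(pairs, n_unmatched=n_unmatched, n_missing=n_missing)


def accuracy_within_margin(cmp: HRComparison, margin: float = 0.10) -> float:
    """Percentage of windows with |est - ref| <= margin * ref."""
    if len(cmp) < 1:
        raise ValueError("no matched windows to evaluate")
    est = cmp.pairs["est_bpm"].to_numpy()
    ref = cmp.pairs["ref_bpm"].to_numpy()
    ok = np.abs(est - ref) <= margin * ref
    return 100.0 * float(np.count_nonzero(ok)) / len(cmp)


def bias_sd(cmp: HRComparison) -> tuple[float, float]:
    """Mean and sample SD of (estimate - reference) in bpm."""
    if len(cmp) < 2:
        raise ValueError("need at least 2 matched windows for bias/SD")
    d = cmp.differences
    return float(np.mean(d)), float(np.std(d, ddof=1))


def difference_quartiles(cmp: HRComparison) -> tuple[float, float, float]:
    """Q1, median and Q3 of the difference spread (linear interpolation)."""
    if len(cmp) < 4:
        raise ValueError("need at least 4 matched windows for quartiles")
    q1, med, q3 = np.percentile(cmp.differences, [25, 50, 75],
                                method="linear")
    return float(q1), float(med), float(q3)


def summary(cmp: HRComparison, margin: float = 0.10) -> dict:
    """All metrics in one dict (for reports and the CLI)."""
    bias, sd = bias_sd(cmp)
    q1, med, q3 = difference_quartiles(cmp)
    return {
        "n_windows": len(cmp),
        "n_missing": cmp.n_missing,
        "n_unmatched": cmp.n_unmatched,
        "accuracy_pct": accuracy_within_margin(cmp, margin),
        "bias_bpm": bias,
        "sd_bpm": sd,
        "q1_bpm": q1,
        "median_bpm": med,
        "q3_bpm": q3,
    }
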