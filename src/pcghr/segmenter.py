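"""Dynamic-threshold segmentation of the transient envelope.

Supra-threshold runs of the (absolute) post-high-pass envelope are grouped
into candidate heart-sound segments: runs separated by less than 100 ms are
merged, segments longer than 200 ms are discarded as artefacts (loud
breathing, snoring, speech), and the detection threshold is updated toward
a fraction of the peak amplitude each time a segment is accepted as a heart
sound:

    thr_new = c1 * thr_old + c2 * r1 * peakamp,   c1=0.9, c2=0.1, r1=1/3

so under a steady peak amplitude ``p`` the threshold settles at ``p/3``.
If the envelope stays entirely above or entirely below the threshold for
longer than five expected heart cycles (5 * D2), the threshold is reset to
its initial value; the reset clock restarts on every threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Union

import numpy as np

from .envelope import TransientEnvelope

#: Segment labels.
S1, S2, DK = "S1", "S2", "DK"


@dataclass
class ThresholdState:
    """Dynamic detection-threshold state."""

    thr: float
    thr_init: float
    c1: float = 0.9
    c2: float = 0.1
    r1: float = 1.0 / 3.0
    last_reset_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.thr > 0:
            raise ValueError(f"threshold must be positive, got {self.thr}")
        if not np.isclose(self.c1 + self.c2, 1.0):
            raise ValueError("threshold weights must satisfy c1 + c2 = 1")
        if not 0 < self.r1 <= 1:
            raise ValueError("peak-amplitude ratio r1 must be in (0, 1]")


@dataclass
class PeakSegment:
    """One candidate heart-sound event.

    ``st`` (segment time) is the time of the maximum envelope sample within
    the segment — the most stable landmark for inter-beat intervals.
    """

    t_start: float
    t_end: float
    st: float
    peakamp: float
    label: str = DK

    def __post_init__(self) -> None:
        if not self.t_start <= self.st <= self.t_end:
            raise ValueError("segment time must lie within [t_start, t_end]")
        if not self.peakamp > 0:
            raise ValueError("peak amplitude must be positive")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def update_threshold(state: ThresholdState, peakamp: float) -> ThresholdState:
    """One detection-threshold update after an S1/S2 classification."""
    if not peakamp > 0:
        raise ValueError(f"peak amplitude must be positive, got {peakamp}")
    new_thr = state.c1 * state.thr + state.c2 * state.r1 * peakamp
    return replace(state, thr=new_thr)


def init_threshold(env: TransientEnvelope, factor: float = 3.0,
                   head_s: float = 10.0, block_s: float = 1.0,
                   **kwargs) -> ThresholdState:
    """Initial threshold from the opening of the recording.

    The absolute post-high-pass envelope over the first ``head_s`` seconds
    is split into ``block_s`` blocks; the median of the per-block maxima
    estimates a typical heart-sound peak amplitude (nearly every block
    contains a heart sound, and the median ignores a minority of blocks
    inflated by artefacts or deflated by pauses).  The threshold starts at
    ``1/factor`` of that estimate, matching the update rule's fixed point
    ``thr* = peakamp / 3`` for the default ``factor = 3``.  Scale-free; a
    noise-floor statistic (e.g. a multiple of the median sample) would sit
    inside the heavy upper tail of the squared envelope's noise
    distribution and drown detection in merged noise runs.
    """
    head = np.abs(env.samples[: max(1, int(head_s * env.fs))])
    nb = max(1, int(block_s * env.fs))
    maxima = [head[i:i + nb].max() for i in range(0, head.size, nb)]
    thr = float(np.median(maxima)) / factor
    if thr <= 0:  # degenerate (e.g. silent lead-in): fall back to the mean
        thr = float(np.mean(head)) / factor
    if thr <= 0:
        raise ValueError("cannot initialize threshold on an all-zero envelope")
    return ThresholdState(thr=thr, thr_init=thr, **kwargs)


def detect_segments(
    env: TransientEnvelope,
    state: ThresholdState,
    gap_ms: float = 100.0,
    d2: Union[float, Callable[[], float]] = 0.87,
    max_seg_ms: float = 200.0,
    edge_s: float = 0.5,
    classify: Optional[Callable[[PeakSegment], str]] = None,
    events: Optional[list] = None,
) -> tuple[list[PeakSegment], ThresholdState]:
    """Scan the envelope and emit ordered candidate segments.

    Parameters
    ----------
    env : TransientEnvelope
        Post-high-pass track; detection runs on its absolute value.
    state : ThresholdState
        Starting threshold state (not mutated; the final state is returned).
    gap_ms : float
        Supra-threshold runs separated by less than this are one segment.
    d2 : float or callable
        Current heart-period estimate (seconds) for the 5*D2 reset clock;
        a callable is polled so the classifier's running estimate can be
        used while detection proceeds.
    max_seg_ms : float
        Segments longer than this are discarded as artefacts.
    edge_s : float
        Envelope margin excluded at both ends (filter edge effects).
    classify : callable, optional
        Invoked with each finalized segment; if it labels the segment (or,
        via pattern relabelling, earlier buffered segments) S1 or S2, the
        threshold is updated once per newly labelled segment.  When the
        callable exposes ``newly_labelled`` segments after the call (as the
        pipeline's classifier adapter does), those drive the update;
        otherwise the returned label alone does.
    events : list, optional
        Appended with ``("reset", time)`` tuples when the threshold resets.

    Returns
    -------
    (segments, final_state)
    """
    x = np.abs(env.samples)
    fs = env.fs
    n = x.size
    gap_n = int(round(gap_ms / 1000.0 * fs))
    max_seg_s = max_seg_ms / 1000.0
    d2_fn = d2 if callable(d2) else (lambda: d2)

    i0 = min(int(edge_s * fs), n)
    i1 = max(n - int(edge_s * fs), i0)

    thr = state.thr
    segments: list[PeakSegment] = []
    last_cross = i0
    run_start: Optional[int] = None
    pend_runs: list[tuple[int, int]] = []  # (start, end) inclusive
    above_prev: Optional[bool] = None

    def finalize() -> None:
        nonlocal thr, pend_runs
        s, e = pend_runs[0][0], pend_runs[-1][1]
        pend_runs = []
        t_start, t_end = s / fs, e / fs
        if t_end - t_start > max_seg_s:
            if events is not None:
                events.append(("artefact_discarded", t_start))
            return
        peak_idx = s + int(np.argmax(x[s : e + 1]))
        seg = PeakSegment(t_start=t_start, t_end=t_end, st=peak_idx / fs,
                          peakamp=float(x[peak_idx]))
        if classify is not None:
            seg.label = classify(seg)
            newly = getattr(classify, "newly_labelled", None)
            if newly is None:
                newly = [seg] if seg.label in (S1, S2) else []
            for labelled in newly:
                thr = state.c1 * thr + state.c2 * state.r1 * labelled.peakamp
        segments.append(seg)

    for i in range(i0, i1):
        above = x[i] > thr
        if above_prev is None or above != above_prev:
            last_cross = i
            above_prev = above
        elif (i - last_cross) / fs > 5.0 * d2_fn():
            # stuck entirely above or below the threshold: reset
            thr = state.thr_init
            if events is not None:
                events.append(("reset", i / fs))
            last_cross = i
            above_prev = None
            continue
        if above:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                pend_runs.append((run_start, i - 1))
                run_start = None
            # a future run would start at >= i+1; close the pending segment
            # as soon as the gap can no longer be < gap_ms
            if pend_runs and (i - pend_runs[-1][1]) >= gap_n - 1:
                finalize()
    if run_start is not None:
        pend_runs.append((run_start, i1 - 1))
    if pend_runs:
        finalize()

    final = replace(state, thr=thr)
    return segments, final
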