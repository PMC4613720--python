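"""Rule-based S1/S2 classification of candidate heart-sound segments.

Each candidate segment is labelled S1, S2 or DK ("do not know") purely from
the time distances to previously labelled segments ("backward event time
analysis") and, when that fails, from the mutual spacing of the last five
segments ("sequence pattern recognition").  Two dynamic time variables
drive every rule:

* ``D1`` — S1-to-S2 separation within one cycle (init 0.32 s),
* ``D2`` — S1-to-S1 separation, one heart period (init 0.87 s),

with margin ratios ``k1 = 0.85`` and ``k2 = 1.1`` admitting peaks up to
15% early or 10% late.  D1 and D2 are exponential averages, updated with
weight 0.1 whenever a rule measures them directly:

    D2 <- 0.9 * D2 + 0.1 * (st(n) - st(n-2))
    D1 <- 0.9 * D1 + 0.1 * (st(n) - st(n-1))

Rules fire in a fixed order; the first that matches wins:

1. Scenarios 1-3: current segment relative to an S1 two back (-> S1, D2
   update), an S1 one back (-> S2, D1 update), or an S2 one back (-> S1,
   no update — the measured span D2 - D1 crosses two cycles).
2. Exceptions 1-4 (only after two consecutive DKs): skip over the unknown
   segment using distances to the segment two back.
3. Patterns 1-5 (current segment still DK, five segments buffered): the
   five mutual spacings must match an S1/S2 cadence; on a match all five
   buffered segments are relabelled and the timing state is reseeded.
   Patterns 3-5 derive a trial period D2_x from the buffer and must pass a
   heart-rate plausibility gate: the implied rate stays below 200 bpm and
   the rate jump since the last accepted period stays below
   ``3.77 * (seconds since last D2 update) + 17`` bpm.  Pattern 3 also
   derives the S1-S2 gap from the systolic-time relation

       D1_x = -0.0018 * (60 / D2_x) + 0.456.

Margin placement in compound bounds follows the printed rule text
literally (the margin multiplies only its adjacent term, e.g.
``k1 * D1 + D2``); ``margin_mode="full"`` applies it to the whole sum for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .segmenter import DK, S1, S2, PeakSegment


@dataclass
class TimingState:
    """Dynamic timing quantities of the classifier."""

    d1: float = 0.32
    d2: float = 0.87
    k1: float = 0.85
    k2: float = 1.1
    d2_last: float = 0.87
    t_last_d2_update: float = 0.0
    hr_max: float = 200.0
    hr_var_slope: float = 3.77
    hr_var_intercept: float = 17.0

    def __post_init__(self) -> None:
        if not 0 < self.d1 < self.d2:
            raise ValueError("require 0 < D1 < D2")
        if not self.k1 < 1 < self.k2:
            raise ValueError("margins must satisfy k1 < 1 < k2")


def update_d2(state: TimingState, measured: float, now: float) -> TimingState:
    """Exponential-average update of the heart period D2."""
    if not measured > 0:
        raise ValueError(f"measured period must be positive, got {measured}")
    new_d2 = 0.9 * state.d2 + 0.1 * measured
    return replace(state, d2=new_d2, d2_last=new_d2, t_last_d2_update=now)


def update_d1(state: TimingState, measured: float) -> TimingState:
    """Exponential-average update of the S1-S2 separation D1."""
    if not measured > 0:
        raise ValueError(f"measured separation must be positive, got {measured}")
    return replace(state, d1=0.9 * state.d1 + 0.1 * measured)


def d1_from_hr(d2_x: float) -> float:
    """S1-S2 separation implied by a heart period, via systolic timing.

    Linear regression of electromechanical systole on heart rate:
    ``D1_x = -0.0018 * HR + 0.456`` with ``HR = 60 / D2_x`` in bpm.
    """
    if not d2_x > 0:
        raise ValueError(f"heart period must be positive, got {d2_x}")
    return -0.0018 * (60.0 / d2_x) + 0.456


def hr_gate(state: TimingState, d2_x: float, now: float) -> bool:
    """Plausibility gate on a trial heart period for Patterns 3-5.

    Accepts ``d2_x`` iff the implied rate is below ``hr_max`` and the rate
    increase relative to the last accepted period is below a variability
    limit that relaxes with time since the last D2 update.
    """
    if not d2_x > 0:
        return False
    hr_measured_var = 60.0 / d2_x - 60.0 / state.d2_last
    limit = state.hr_var_slope * (now - state.t_last_d2_update) \
        + state.hr_var_intercept
    return hr_measured_var < limit and 60.0 / d2_x < state.hr_max


class HeartSoundClassifier:
    """Sequential rule engine over a five-segment buffer.

    Holds the :class:`TimingState`, the last five segments (labels mutable,
    for pattern relabelling), and a structured log of every decision.  One
    instance processes one recording; classification is deterministic.
    """

    def __init__(self, state: Optional[TimingState] = None,
                 margin_mode: str = "literal"):
        if margin_mode not in ("literal", "full"):
            raise ValueError("margin_mode must be 'literal' or 'full'")
        self.state = state if state is not None else TimingState()
        self.margin_mode = margin_mode
        self.buffer: list[PeakSegment] = []   # last <= 5 segments, incl. current
        self.log: list[dict] = []
        #: segments whose label changed from DK to S1/S2 in the last call
        self.newly_labelled: list[PeakSegment] = []

    # -- bound helpers ----------------------------------------------------
    @staticmethod
    def _within(x: float, lo: float, hi: float) -> bool:
        return lo < x < hi

    def _bounds(self, margin_on: float, offset: float) -> tuple[float, float]:
        """Margined interval; placement controlled by ``margin_mode``."""
        k1, k2 = self.state.k1, self.state.k2
        if self.margin_mode == "literal":
            return k1 * margin_on + offset, k2 * margin_on + offset
        return k1 * (margin_on + offset), k2 * (margin_on + offset)

    # -- rule engine ------------------------------------------------------
    def classify(self, seg: PeakSegment) -> str:
        """Label one segment; may relabel buffered predecessors (patterns)."""
        st = self.state
        before = (st.d1, st.d2)
        seg.label = DK
        self.newly_labelled = []
        rule = None

        prev = self.buffer[-1] if len(self.buffer) >= 1 else None
        prev2 = self.buffer[-2] if len(self.buffer) >= 2 else None
        dt1 = seg.st - prev.st if prev is not None else None
        dt2 = seg.st - prev2.st if prev2 is not None else None

        # --- backward event time analysis: scenarios ---
        # scenarios are the "normal" path: they need a classified recent
        # history (a DK at n-1 routes the same geometry to Exception 1)
        if prev2 is not None and prev2.label == S1 and prev.label != DK and \
                self._within(dt2, st.k1 * st.d2, st.k2 * st.d2):
            seg.label, rule = S1, "scenario1"
            self.state = update_d2(st, dt2, seg.st)
        elif prev is not None and prev.label == S1 and \
                self._within(dt1, st.k1 * st.d1, st.k2 * st.d1):
            seg.label, rule = S2, "scenario2"
            self.state = update_d1(st, dt1)
        elif prev is not None and prev.label == S2 and \
                self._within(dt1, st.k1 * (st.d2 - st.d1),
                             st.k2 * (st.d2 - st.d1)):
            # spans two different cycles: no D1/D2 redefinition
            seg.label, rule = S1, "scenario3"

        # --- exceptions: require two consecutive DKs ---
        if seg.label == DK and prev is not None and prev.label == DK \
                and prev2 is not None:
            if prev2.label == S1 and \
                    self._within(dt2, st.k1 * st.d2, st.k2 * st.d2):
                seg.label, rule = S1, "exception1"
                self.state = update_d2(st, dt2, seg.st)
            elif prev2.label == S2 and \
                    self._within(dt2, st.k1 * st.d2, st.k2 * st.d2):
                # update stated only for an S1 at n-2, so none here
                seg.label, rule = S2, "exception2"
            elif prev2.label == S2 and \
                    self._within(dt2, (st.k1 * st.d2) * 2 - st.d1,
                                 (st.k2 * st.d2) * 2 - st.d1):
                seg.label, rule = S1, "exception3"
            elif prev2.label == S2 and \
                    self._within(dt2, st.k1 * st.d2 - st.d1,
                                 st.k2 * st.d2 - st.d1):
                seg.label, rule = S1, "exception4"

        # --- sequence pattern recognition ---
        if seg.label == DK and len(self.buffer) >= 4:
            rule = self._try_patterns(seg)

        if seg.label in (S1, S2) and rule is not None \
                and not rule.startswith("pattern"):
            self.newly_labelled = [seg]

        self.buffer.append(seg)
        if len(self.buffer) > 5:
            self.buffer.pop(0)

        self.log.append({
            "st": seg.st, "label": seg.label, "rule": rule,
            "d1_before": before[0], "d2_before": before[1],
            "d1_after": self.state.d1, "d2_after": self.state.d2,
        })
        return seg.label

    def _try_patterns(self, seg: PeakSegment) -> Optional[str]:
        st = self.state
        five = self.buffer[-4:] + [seg]
        t = [s.st for s in five]
        g1 = t[4] - t[3]
        g2 = t[4] - t[2]
        g3 = t[4] - t[1]
        g4 = t[4] - t[0]
        w = self._within

        # Pattern 1: cadence ending on an S2
        if w(g1, st.k1 * st.d1, st.k2 * st.d1) and \
                w(g2, st.k1 * st.d2, st.k2 * st.d2) and \
                w(g3, *self._bounds(st.d1, st.d2)) and \
                w(g4, *self._bounds(st.d2, st.d2)):
            self._relabel(five, [S2, S1, S2, S1, S2])
            self.state = replace(st, d2_last=st.d2, t_last_d2_update=seg.st)
            return "pattern1"

        # Pattern 2: cadence ending on an S1
        lo1, hi1 = self._bounds(st.d2, -st.d1)
        if w(g1, lo1, hi1) and \
                w(g2, st.k1 * st.d2, st.k2 * st.d2) and \
                w(g3, st.k1 * (st.d2 - st.d1) + st.d2,
                  st.k2 * (st.d2 - st.d1) + st.d2) and \
                w(g4, *self._bounds(st.d2, st.d2)):
            self._relabel(five, [S1, S2, S1, S2, S1])
            self.state = replace(st, d2_last=st.d2, t_last_d2_update=seg.st)
            return "pattern2"

        # Patterns 3 and 4: free trial period from the buffer itself
        d2x = g2
        if d2x > 0 and hr_gate(st, d2x, seg.st):
            for name, d1x in (("pattern3", d1_from_hr(d2x)), ("pattern4", st.d1)):
                # d1x < d2x keeps the reseeded state physically consistent
                if 0 < d1x < d2x and \
                        w(g1, st.k1 * d1x, st.k2 * d1x) and \
                        w(g3, *self._bounds(d1x, d2x)) and \
                        w(g4, *self._bounds(d2x, d2x)):
                    self._relabel(five, [S2, S1, S2, S1, S2])
                    new_d1 = d1x if name == "pattern3" else st.d1
                    self.state = replace(
                        st, d1=new_d1, d2=d2x, d2_last=d2x,
                        t_last_d2_update=seg.st)
                    return name

        # Pattern 5: five consecutive S1 sounds (S2s unseen)
        d2x = g1
        if d2x > 0 and st.d1 < d2x and hr_gate(st, d2x, seg.st):
            if all(w(t[j + 1] - t[j], st.k1 * d2x, st.k2 * d2x)
                   for j in range(3)):
                self._relabel(five, [S1, S1, S1, S1, S1])
                self.state = replace(st, d2=d2x, d2_last=d2x,
                                     t_last_d2_update=seg.st)
                return "pattern5"
        return None

    def _relabel(self, five: list[PeakSegment], labels: list[str]) -> None:
        self.newly_labelled = []
        for s, lab in zip(five, labels):
            if s.label != lab:
                s.label = lab
                self.newly_labelled.append(s)


def classify_segment(buffer: list[PeakSegment], state: TimingState,
                     seg: PeakSegment, margin_mode: str = "literal",
                     ) -> tuple[str, TimingState, list[PeakSegment]]:
    """Functional one-shot wrapper around :class:`HeartSoundClassifier`.

    Returns ``(label, updated_state, updated_buffer)``; pattern matches are
    reflected in the labels of the returned buffer segments.
    """
    clf = HeartSoundClassifier(state=state, margin_mode=margin_mode)
    clf.buffer = list(buffer)
    label = clf.classify(seg)
    return label, clf.state, clf.buffer
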