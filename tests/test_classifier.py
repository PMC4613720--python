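import numpy as np
import pytest

from pcghr.classifier import (HeartSoundClassifier, TimingState,
                              classify_segment, d1_from_hr, hr_gate,
                              update_d1, update_d2)
from pcghr.segmenter import DK, S1, S2, PeakSegment


def seg(st, label=DK, amp=1.0):
    return PeakSegment(t_start=st - 0.02, t_end=st + 0.02, st=st,
                       peakamp=amp, label=label)


def feed(clf, times):
    return [clf.classify(seg(t)) for t in times]


class TestTimingUpdates:
    def test_d2_fixed_point(self):
        st = update_d2(TimingState(), 0.87, now=1.0)
        assert st.d2 == pytest.approx(0.87, abs=1e-12)
        assert st.t_last_d2_update == 1.0

    def test_d2_weighted_average(self):
        st = update_d2(TimingState(), 1.00, now=0.0)
        assert st.d2 == pytest.approx(0.883, abs=1e-12)

    def test_d2_converges_geometrically(self):
        st = TimingState(d2=1.0)
        for _ in range(100):
            st = update_d2(st, 0.5, now=0.0)
        assert st.d2 == pytest.approx(0.5, abs=1e-4)

    def test_d1_fixed_point_and_average(self):
        assert update_d1(TimingState(), 0.32).d1 == pytest.approx(0.32)
        assert update_d1(TimingState(), 0.40).d1 == pytest.approx(0.328,
                                                                  abs=1e-12)

    def test_d1_converges_geometrically(self):
        st = TimingState(d1=0.5)
        for _ in range(100):
            st = update_d1(st, 0.3)
        assert st.d1 == pytest.approx(0.3, abs=1e-4)

    @pytest.mark.parametrize("fn", [
        lambda s: update_d2(s, -0.1, 0.0), lambda s: update_d1(s, 0.0)])
    def test_nonpositive_measurement_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(TimingState())


class TestHrGate:
    def test_steady_rate_accepted(self):
        st = TimingState(d2_last=1.0, t_last_d2_update=0.0)
        assert hr_gate(st, 1.0, now=0.0)

    def test_rate_above_maximum_rejected(self):
        st = TimingState(d2_last=1.0)
        assert not hr_gate(st, 0.25, now=100.0)  # 240 bpm

    def test_fast_rate_jump_rejected(self):
        # +40 bpm jump after 1 s: limit is 3.77*1 + 17 = 20.77
        st = TimingState(d2_last=1.0, t_last_d2_update=0.0)
        assert not hr_gate(st, 0.6, now=1.0)

    def test_limit_relaxes_with_time(self):
        st = TimingState(d2_last=1.0, t_last_d2_update=0.0)
        assert hr_gate(st, 0.6, now=10.0)  # limit 54.7 > 40


class TestSystolicRelation:
    def test_values_at_60_and_100_bpm(self):
        assert d1_from_hr(1.0) == pytest.approx(0.348, abs=1e-12)
        assert d1_from_hr(0.6) == pytest.approx(0.276, abs=1e-12)

    def test_monotone_decreasing_in_rate(self):
        periods = np.linspace(0.3, 1.5, 50)
        gaps = [d1_from_hr(p) for p in periods]
        assert all(a < b for a, b in zip(gaps, gaps[1:]))

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            d1_from_hr(0.0)


class TestScenarios:
    def test_scenario1_labels_s1_and_updates_d2(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S1), seg(0.32, S2)]
        assert clf.classify(seg(0.87)) == S1
        assert clf.log[-1]["rule"] == "scenario1"
        assert clf.state.d2 == pytest.approx(0.87, abs=1e-12)

    def test_scenario2_labels_s2_and_updates_d1(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S1)]
        assert clf.classify(seg(0.32)) == S2
        assert clf.log[-1]["rule"] == "scenario2"
        assert clf.state.d1 == pytest.approx(0.32, abs=1e-12)

    def test_scenario3_labels_s1_without_updates(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S2)]
        assert clf.classify(seg(0.55)) == S1
        assert clf.log[-1]["rule"] == "scenario3"
        assert clf.state.d1 == 0.32 and clf.state.d2 == 0.87

    def test_out_of_margin_separation_stays_dk(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S1), seg(0.32, S2)]
        assert clf.classify(seg(1.2)) == DK  # 1.2 > 1.1 * 0.87


class TestExceptions:
    def test_exception1_skips_a_dk_and_updates_d2(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S1), seg(0.4, DK)]
        assert clf.classify(seg(0.87)) == S1
        assert clf.log[-1]["rule"] == "exception1"
        assert clf.state.d2 == pytest.approx(0.87, abs=1e-12)
        assert clf.state.t_last_d2_update == pytest.approx(0.87)

    def test_exception2_no_d2_update_for_s2_anchor(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S2), seg(0.4, DK)]
        assert clf.classify(seg(0.87)) == S2
        assert clf.log[-1]["rule"] == "exception2"
        assert clf.state.t_last_d2_update == 0.0

    def test_exception3_spans_two_cycles(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S2), seg(0.6, DK)]
        # (k1*D2)*2 - D1 = 1.159 < 1.3 < (k2*D2)*2 - D1 = 1.594
        assert clf.classify(seg(1.3)) == S1
        assert clf.log[-1]["rule"] == "exception3"

    def test_exception4_spans_s2_to_next_s1(self):
        clf = HeartSoundClassifier()
        clf.buffer = [seg(0.0, S2), seg(0.2, DK)]
        # k1*D2 - D1 = 0.4195 < 0.5 < k2*D2 - D1 = 0.637
        assert clf.classify(seg(0.5)) == S1
        assert clf.log[-1]["rule"] == "exception4"


class TestPatterns:
    def test_alternating_cadence_relabels_buffer(self):
        """Five DKs at S2/S1 cadence match the alternating pattern."""
        clf = HeartSoundClassifier()
        labels = feed(clf, [0.0, 0.55, 0.87, 1.42])
        assert labels == [DK, DK, DK, DK]
        assert clf.classify(seg(1.74)) == S2
        assert clf.log[-1]["rule"] == "pattern1"
        assert [s.label for s in clf.buffer] == [S2, S1, S2, S1, S2]

    def test_pattern_relabels_only_the_buffered_five(self):
        clf = HeartSoundClassifier()
        first = seg(-3.0)
        clf.classify(first)
        feed(clf, [0.0, 0.55, 0.87, 1.42])
        clf.classify(seg(1.74))
        assert first.label == DK  # earlier history is immutable

    def test_pattern3_reseeds_timing_from_buffer(self):
        # 50 bpm rhythm: far outside the initial D1/D2, so only the
        # free-period pattern with the systolic relation can lock
        clf = HeartSoundClassifier()
        times = [0.0, 0.366, 1.2, 1.566, 2.4, 2.766]
        for t in times[:-1]:
            clf.classify(seg(t))
        assert clf.classify(seg(times[-1])) == S2
        assert clf.log[-1]["rule"] == "pattern3"
        assert clf.state.d2 == pytest.approx(1.2)
        assert clf.state.d1 == pytest.approx(d1_from_hr(1.2))
        assert [s.label for s in clf.buffer] == [S2, S1, S2, S1, S2]

    def test_pattern5_locks_onto_s1_only_train(self):
        # only every other sound detected: equal spacings of one period
        clf = HeartSoundClassifier()
        feed(clf, [0.0, 1.0, 2.0, 3.0])
        assert clf.classify(seg(4.0)) == S1
        assert clf.log[-1]["rule"] == "pattern5"
        assert [s.label for s in clf.buffer] == [S1] * 5
        assert clf.state.d2 == pytest.approx(1.0)


class TestDynamics:
    def test_deterministic_relabelling_reproducible(self):
        times = list(np.cumsum([0.9, 0.35, 0.55, 0.31, 0.58, 0.9, 0.33]))
        runs = []
        for _ in range(2):
            clf = HeartSoundClassifier()
            feed(clf, times)
            runs.append([(r["st"], r["label"], r["rule"]) for r in clf.log])
        assert runs[0] == runs[1]

    def test_periodic_train_locks_and_recovers_period(self):
        """On a clean periodic train the classifier locks within 20 beats,
        labels alternate S1/S2 with no DK, and D2 converges to the period."""
        period, gap = 1.0, 0.348
        clf = HeartSoundClassifier()
        labels = []
        for k in range(30):
            labels.append(clf.classify(seg(k * period)))
            labels.append(clf.classify(seg(k * period + gap)))
        lock = next(i for i, r in enumerate(clf.log) if r["rule"] is not None)
        assert lock <= 2 * 20
        tail = labels[lock + 1:]
        assert DK not in tail
        assert all(lab == (S1 if i % 2 == 0 else S2)
                   for i, lab in enumerate(tail, start=lock + 1))
        assert abs(clf.state.d2 - period) / period <= 0.02

    def test_scenario1_firings_respect_margins(self):
        """Every scenario-1 separation lies within (k1*D2, k2*D2) at fire
        time (audited from the classification log)."""
        rng = np.random.default_rng(12)
        t, times = 0.0, []
        for _ in range(60):
            p = 0.85 + rng.normal(0, 0.02)
            times += [t, t + 0.34]
            t += p
        clf = HeartSoundClassifier()
        feed(clf, times)
        fired = [i for i, r in enumerate(clf.log) if r["rule"] == "scenario1"]
        assert fired
        for i in fired:
            dt2 = clf.log[i]["st"] - clf.log[i - 2]["st"]
            assert clf.state.k1 * clf.log[i]["d2_before"] < dt2
            assert dt2 < clf.state.k2 * clf.log[i]["d2_before"]


class TestFunctionalWrapper:
    def test_classify_segment_returns_label_state_buffer(self):
        buf = [seg(0.0, S1), seg(0.32, S2)]
        label, state, out = classify_segment(buf, TimingState(), seg(0.87))
        assert label == S1
        assert state.d2 == pytest.approx(0.87)
        assert len(out) == 3
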