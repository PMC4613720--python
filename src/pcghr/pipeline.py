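"""End-to-end pipeline: raw recording in, beats and heart rate out.

Stage order: anti-alias low-pass -> decimation -> Meyer CWT filter bank ->
squared per-sample max -> transient high-pass -> dynamic-threshold
segmentation interleaved with rule-based S1/S2 classification -> beat
merging -> windowed heart rate.  Segmentation and classification run
interleaved because the detection threshold is updated after every
accepted heart sound and the 5*D2 reset clock tracks the classifier's
current period estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classifier import HeartSoundClassifier, TimingState
from .config import PipelineConfig
from .envelope import (FilterBankSpec, TransientEnvelope, build_filterbank,
                       cwt_envelope, transient_highpass)
from .heartrate import BeatSeries, HRSeries, compute_hr, merge_beats
from .preprocess import RawRecording, condition
from .segmenter import PeakSegment, init_threshold, detect_segments


@dataclass
class PipelineResult:
    """Everything the pipeline produces for one recording."""

    beats: BeatSeries
    hr: HRSeries
    segments: list[PeakSegment]
    log: list[dict]
    events: list[tuple]
    envelope: TransientEnvelope


class _ClassifierAdapter:
    """Callable bridge exposing the classifier's relabel bookkeeping."""

    def __init__(self, clf: HeartSoundClassifier):
        self.clf = clf
        self.newly_labelled: list[PeakSegment] = []

    def __call__(self, seg: PeakSegment) -> str:
        label = self.clf.classify(seg)
        self.newly_labelled = self.clf.newly_labelled
        return label


def run_pipeline(rec: RawRecording,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Process one recording with the full algorithm.

    Deterministic: identical input and configuration yield identical
    output.  Raises ``ValueError`` for configurations that are invalid at
    the recording's sampling rate.
    """
    cfg = cfg if cfg is not None else PipelineConfig()

    sig = condition(rec, cfg.lpf_cutoff_hz, cfg.lpf_order,
                    cfg.downsample_factor)
    bank = build_filterbank(
        FilterBankSpec(cfg.n_filters, cfg.f_min_hz, cfg.f_max_hz), sig.fs)
    env = transient_highpass(cwt_envelope(sig, bank),
                             cfg.hpf_cutoff_hz, cfg.hpf_order)

    thr0 = init_threshold(env, cfg.thr_init_factor, cfg.thr_init_head_s,
                          c1=cfg.c1, c2=cfg.c2, r1=cfg.r1)
    clf = HeartSoundClassifier(
        TimingState(d1=cfg.d1_init_s, d2=cfg.d2_init_s, k1=cfg.k1, k2=cfg.k2,
                    d2_last=cfg.d2_init_s, hr_max=cfg.hr_max_bpm,
                    hr_var_slope=cfg.hr_var_slope,
                    hr_var_intercept=cfg.hr_var_intercept),
        margin_mode=cfg.margin_mode)
    events: list[tuple] = []
    segments, _ = detect_segments(
        env, thr0, gap_ms=cfg.gap_ms, d2=lambda: clf.state.d2,
        max_seg_ms=cfg.max_seg_ms, edge_s=cfg.edge_s,
        classify=_ClassifierAdapter(clf), events=events)

    beats = merge_beats(segments)
    hr = compute_hr(beats, cfg.window_len_s, cfg.hop_s,
                    t_start=0.0, t_end=rec.duration)
    return PipelineResult(beats=beats, hr=hr, segments=segments,
                          log=clf.log, events=events, envelope=env)
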