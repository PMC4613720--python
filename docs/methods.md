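# Methods

`pcghr` extracts heart rate from single-channel acoustic recordings made at
the suprasternal notch (the dip at the base of the throat).  Signals there
are strongly low-pass-filtered versions of chest heart sounds: the first
(S1) and second (S2) heart sound arrive as short transients whose energy
concentrates below ~25 Hz, superimposed on breathing noise and occasional
loud artefacts (snoring, speech).  The pipeline detects candidate
heart-sound events, labels them S1/S2/DK with purely time-based rules, and
converts S1 times into a windowed heart rate.

## Pipeline stages

**Conditioning.**  The raw signal (nominally 2205 Hz, 10-bit) is low-pass
filtered at 100 Hz with an 8th-order Butterworth applied forward-backward
and decimated by 10 to 220.5 Hz.  The zero-phase realization is a design
choice: all later stages reason about event *times*, and offline
processing permits non-causal filtering.  Decimation keeps every 10th
sample starting at index 0; times in seconds are `index / fs`.

**Transient envelope.**  A bank of 15 continuous-wavelet band-pass filters
(Meyer mother wavelet) spans 8.9–23 Hz with linearly spaced centre
frequencies — the quoted range is under 1.4 octaves, so linear and
logarithmic spacing are nearly indistinguishable.  The Meyer wavelet is
defined in closed form in the frequency domain, so each band is realized
as a zero-phase FFT-domain filter with unit peak gain; the scale for
centre frequency `f` is `(2/3)·fs/f`, `2/3` being the Meyer wavelet's
natural peak frequency.  Per sample, the largest squared band output is
kept; squaring folds both signal polarities into energy, and the max
tracks whichever band carries a given subject's heart-sound energy.  An
8th-order windowed-sinc (Hamming) FIR high-pass at 40 Hz, built by
spectral inversion so its DC gain is exactly zero, then suppresses slow
energy drift relative to transient ripple.  At 9 taps on a 220.5 Hz track
this filter is deliberately weak (gain ≈ 0.001 at 4 Hz vs ≈ 0.05–0.1 at
28–36 Hz, the squared-carrier ripple of the bursts): enough selectivity to
favour transients over breathing; both cutoff and order are
configuration keys.  The first and last 0.5 s of the envelope are excluded
from detection (FFT edge effects).

**Segmentation.**  Detection operates on the absolute value of the
high-passed track (the high-pass can produce negative excursions; the
squaring intent is energy magnitude).  Supra-threshold runs separated by
less than 100 ms are grouped into one segment; the merge threshold is
needed because the squared-carrier ripple of a single burst crosses zero
every ~15–20 ms.  Segments longer than 200 ms are discarded as artefacts
before classification.  Each surviving segment carries its peak amplitude
and a segment time `st` — the time of the maximum envelope sample, the
most stable landmark for inter-beat intervals.  After every segment the
classifier accepts as S1 or S2, the threshold moves toward one third of
the peak amplitude:

    thr_new = 0.9·thr_old + 0.1·(1/3)·peakamp

whose fixed point under constant peaks `p` is `p/3`.  If the envelope
stays entirely above or entirely below the threshold for longer than five
expected heart cycles (5·D2), the threshold resets to its initial value;
the reset clock restarts at every threshold crossing.

*Initial threshold.*  The opening 10 s are split into 1 s blocks and the
threshold starts at one third of the median per-block maximum.  Nearly
every block contains at least one heart sound, so the median block maximum
estimates a typical S1/S2 peak, is robust to a minority of
artefact-inflated blocks, and is scale-free.  A noise-floor statistic
(e.g. a small multiple of the median sample) was rejected: the squared
envelope's noise distribution is heavy-tailed, so such a threshold sits
inside the tail and noise exceedances merge into long segments that are
then discarded wholesale, starving the classifier.

**Classification.**  Two dynamic time variables drive every rule: `D1`,
the S1→S2 separation within a cycle (initial 0.32 s), and `D2`, the
S1→S1 heart period (initial 0.87 s).  Margins `k1 = 0.85`, `k2 = 1.1`
admit peaks 15% early or 10% late.  Rules fire in a fixed order — three
scenarios (backward look at a labelled S1 or S2 one or two segments back),
four exceptions (skipping over a DK segment; triggered only after two
consecutive DKs), then five buffer patterns that test the mutual spacings
of the last five segments and, on a match, relabel all five and reseed
`D1`/`D2`.  The first matching rule wins, so classification is
deterministic.  Successful direct measurements update the state as
exponential averages with weight 0.1
(`D2 ← 0.9·D2 + 0.1·(st(n) − st(n−2))`, analogously for `D1`).  Patterns
3–5 derive a trial period `D2_x` from the buffer itself and must pass a
plausibility gate: implied rate below 200 bpm and a rate *increase* since
the last accepted period below `3.77·Δt + 17` bpm, where `Δt` is the time
since the last `D2` update (clock starts at 0 at recording start).
Pattern 3 derives the matching S1–S2 gap from the systolic-time relation
`D1_x = −0.0018·HR + 0.456` (HR in bpm); Pattern 4 reuses the current
`D1`; Pattern 5 matches five equally spaced sounds (only S1s visible) and
requires `D2_x > D1` so the reseeded state stays physically consistent.

Two choices in the compound pattern bounds were genuinely open:
in a bound written as `k1 × D1 + D2` the margin multiplies only its
adjacent term (bounds that intend the margin on a difference carry
explicit parentheses, so their absence is taken as meaningful); the
`margin_mode="full"` configuration applies the margin to the whole sum for
sensitivity analysis.  Scenario 1 additionally requires the segment at
n−1 to be labelled (not DK) — otherwise the identical geometry of
Exception 1 could never fire and the exception tier would be dead code.
Exception-tier `D2` updates apply only when the anchor at n−2 is an S1.
Patterns 1–2 judge the buffer against the existing `D1`/`D2` without the
rate gate and leave both values unchanged on a match (they confirm the
current rhythm rather than measure a new one); they do refresh the
update clock.

**Heart rate.**  Every S1 anchors one heartbeat; a following S2 is
absorbed, orphan S2s and DKs contribute nothing.  Heart rate per 60 s
window is the number of inter-beat intervals with *both* endpoints inside
the (closed) window divided by the window length, times 60.  Windows tile
by default (hop = window length, matching comparison against 60 s
reference averages); a window with fewer than two beats reports a missing
value, never zero.  Rates above 300 bpm are flagged, not clipped.

## Synthetic recordings

The clinical recordings the algorithm was developed on are not publicly
available, so validation uses a seeded simulator that reproduces exactly
the features the pipeline keys on:

* S1/S2 as Gaussian-windowed sinusoids (defaults: 14 Hz / 18 Hz carriers,
  80 ms / 60 ms FWHM, S2 at half the S1 amplitude).  With these widths
  ≥ 80% of a burst's spectral energy lies inside the 8.9–23 Hz analysis
  band.  The burst is *not* a physiological template; the classifier
  consumes only timing and in-band energy, which the model controls
  exactly.
* the S1→S2 gap follows the systolic relation `D1 = −0.0018·HR + 0.456`
  at the instantaneous rate, so the pattern tier's Pattern 3 can lock;
* beat periods `60/HR` plus Gaussian jitter (SD 0.02 s, typical of quiet
  sleep), with an optional arbitrary bpm trajectory;
* white sensor noise (SD 0.02 versus S1 amplitude 0.3), a 0.25 Hz
  breathing sinusoid (amplitude 0.1), optional 10-bit quantization;
* snore-like artefacts: band-limited (5–30 Hz) noise bursts of 0.25–0.6 s
  at three times the S1 amplitude; exactly `rate × duration` are inserted
  at random positions so the nominal events-per-minute figure is met
  rather than Poisson-approximated.

All randomness flows from a single seed; identical configurations are
bit-identical.  What passing tests on this simulator do *not* show:
robustness to real murmurs, split heart sounds, sensor detachment, or
breathing spectra overlapping the analysis band.

## Numerical choices and degenerate inputs

* Interval-count quantization bounds the window HR error by two counts
  (one partial interval per window edge), i.e. 2 bpm at 60 s windows.
* The 5·D2 reset clock uses the classifier's *current* `D2`.
* Supra-threshold comparison is strict (`> thr`); run merging uses the
  exact sample-domain equivalent of "gap < 100 ms".
* Empty envelopes yield empty segment lists; an all-zero envelope head
  makes threshold initialization fail loudly rather than silently detect
  nothing.
* WAV integers are normalized by PCM full scale, CSV integers by 2⁹
  (raw 10-bit ADC counts).

## Problem sizes used in validation

End-to-end checks run on 10-minute recordings (clean and artefact-laden)
plus 3-minute recordings per rate for a 50–120 bpm sweep; unit and oracle
checks use seconds-long envelopes and five hundred random segmentation
cases.  These sizes give every stage (threshold adaptation, pattern
re-locks, window statistics) room to reach steady state while keeping the
whole suite fast.

## Known limitations

* With six 0.25–0.6 s artefacts per minute, an artefact plus the 100 ms
  merge margins covers most of a 0.86 s cycle, so roughly 80% of artefacts
  destroy one S1 beyond recovery.  The windowed interval count then reads
  ~5–6 bpm low, and only about half the windows stay within ±10% of truth
  — degraded but not destroyed.  A mean-inter-beat-interval estimator
  over gap-filtered intervals would be robust to such dropout but would
  be a different output definition than the windowed interval count this
  package implements.
* At high rates the gate `3.77·Δt + 17` delays the first pattern lock
  (e.g. ~9 s at 120 bpm from a cold start), biasing the first window low.
* The rule constants (0.32 s, 0.87 s, margins, gate) encode neck-signal
  timing at rest/sleep; chest recordings or exercise rates need retuning.
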