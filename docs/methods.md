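# Methods

This note records the models, estimators and numerical choices behind
`breathvoice`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about real recordings.

## Signal model and synthetic data

The generator realizes the standard source–filter view of phonation.
The glottal source is a Rosenberg-style flow pulse: a raised-cosine
opening ramp and a cosine closing fall inside the open fraction (the
open quotient, OQ) of each cycle.  Its first difference excites a
cascade of four fixed second-order resonances (660, 1200, 2600,
3300 Hz — a generic open-vowel setting), which is enough to exercise
cepstral and spectral measures; vowel identity and room acoustics are
out of scope.

Breathiness is a single scalar `b` in [0, 1] that drives four coupled
physiological expressions:

1. **Aspiration noise.**  White noise band-passed 500–8000 Hz is shaped
   by the same formant filter as the glottal source (turbulence is
   generated at the glottis and filtered by the same tract), gated by
   the open phase, and rolled off above ~4.8 kHz, where at the 45 dB
   recording SNR it would sit below the noise floor anyway.  Its RMS is
   `(0.05 + 0.95·b) × 0.7` of the voiced RMS: a 5% turbulence pedestal
   remains at `b = 0` because no phonation is turbulence-free.
2. **Open quotient.**  An affine map `OQ = 0.50 + 0.15·b`, matching the
   span of class-mean open quotients observed perceptually (~0.53 at
   the least breathy class to ~0.65 at the most).  No quantitative
   breathiness→OQ law is established; the map is a modelling choice.
3. **Incomplete closure.**  The closing phase lengthens from 40% to 65%
   of the open phase as `b` rises, weakening the high harmonics of the
   source — the spectral signature of a glottis that never fully shuts.
4. **Amplitude instability.**  Cycle-wise source gains are perturbed
   with sd `0.01 + 0.06·b` (1% for stable phonation up to 7% for
   severely breathy), giving shimmer a true physiological component.

Background noise is added at a clean-to-noise ratio of 45 dB for the
microphone channel; the EGG channel carries its own noise at 30 dB.
These are the noise levels of the motivating recording chain and are
verified by a measured-SNR contract test (±2 dB).

The EGG waveform is built directly in the contact-area domain: a sharp
raised-cosine contacting rise (3% of the cycle), a contact plateau, a
slower de-contacting fall (8%), and an open baseline, laid out so the
positive and negative dEGG peaks are exactly `(1 − OQ)·T` apart.  That
makes the generator's OQ an exact geometric ground truth for both
estimators.

Respiratory traces are piecewise-linear realizations of the four-stage
thoracic pattern of a sustained trial (expansion to a pre-onset
maximum; slow decline; faster collapse; plateau), embedded between
resting tidal cycles at ≤ 0.3 Hz and smoothed below ~8 Hz.  Raters are
simulated as truth + Gaussian noise snapped to the 0–4 half-point grid.

Phonation durations follow an air-depletion model: transglottal flow
rises linearly from 1 at `b = 0` to 1.748 at `b = 1` (reflecting the
reported ~60–75% airflow increase in breathy phonation), against a lung
capacity worth 12.43 s of non-breathy phonation; gradual-breathiness
trials integrate the ramp, landing near 9 s, and fully breathy trials
near 7.1 s.

**What the synthetic data do not show.**  All breathiness expressions
derive from one latent scalar, so feature covariances are simpler than
in real voices (no vowel, register, singer or session effects beyond
the modelled pitch/intensity/OQ scatter), and passing tests demonstrate
estimator correctness and pipeline-level sign structure — not clinical
validity on real recordings.

## Estimators

**Pitch.**  Frame-wise normalized autocorrelation (window of three
minimum-f0 periods, Hann-windowed, window-autocorrelation corrected),
candidate local maxima scored with a 0.01-per-octave cost, voicing
threshold 0.45, parabolic lag interpolation.  Because a periodic signal
scores near-equally at twice its period, a subharmonic-descent step
prefers the half lag when it carries a comparable maximum, and a second
pass re-searches frames deviating more than a third of an octave from
the track median.  Accuracy on clean tones is better than 0.1 Hz; the
white-noise unvoiced rate exceeds 90%.

**CPPS.**  Frames of two pitch-floor periods (33 ms) at a 2 ms step,
pre-emphasis above 50 Hz, Gaussian window, FFT at the next power of two
above twice the window.  The cepstrum is reported as
20·log10|FFT(log-power-spectrum)|; magnitudes are smoothed first across
time (10 ms) then across quefrency (1 ms) in the linear domain, with no
trend subtraction before smoothing.  The peak is searched within
quefrencies 1/330–1/60 s with parabolic interpolation; the trend is a
Theil–Sen straight line fitted from 1 ms to the longest quefrency (the
nominal "0–0.001 s" trend-range convention printed in some parameter
listings would exclude the whole peak region and is read as the
complementary interval).  The per-sample value is the mean over frames
whose prominence exceeds the 0.05 tolerance; the aggregation of frame
values to the sample scalar is unstated in the motivating description,
and the arithmetic mean is used.  On this cepstral scale, absolute CPPS
values differ from tool-specific conventions; all contracts are
relative (monotone degradation with aspiration, gain invariance within
0.1 dB, ≥ 15 dB separation between periodic trains and noise).

**Open quotient.**  The EGG is high-passed at 20 Hz (larynx-movement
drift) and low-passed at 4 kHz (sensor noise; the symmetric zero-phase
filter does not move edge centers) before differencing.  Contacting
instants are midpoints of runs where the dEGG exceeds half its maximum;
this is robust both for sharp pulses and for plateau-like derivatives
(a symmetric triangle wave yields OQ 0.5 exactly).  DECOM: period from
the parabolic-refined autocorrelation peak of the rectified dEGG;
closed phase from each contacting instant to the midpoint of the next
sub-half-minimum run (the de-contacting event); OQ = 1 − closed/T.
Howard: closed phase from the contacting instant to the point where the
EGG falls through `min + 0.3·(max − min)` of that cycle, linearly
interpolated.  The 3:7 threshold orientation is configurable; the
default (closed while above the 30% level) recovers the construction
within 0.01 and sits ~0.01 below DECOM, matching the published
behaviour of the two schemes.  Cycles without a resolvable
de-contacting event are skipped and counted; samples with > 50% skips
are flagged rather than averaged.

**Perturbation measures.**  Cycle anchors come from a peak walk on the
fundamental band (0.75–1.3 f0): one peak per cycle by construction, so
noise cannot add or drop cycles.  Periods are then measured by
waveform matching on the raw signal — a Hann-tapered single-cycle
template cross-correlated against the next cycle (±25% lag search,
parabolic refinement).  The taper keeps the effective span inside one
cycle (a rectangular full-cycle window smooths the very jitter being
measured) and cancels the edge-truncation bias of the correlation
peak.  Jitter is the mean absolute consecutive period difference over
the mean period; PSD is the period standard deviation.  Per-cycle
amplitudes are cycle RMS values of the raw waveform (single-sample
peaks carry a pitch-dependent noise floor under strong aspiration);
shimmer is reported in % and dB.  At very low SNR (severely breathy
voices) the measured jitter and shimmer include an irreducible
estimation floor that grows with the noise — a property shared by any
waveform-based perturbation estimator, and visible as a saturation of
the composite ABI at the extreme end of the breathiness range.

**Spectral noise measures.**  HNR splits a Hann spectrum into a comb of
harmonic windows (width growing with harmonic number, since period
perturbation broadens high harmonics) against the 0–4.5 kHz residual;
the f0 is first sharpened against the strongest of the first three
spectral harmonics so the comb stays aligned across the band.  H1−H2 is
the level difference of the first two harmonics.  GNE resamples to
10 kHz, splits 0–4.5 kHz into 21 Hann bands of 1 kHz, high-passes the
Hilbert envelopes at 600 Hz (removing the shared cycle-rate loudness
modulation so coherence reflects excitation fine structure), and takes
the maximum correlation over band pairs separated by more than a full
band width — overlapping bands share noise and would correlate
trivially.  Hfno is the energy above 6 kHz relative to total, in dB.

**ABI, CDH, CDH+ABI.**  The three index equations are evaluated exactly
as printed, with no clipping and no intercept for CDH/CDH+ABI; finite
differences reproduce every coefficient to 1e-9.  Singing material
provides no usable connected speech, so one sustained signal feeds all
nine ABI sub-measures.  Because this implementation's sub-measure
scales differ from those of the original ABI tooling, absolute ABI
values are not comparable across implementations; the tested contracts
are the exact equation arithmetic and the qualitative behaviour
(upward trend with breathiness, positive cohort correlation).

**Ratings and statistics.**  Two half-point scores average onto a
17-value 0.25-step grid and classify as <0.75 / ≤1.5 / ≤2.25 / ≤3.25 /
≤4 (three grid values in each extreme class).  Inter-rater deviation is
binned in half-point steps (exact / 1 / 2–3 / 4–5 / 6–8), percentages
rounded to one decimal; with the reported deviation counts the 2–3-step
bin rounds to 11.8% directly and to 11.9% as the complement of the
other rounded bins — the reporting convention evidently used, so the
acceptance script reports the complement.  Pearson/Spearman run through
scipy with t-distribution p-values (n − 2 df, rank-tie corrected) and
are cross-checked against direct formulas to 1e-12; samples with
flagged features are excluded pairwise with n reported.  Index
refitting is ordinary least squares with the intercept suppressed by
default (the printed indices have none) and classical standard
errors/p-values.

**Respiration.**  Traces are low-passed at 40 Hz with a zero-phase
order-6 Butterworth (passband < 10 Hz within ±1 dB, ≥ 20 dB at 50 Hz,
extrema timing preserved) and decimated to 100 Hz.  Cycles are
alternating extrema with a 1 s minimum separation and 5% range
prominence.  Stage segmentation — a heuristic quantifying a pattern
usually assessed visually — ends stage 1 at the local maximum within
2 s before phonation onset, stops the declining segment where the 1-s
look-ahead decrease falls below 2% of the accumulated drop, splits
stages 2/3 at the two-piece linear-fit breakpoint (prefix-sum
implementation, verified against an exhaustive scan; each piece at
least 0.5 s), starts stage 4 where the local slope falls below 10% of
the stage-3 slope, and flags stages 2–3 as merged when |slope3| <
1.5·|slope2|.  All thresholds are exposed and carry no claim of
physiological optimality.

**Phonation duration.**  The span between the first and last 50 ms
frame whose RMS exceeds the peak frame level minus 25 dB, rounded to
0.1 s; the relative threshold makes the measure gain-invariant.
Glissando and arpeggio trials are excluded upstream.

## Segmentation conventions

2-second windows are cut consecutively with the trailing remainder
discarded, numbered with zero-padded labels continuing across
participants (a second participant starts at the next free index).
Note one inconsistency in the motivating material: a 464 s processed
recording implies 232 windows by the floor rule, yet the published
numbering spans 231 labels; this package follows the floor rule.

## Synthetic cohort for end-to-end checks

`pipeline.gen_cohort` draws per-sample breathiness uniformly on [0, 1],
pitch from a trial mixture (60% comfortable 200–300 Hz, 20% low
150–200 Hz, 20% high 300–400 Hz, log-uniform within bands), intensity
±6 dB, and OQ scatter of sd 0.02 around the breathiness map — the
nuisance variance without which CPPS would be an unrealistically clean
single predictor.  Ratings are simulated at truth `4·b` with noise sd
0.3 per rater.  Analysis runs at 16 kHz, which halves compute without
touching any band the measures use (CPPS analyses to 5 kHz, GNE to
4.5 kHz, Hfno to the 6–8 kHz octave).  On 400 such samples the Pearson
correlations reproduce the expected structure: CPPS strongly negative,
DOQ/HOQ/CDH strongly positive, ABI moderately positive, and CDH+ABI at
least as strong as CPPS alone.

## Known limitations

* One latent breathiness scalar drives all expressions; real multi-
  cause covariance (and therefore the exact ranking of composite
  indices) is only partially reproduced.
* Absolute CPPS and ABI values are scale-convention dependent and not
  interchangeable with other tools' outputs; comparisons should stay
  within one pipeline.
* ABI saturates at extreme synthetic breathiness as perturbation
  estimation degrades with SNR.
* The respiration stage segmenter is a formalized heuristic; its
  thresholds are design choices, not fitted constants.
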