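# breathvoice

Multi-sensor analysis of breathiness in the singing voice: from paired
condenser-microphone (CM) and electroglottograph (EGG) recordings — plus
respiratory-effort traces and perceptual ratings — to the acoustic and
glottal features that track perceived breathiness, and to composite
linear indices built from them.

It is written for voice scientists, vocal pedagogues and speech-signal
engineers who want a tested, scriptable pipeline for questions like: how
well does smoothed cepstral peak prominence track perceived breathiness
in singing? does the vocal-fold open quotient rise with it? does a
microphone remain a reliable pitch sensor as the voice gets breathier?

## What it computes

Per 2-second paired sample:

* **PD / MPD** — pitch difference between CM and EGG f0 estimates, in Hz
  and on the mel scale (mel = 2595·log10(1 + f/700)); an
  autocorrelation tracker with octave-cost candidate scoring runs on
  both channels.
* **CPPS** — smoothed cepstral peak prominence: the height (dB) of the
  cepstral peak in the 60–330 Hz quefrency range above a robust straight
  trend line, after time- and quefrency-smoothing of the cepstrogram.
* **DOQ / HOQ** — vocal-fold open quotient from the EGG derivative
  (dEGG): DOQ by the DECOM scheme (closing-peak to opening-peak against
  a correlation-based period), HOQ by the Howard scheme (closing peak to
  the 3:7 amplitude crossing).  CQ + OQ = 1 throughout.
* **ABI** — the nine-variable Acoustic Breathiness Index, evaluated with
  its published coefficients over CPPS, jitter, shimmer (%, dB), GNE,
  high-frequency noise, HNR, H1−H2 and period SD:

  ABI = (5.0447730915 − 0.172·CPPS − 0.193·Jit − 1.283·GNEmax −
  0.396·Hfno + 0.01·HNR + 0.017·(H1−H2) + 1.473·Shim-dB − 0.088·Shim −
  68.295·PSD) × 2.9257400394

* **CDH and CDH+ABI** — composite breathiness indices combining
  microphone and EGG information:

  CDH = −0.20688984·CPPS − 3.21878076·DOQ + 9.56627174·HOQ
  CDH+ABI = −0.06959419·CPPS − 3.26429585·DOQ + 8.27435347·HOQ + 0.2633933·ABI

Around these: WAV I/O (16/24/32-bit PCM and float), 2-s segmentation
with continuous numbering, respiratory low-pass filtering and
cycle/stage analysis, phonation-duration measurement, rating averaging
with the 5-class taxonomy, inter-rater agreement tables, Pearson and
Spearman correlation analysis, and OLS refitting of index coefficients.

A first-class synthetic-data module (`breathvoice.synthdata`) generates
paired voice/EGG signals with controllable breathiness and open
quotient, respiratory traces with the four-stage thoracic pattern, and
simulated half-point raters, so every stage is testable without studio
recordings.

## Worked example

```python
from breathvoice import SynthParams, cpps, oq_decom, oq_howard
from breathvoice.synthdata import breathiness_to_oq, gen_voice, gen_egg

for level in (0.0, 0.25, 0.5, 0.75, 1.0):
    v = gen_voice(SynthParams(f0_hz=220.0, breathiness_level=level,
                              oq_target=breathiness_to_oq(level),
                              sample_rate=16000.0, seed=3))
    print(level, round(cpps(v)[0], 2))
```

prints

```
0.0  13.58
0.25 11.52
0.5  10.21
0.75  8.52
1.0   7.26
```

— CPPS falls monotonically as aspiration noise erodes the cepstral
peak.  The same signals' EGG channels recover their open-quotient
targets (DECOM / Howard at target 0.55: 0.5513 / 0.5416, from 219
detected cycles).  `examples/` holds one short script per capability,
including a full cohort correlation analysis
(`04_cohort_correlations.py`) whose output reproduces the expected sign
structure: CPPS negative, DOQ/HOQ/ABI/CDH/CDH+ABI positive, with the
composite indices among the strongest correlates.

A thin CLI wraps the pipeline: `breathvoice synth` (54-trial protocol
dataset with ground truth and simulated ratings), `breathvoice extract`
(features.csv) and `breathvoice analyze` (correlation report, class
descriptives, agreement table, refitted index model).

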