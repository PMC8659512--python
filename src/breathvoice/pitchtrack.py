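"""Fundamental-frequency estimation and microphone-vs-EGG pitch comparison.

The tracker is a normalized-autocorrelation method in the Boersma style:
per-frame autocorrelation corrected for the analysis window, candidate
peaks penalized by an octave cost, a voicing threshold on the best
candidate, and parabolic interpolation of the winning lag.

The per-sample pitch difference (PD) is the mean voiced f0 of the
microphone channel minus that of the EGG channel; MPD is the same
difference after converting the two means to the mel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import MonoSignal, SignalError, VoiceSample


@dataclass
class PitchTrack:
    times: np.ndarray
    f0: np.ndarray            # Hz; NaN on unvoiced frames
    voiced: np.ndarray        # boolean per frame
    fmin: float
    fmax: float
    time_step: float

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    @property
    def mean_f0(self) -> float:
        v = self.voiced_f0
        return float(np.mean(v)) if v.size else float("nan")


@dataclass
class PitchComparison:
    """Per-sample CM-minus-EGG pitch difference in Hz (PD) and mel (MPD)."""

    pd_hz: float
    mpd_mel: float
    mean_f0_cm: float
    mean_f0_egg: float
    valid: bool = True

    @property
    def abs_pd_hz(self) -> float:
        return abs(self.pd_hz)

    @property
    def abs_mpd_mel(self) -> float:
        return abs(self.mpd_mel)


def hz_to_mel(f):
    """Mel scale: 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def hz_diff_to_cents(delta_hz: float, ref_hz: float) -> float:
    """Cents spanned by a frequency deviation delta at reference ref:
    1200 * log2((ref + delta) / ref)."""
    if ref_hz <= 0:
        raise SignalError("reference frequency must be positive")
    return 1200.0 * np.log2((ref_hz + delta_hz) / ref_hz)


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, i, i+1); returns (offset, value)."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0, float(y[i])
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(d), float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d)


def estimate_f0(signal: MonoSignal, fmin: float = 60.0, fmax: float = 1600.0,
                time_step: float = 0.01, voicing_threshold: float = 0.45,
                octave_cost: float = 0.01,
                silence_threshold: float = 0.03) -> PitchTrack:
    """Autocorrelation pitch track with voicing decision.

    Frames of three fmin periods are Hann-windowed; the frame
    autocorrelation is normalized by the window autocorrelation, candidate
    maxima in [1/fmax, 1/fmin] are scored with an octave cost favouring
    shorter lags, and the winning lag is refined parabolically.
    """
    fs = signal.sample_rate
    if fmax >= fs / 2:
        fmax = fs / 2 - 1
    win = int(round(3.0 / fmin * fs))
    if len(signal) < win:
        raise SignalError(
            f"signal too short for pitch analysis: need {win} samples, got {len(signal)}"
        )
    hop = max(1, int(round(time_step * fs)))
    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    window = np.hanning(win)
    # window autocorrelation used to undo the taper bias (Boersma correction)
    wspec = np.abs(np.fft.rfft(window, nfft)) ** 2
    wacf = np.fft.irfft(wspec)
    wacf /= wacf[0]

    lag_min = max(2, int(np.floor(fs / fmax)))
    lag_max = int(np.ceil(fs / fmin))
    x = signal.samples
    global_peak = float(np.max(np.abs(x))) if x.size else 0.0

    starts = np.arange(0, x.size - win + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(frames * window, nfft, axis=1)) ** 2
    acf = np.fft.irfft(spec, axis=1)

    times = (starts + win / 2.0) / fs
    f0 = np.full(starts.size, np.nan)
    voiced = np.zeros(starts.size, dtype=bool)
    lags = np.arange(lag_max + 2)
    for i in range(starts.size):
        a = acf[i]
        if a[0] <= 0:
            continue
        local_peak = float(np.max(np.abs(frames[i])))
        if global_peak > 0 and local_peak < silence_threshold * global_peak:
            continue
        r = a[: lag_max + 2] / a[0]
        r = r / np.maximum(wacf[: lag_max + 2], 1e-6)
        seg = r[lag_min:lag_max + 1]
        # local maxima of the normalized autocorrelation
        cand = np.where((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))[0] + 1
        if cand.size == 0:
            continue
        cand_lags = lags[lag_min + cand]
        strengths = seg[cand] - octave_cost * np.log2(fmin * cand_lags / fs)
        best = int(cand[np.argmax(strengths)])
        if seg[best] < voicing_threshold:
            continue
        # subharmonic descent: a periodic signal scores (near-)equally at
        # twice its period, so prefer the half lag whenever it carries a
        # comparable maximum
        j = lag_min + best
        while True:
            half = j // 2
            if half < lag_min:
                break
            w0 = max(lag_min, int(half * 0.9))
            w1 = min(lag_max, int(np.ceil(half * 1.1))) + 1
            if w1 <= w0 + 1:
                break
            k = w0 + int(np.argmax(r[w0:w1]))
            if r[k] > 0.85 * r[j] and r[k] > voicing_threshold:
                j = k
            else:
                break
        off, _ = _parabolic(r, j)
        lag = j + off
        f = fs / lag
        if fmin <= f <= fmax:
            f0[i] = f
            voiced[i] = True

    # second pass: octave-error cleanup against the track median.  Frames
    # deviating by more than ~a third of an octave re-search their
    # autocorrelation in a restricted lag band around the median period.
    if np.sum(voiced) >= 3:
        med = float(np.median(f0[voiced]))
        for i in np.where(voiced)[0]:
            if abs(np.log2(f0[i] / med)) <= 0.35:
                continue
            a = acf[i]
            r = a[: lag_max + 2] / a[0]
            r = r / np.maximum(wacf[: lag_max + 2], 1e-6)
            lo = max(lag_min, int(fs / (med * 2 ** 0.35)))
            hi = min(lag_max, int(np.ceil(fs / (med * 2 ** -0.35))))
            if hi <= lo + 1:
                continue
            j = lo + int(np.argmax(r[lo:hi + 1]))
            if r[j] < voicing_threshold:
                voiced[i] = False
                f0[i] = np.nan
                continue
            off, _ = _parabolic(r, j)
            f = fs / (j + off)
            if fmin <= f <= fmax:
                f0[i] = f
    return PitchTrack(times=times, f0=f0, voiced=voiced,
                      fmin=fmin, fmax=fmax, time_step=time_step)


def compare_pitch(sample: VoiceSample, fmin: float = 60.0, fmax: float = 1600.0,
                  time_step: float = 0.01) -> PitchComparison:
    """PD/MPD between the microphone and EGG channels of one sample.

    A channel with no voiced frame yields an invalid (flagged) comparison
    so the sample can be excluded from correlation rather than zeroed.
    """
    track_cm = estimate_f0(sample.cm, fmin, fmax, time_step)
    track_egg = estimate_f0(sample.egg, fmin, fmax, time_step)
    f_cm, f_egg = track_cm.mean_f0, track_egg.mean_f0
    if np.isnan(f_cm) or np.isnan(f_egg):
        return PitchComparison(np.nan, np.nan, f_cm, f_egg, valid=False)
    pd = f_cm - f_egg
    mpd = float(hz_to_mel(f_cm) - hz_to_mel(f_egg))
    return PitchComparison(pd, mpd, f_cm, f_egg, valid=True)
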