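"""Phonation-duration measurement for sustained trials.

Duration is the span between the first and last analysis frame whose RMS
level exceeds the trial's peak frame level minus a relative threshold
(default 25 dB), rounded to one decimal.  Glissando and arpeggio trials
are excluded upstream because in-trial pitch changes confound duration.
The threshold is relative to the peak, so the measure is gain-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MonoSignal


@dataclass
class DurationResult:
    duration_s: float            # rounded to 0.1 s
    trial_id: str = ""
    threshold_db_below_peak: float = 25.0
    silent: bool = False


def measure_phonation(signal: MonoSignal, threshold_db_below_peak: float = 25.0,
                      frame_s: float = 0.05, hop_s: float = 0.01,
                      trial_id: str = "") -> DurationResult:
    """Relative-energy phonation detector.

    All-silent input yields duration 0.0 with the silent flag set rather
    than an error.
    """
    fs = signal.sample_rate
    win = max(1, int(round(frame_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    x = signal.samples
    if x.size < win:
        return DurationResult(0.0, trial_id, threshold_db_below_peak, silent=True)
    starts = np.arange(0, x.size - win + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    rms = np.sqrt(np.mean(np.square(frames), axis=1))
    peak = float(np.max(rms))
    if peak <= 0:
        return DurationResult(0.0, trial_id, threshold_db_below_peak, silent=True)
    level = peak * 10.0 ** (-threshold_db_below_peak / 20.0)
    above = np.where(rms > level)[0]
    if above.size == 0:
        return DurationResult(0.0, trial_id, threshold_db_below_peak, silent=True)
    dur = (above[-1] - above[0]) * hop_s + frame_s
    return DurationResult(round(dur, 1), trial_id, threshold_db_below_peak)
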