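"""Respiratory-effort trace analysis: cycle detection and four-stage
thoracic pattern segmentation.

A respiratory effort transducer records torso circumference; its content
of interest sits below 10 Hz (resting breathing near 0.2-0.3 Hz).  During
a sustained phonation trial the thoracic trace typically shows four
stages: (1) expansion to a local maximum just before phonation onset,
(2) a slow linear decrease, (3) a distinctly faster collapse, and (4) a
plateau at a local minimum.  The segmentation here quantifies that
pattern with exposed thresholds and confidence flags; it is a heuristic
formalization of what is usually assessed visually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .audioio import lowpass_resp
from .core import MonoSignal, SignalError

#: analysis rate after decimation; respiratory content lives below 10 Hz
ANALYSIS_RATE = 100.0

#: stage 4 starts when the local slope falls below this fraction of the
#: stage-3 slope
STAGE4_SLOPE_FRACTION = 0.1

#: stages 2 and 3 are flagged as merged when |slope3| / |slope2| is below this
MERGE_RATIO = 1.5


@dataclass
class RespTrace:
    signal: MonoSignal
    site: str = "thoracic"
    cycles: list = field(default_factory=list)


@dataclass
class StageSegmentation:
    """Boundaries (stage-1 end, stage-2/3 breakpoint, stage-4 start) and
    per-stage linear-fit slopes."""

    boundaries: tuple[float, float, float]
    slopes: dict[str, float]
    merged_23: bool = False
    flagged: bool = False
    note: str = ""


def _prepare(trace: RespTrace) -> MonoSignal:
    sig = lowpass_resp(trace.signal)
    fs = sig.sample_rate
    if fs > ANALYSIS_RATE:
        factor = int(round(fs / ANALYSIS_RATE))
        x = sps.resample_poly(sig.samples, 1, factor)
        return MonoSignal(x, fs / factor)
    return sig


def detect_resp_cycles(trace: RespTrace, min_period_s: float = 1.0) -> list[tuple[float, float]]:
    """Respiratory cycles as (inhale-peak time, exhale-trough time) pairs.

    Local maxima and minima are detected on the low-passed, decimated
    trace with a minimum separation of min_period_s and a prominence of 5%
    of the trace range; peaks and troughs are paired alternately.
    """
    if trace.signal.duration_s < 2 * min_period_s:
        raise SignalError("trace shorter than two minimum periods")
    sig = _prepare(trace)
    x = sig.samples
    fs = sig.sample_rate
    rng_amp = float(np.max(x) - np.min(x))
    if rng_amp <= 1e-9 * max(1.0, float(np.max(np.abs(x)))):
        return []
    dist = max(1, int(min_period_s * fs))
    prom = 0.05 * rng_amp
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = sps.find_peaks(-x, distance=dist, prominence=prom)
    cycles = []
    for p in peaks:
        later = troughs[troughs > p]
        if later.size:
            cycles.append((p / fs, later[0] / fs))
    return cycles


def _two_piece_sse(y: np.ndarray, min_seg: int = 2) -> tuple[int, float]:
    """Breakpoint (index) minimizing the summed SSE of two linear fits.

    Evaluated for every candidate split with O(n) prefix sums; equivalent
    to an exhaustive scan.
    """
    n = y.size
    t = np.arange(n, dtype=float)

    def _sse_prefix(tt, yy):
        # SSE of a linear fit on every prefix, via running sums
        c = np.arange(1, tt.size + 1, dtype=float)
        st, sy = np.cumsum(tt), np.cumsum(yy)
        stt, sty, syy = np.cumsum(tt * tt), np.cumsum(tt * yy), np.cumsum(yy * yy)
        denom = c * stt - st ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (c * sty - st * sy) / denom
            inter = (sy - slope * st) / c
            sse = (syy - 2 * slope * sty - 2 * inter * sy
                   + slope ** 2 * stt + 2 * slope * inter * st + inter ** 2 * c)
        sse[~np.isfinite(sse)] = 0.0
        return np.maximum(sse, 0.0)

    left = _sse_prefix(t, y)
    right = _sse_prefix(t[::-1], y[::-1])[::-1]
    best_k, best = -1, np.inf
    for k in range(min_seg, n - min_seg):
        total = left[k - 1] + right[k]
        if total < best:
            best, best_k = total, k
    return best_k, float(best)


def _slope(y: np.ndarray, fs: float) -> float:
    if y.size < 2:
        return 0.0
    t = np.arange(y.size) / fs
    return float(np.polyfit(t, y, 1)[0])


def segment_stages(trace: RespTrace, phonation_onset_t: float,
                   max_pre_onset_s: float = 2.0) -> StageSegmentation:
    """Segment the four-stage thoracic pattern around one phonation trial.

    Stage 1 ends at the local maximum within max_pre_onset_s before the
    phonation onset; the declining segment from there to its minimum is
    split into stages 2 and 3 at the breakpoint minimizing the two-piece
    linear-fit residual; stage 4 begins where the local slope magnitude
    falls below 10% of the stage-3 slope.  If no pre-onset maximum exists
    the result is flagged with no boundaries.
    """
    sig = _prepare(trace)
    x = sig.samples
    fs = sig.sample_rate
    i_on = int(round(phonation_onset_t * fs))
    lo = max(0, i_on - int(max_pre_onset_s * fs))
    window = x[lo:i_on + 1]
    if window.size < 3:
        return StageSegmentation((np.nan,) * 3, {}, flagged=True,
                                 note="no pre-onset window")
    peaks, _ = sps.find_peaks(window)
    if peaks.size == 0:
        if np.argmax(window) == window.size - 1 and window.size > 2:
            i_max = lo + window.size - 1
        else:
            return StageSegmentation((np.nan,) * 3, {}, flagged=True,
                                     note="no pre-onset local maximum")
    else:
        i_max = lo + peaks[np.argmax(window[peaks])]

    # declining segment: from the pre-onset max until the trace stops
    # falling (the decrease over a 1 s look-ahead drops below 2% of the
    # accumulated drop, or the trace turns upward) — robust against later
    # tidal dips undercutting the plateau
    tail = x[i_max:]
    w = max(2, int(1.0 * fs))
    i_min_rel = int(np.argmin(tail))
    for j in range(5, tail.size - w):
        accumulated = tail[0] - tail[j]
        decrease = tail[j] - tail[j + w]
        if accumulated > 0 and (decrease < 0.02 * accumulated or tail[j + w] > tail[j]):
            i_min_rel = j
            break
    if i_min_rel < 5:
        return StageSegmentation((np.nan,) * 3, {}, flagged=True,
                                 note="no decline after the pre-onset maximum")
    decline = tail[:i_min_rel + 1]
    # keep at least half a second in each piece so corner samples cannot
    # masquerade as a stage
    k, _ = _two_piece_sse(decline, min_seg=max(2, int(0.5 * fs)))
    t1 = i_max / fs
    t2 = (i_max + k) / fs
    slope2 = _slope(decline[:k], fs)
    slope3 = _slope(decline[k:], fs)

    # stage 4: local slope flattens out relative to stage 3
    win = max(2, int(0.3 * fs))
    start4 = i_max + i_min_rel
    seg = x[i_max + k:]
    for j in range(seg.size - win):
        if abs(_slope(seg[j:j + win], fs)) < STAGE4_SLOPE_FRACTION * abs(slope3):
            start4 = i_max + k + j + win // 2
            break
    t3 = start4 / fs
    slope4 = _slope(x[start4:start4 + int(2 * fs)], fs)

    merged = abs(slope3) < MERGE_RATIO * abs(slope2)
    return StageSegmentation(
        boundaries=(t1, t2, t3),
        slopes={"stage2": slope2, "stage3": slope3, "stage4": slope4},
        merged_23=merged,
    )
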