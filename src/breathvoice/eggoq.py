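"""Open-quotient extraction from the electroglottographic (EGG) signal.

The EGG waveform rises with vocal-fold contact.  Its first derivative
(dEGG) has a sharp positive peak at each contacting (closing) instant and
a negative peak at de-contacting.  Two estimators are provided:

* DECOM: the cycle period comes from the autocorrelation of the rectified
  dEGG (a correlation-based period of the closing-peak train); the closed
  phase runs from each closing peak to the following negative dEGG peak;
  OQ = 1 - closed / T per cycle.

* Howard: the closed phase starts at the dEGG positive peak and ends where
  the EGG amplitude falls through the 3:7 level of the cycle's
  peak-to-peak amplitude (cycle minimum + 0.3 * (max - min)), with linear
  interpolation between the straddling samples; OQ = 1 - closed / T.

Open and contact quotient are complementary: CQ + OQ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import MonoSignal, SignalError

#: orientation of the 3:7 threshold: fraction of peak-to-peak above the
#: cycle minimum at which the closed phase is taken to end
HOWARD_THRESHOLD = 0.3


@dataclass
class CycleMarks:
    closing_instants: np.ndarray    # seconds, dEGG positive peaks
    opening_instants: np.ndarray    # seconds
    periods: np.ndarray             # seconds per cycle


@dataclass
class OQSeries:
    per_cycle_oq: np.ndarray
    method: str
    n_cycles: int = 0
    n_skipped: int = 0
    flagged: bool = False

    @property
    def mean_oq(self) -> float:
        return float(np.mean(self.per_cycle_oq)) if self.per_cycle_oq.size else float("nan")


def _preprocess(signal: MonoSignal) -> np.ndarray:
    """High-pass at 20 Hz to strip larynx-movement drift, plus a gentle
    low-pass that suppresses wide-band sensor noise without moving the
    symmetric contacting/de-contacting edges."""
    fs = signal.sample_rate
    x = signal.samples
    sos_hp = sps.butter(2, 20.0, btype="highpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x)
    lp = min(4000.0, 0.45 * fs)
    sos_lp = sps.butter(4, lp, fs=fs, output="sos")
    return sps.sosfiltfilt(sos_lp, x)


def degg(signal: MonoSignal, preprocess: bool = True) -> MonoSignal:
    """First difference scaled by the sample rate (units per second),
    after drift removal."""
    x = _preprocess(signal) if preprocess else signal.samples
    d = np.diff(x, prepend=x[0]) * signal.sample_rate
    return MonoSignal(d, signal.sample_rate)


def _period_from_degg(d: np.ndarray, fs: float, f0_hint: float) -> float:
    """Correlation-based period: lag maximizing the autocorrelation of the
    rectified dEGG, searched around 1/f0_hint, refined parabolically."""
    pos = np.maximum(d, 0.0)
    pos = pos - pos.mean()
    n = pos.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acf = np.fft.irfft(np.abs(np.fft.rfft(pos, nfft)) ** 2)
    lag_lo = max(2, int(0.5 * fs / f0_hint))
    lag_hi = min(int(1.5 * fs / f0_hint), n - 2)
    if lag_hi <= lag_lo + 1:
        raise SignalError("signal too short to estimate the cycle period")
    seg = acf[lag_lo:lag_hi]
    i = int(np.argmax(seg)) + lag_lo
    y0, y1, y2 = acf[i - 1], acf[i], acf[i + 1]
    denom = y0 - 2 * y1 + y2
    off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return (i + off) / fs


def _run_midpoints(mask: np.ndarray, min_gap: int) -> np.ndarray:
    """Midpoints (integer indices) of True runs, with runs separated by
    gaps shorter than min_gap merged — robust both for sharp dEGG peaks
    and for plateau-like derivatives (e.g. triangle waves)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    breaks = np.where(np.diff(idx) > min_gap)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return ((starts + ends) // 2).astype(int)


def _closing_peaks(d: np.ndarray, fs: float, period_s: float) -> np.ndarray:
    """Contacting instants: midpoints of the runs where the dEGG exceeds
    half its maximum (one run per cycle; filter ringing after the
    de-contacting fall stays below the threshold).  Ties inside a run
    resolve to the run midpoint."""
    level = 0.5 * float(np.max(d))
    if level <= 0:
        return np.array([], dtype=int)
    min_gap = max(1, int(0.25 * period_s * fs))
    mids = _run_midpoints(d > level, min_gap)
    # enforce one instant per period
    keep = []
    for m in mids:
        if not keep or m - keep[-1] > 0.6 * period_s * fs:
            keep.append(m)
    return np.asarray(keep, dtype=int)


def _opening_instant(window: np.ndarray, fs: float, period_s: float):
    """De-contacting instant within one cycle window: midpoint of the run
    where the dEGG falls below half its most negative value."""
    if window.size < 3:
        return None
    floor = 0.5 * float(np.min(window))
    if floor >= 0:
        return None
    min_gap = max(1, int(0.25 * period_s * fs))
    mids = _run_midpoints(window < floor, min_gap)
    if mids.size == 0:
        return None
    return int(mids[0])


def cycle_marks(signal: MonoSignal, f0_hint: float) -> CycleMarks:
    """Closing/opening instants and per-cycle periods from the dEGG."""
    fs = signal.sample_rate
    d = degg(signal).samples
    period = _period_from_degg(d, fs, f0_hint)
    closings = _closing_peaks(d, fs, period)
    openings = []
    for c in closings[:-1]:
        w = d[c + 1:c + int(period * fs)]
        j = _opening_instant(w, fs, period)
        if j is not None:
            openings.append(c + 1 + j)
    closings_t = closings / fs
    return CycleMarks(
        closing_instants=closings_t,
        opening_instants=np.asarray(openings, dtype=float) / fs,
        periods=np.diff(closings_t),
    )


def oq_decom(signal: MonoSignal, f0_hint: float) -> OQSeries:
    """Open quotient by the dEGG-peak method with a correlation-based
    period.  Cycles whose opening peak is not resolvable are skipped and
    counted; a sample with more than half its cycles skipped is flagged."""
    fs = signal.sample_rate
    d = degg(signal).samples
    period = _period_from_degg(d, fs, f0_hint)
    closings = _closing_peaks(d, fs, period)
    if closings.size < 3:
        raise SignalError("need at least 3 cycles for OQ analysis")
    oqs, skipped = [], 0
    win = int(period * fs)
    for c in closings[:-1]:
        w = d[c + 1:c + win]
        j = _opening_instant(w, fs, period)
        if j is None:               # no credible de-contacting event
            skipped += 1
            continue
        closed = (j + 1) / fs
        oq = 1.0 - closed / period
        if 0.0 < oq < 1.0:
            oqs.append(oq)
        else:
            skipped += 1
    n_total = closings.size - 1
    return OQSeries(per_cycle_oq=np.asarray(oqs), method="DECOM",
                    n_cycles=len(oqs), n_skipped=skipped,
                    flagged=skipped > 0.5 * max(1, n_total))


def oq_howard(signal: MonoSignal, f0_hint: float,
              threshold: float = HOWARD_THRESHOLD) -> OQSeries:
    """Open quotient by the Howard method: dEGG closing peak to the 3:7
    amplitude crossing on the EGG waveform, linearly interpolated."""
    fs = signal.sample_rate
    x = _preprocess(signal)
    d = np.diff(x, prepend=x[0]) * fs
    period = _period_from_degg(d, fs, f0_hint)
    closings = _closing_peaks(d, fs, period)
    if closings.size < 3:
        raise SignalError("need at least 3 cycles for OQ analysis")
    oqs, skipped = [], 0
    for c0, c1 in zip(closings[:-1], closings[1:]):
        cyc = x[c0:c1]
        t_cycle = (c1 - c0) / fs
        cmin, cmax = float(cyc.min()), float(cyc.max())
        if cmax <= cmin:
            skipped += 1
            continue
        level = cmin + threshold * (cmax - cmin)
        high = cyc >= cmin + 0.7 * (cmax - cmin)
        if not np.any(high):
            skipped += 1
            continue
        start = int(np.argmax(high))        # first sample on the plateau
        below = np.where(cyc[start:] < level)[0]
        if below.size == 0:
            skipped += 1
            continue
        j = start + below[0]
        # linear interpolation between the straddling samples
        y0, y1 = cyc[j - 1], cyc[j]
        frac = (y0 - level) / (y0 - y1) if y0 != y1 else 0.0
        closed = (j - 1 + frac) / fs
        oq = 1.0 - closed / t_cycle
        if 0.0 < oq < 1.0:
            oqs.append(oq)
        else:
            skipped += 1
    n_total = closings.size - 1
    return OQSeries(per_cycle_oq=np.asarray(oqs), method="HOWARD",
                    n_cycles=len(oqs), n_skipped=skipped,
                    flagged=skipped > 0.5 * max(1, n_total))
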