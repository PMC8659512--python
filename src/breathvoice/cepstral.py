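"""Power cepstrum and smoothed cepstral peak prominence (CPPS).

The power cepstrum of a frame is the Fourier transform of the logarithm of
its power spectrum; for a voiced frame its dominant peak sits at a
quefrency of 1/f0.  CPPS measures the height of that peak above a straight
trend line fitted robustly over quefrency, after the cepstrogram has been
smoothed first across time and then across quefrency.  High values mean
strong periodicity; breathy voice erodes the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import MonoSignal, SignalError

_DB_FLOOR = -200.0


@dataclass(frozen=True)
class CepstralParams:
    """CPPS parametrization (all windows in seconds, frequencies in Hz).

    The trend line is fitted from trend_from_s up to the longest
    representable quefrency: the nominal "0-0.001 s" printed in some
    parameter listings would exclude the whole peak-search region, so the
    conventional reading (0.001 s to the maximum quefrency) is used and
    exposed here.
    """

    pitch_floor: float = 60.0
    time_step: float = 0.002
    max_frequency: float = 5000.0
    preemphasis_from: float = 50.0
    time_avg_window: float = 0.01
    quefrency_avg_window: float = 0.001
    peak_search_fmin: float = 60.0
    peak_search_fmax: float = 330.0
    tolerance: float = 0.05
    trend_from_s: float = 0.001
    trend_points: int = 120

    def __post_init__(self) -> None:
        for name in ("pitch_floor", "time_step", "max_frequency",
                     "time_avg_window", "quefrency_avg_window",
                     "peak_search_fmin", "peak_search_fmax", "trend_from_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_search_fmin >= self.peak_search_fmax:
            raise ValueError("peak search range is empty")


@dataclass
class Cepstrogram:
    quefrencies: np.ndarray       # seconds, shared across frames
    frames: np.ndarray            # (n_frames, n_quefrencies) magnitudes, dB
    frame_times: np.ndarray


def _gaussian_window(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.exp(-0.5 * ((k - (n - 1) / 2) / ((n - 1) / 5.0)) ** 2)


def power_cepstrum(frame: np.ndarray, sample_rate: float,
                   nfft: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Cepstrum of one (already windowed) frame.

    Returns (quefrencies, cepstrum_db): the log-magnitude, in dB, of the
    Fourier transform of the frame's log power spectrum.  An all-zero frame
    yields a flat floored cepstrum instead of a log-of-zero failure.
    """
    frame = np.asarray(frame, dtype=float)
    if nfft is None:
        nfft = 1 << int(np.ceil(np.log2(max(2, 2 * frame.size))))
    spec = np.abs(np.fft.rfft(frame, nfft)) ** 2
    if not np.any(spec > 0):
        q = np.arange(nfft // 2 + 1) / sample_rate
        return q, np.full(nfft // 2 + 1, _DB_FLOOR)
    log_spec = 10.0 * np.log10(spec + 1e-300)
    cep = np.fft.irfft(log_spec, nfft)
    mag = np.abs(cep[: nfft // 2 + 1])
    q = np.arange(nfft // 2 + 1) / sample_rate
    cep_db = 20.0 * np.log10(np.maximum(mag, 10 ** (_DB_FLOOR / 20.0)))
    return q, cep_db


def _theil_sen_trend(q: np.ndarray, y: np.ndarray, n_points: int) -> tuple[float, float]:
    """Theil-Sen slope with median intercept on a subsampled set."""
    if q.size > n_points:
        idx = np.linspace(0, q.size - 1, n_points).astype(int)
        q, y = q[idx], y[idx]
    dq = q[:, None] - q[None, :]
    dy = y[:, None] - y[None, :]
    mask = np.triu(np.ones_like(dq, dtype=bool), k=1) & (dq != 0)
    slope = float(np.median(dy[mask] / dq[mask]))
    intercept = float(np.median(y - slope * q))
    return slope, intercept


def cepstrogram(signal: MonoSignal, params: CepstralParams = CepstralParams()) -> Cepstrogram:
    """Frame-wise power cepstra at the configured time step.

    Frames are pre-emphasized above preemphasis_from, Gaussian-windowed
    over two pitch_floor periods, and analyzed with an FFT of the next
    power of two above twice the window length.
    """
    fs = signal.sample_rate
    win = int(round(2.0 / params.pitch_floor * fs))
    hop = max(1, int(round(params.time_step * fs)))
    x = signal.samples
    if x.size < win + hop:
        raise SignalError("signal too short for cepstral analysis (need >= 2 frames)")
    a = np.exp(-2.0 * np.pi * params.preemphasis_from / fs)
    x = np.concatenate([[x[0] * (1 - a)], x[1:] - a * x[:-1]])

    starts = np.arange(0, x.size - win + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    window = _gaussian_window(win)
    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    spec = np.abs(np.fft.rfft(frames * window, nfft, axis=1)) ** 2
    log_spec = 10.0 * np.log10(spec + 1e-300)
    cep = np.fft.irfft(log_spec, nfft, axis=1)
    mag = np.abs(cep[:, : nfft // 2 + 1])
    q = np.arange(nfft // 2 + 1) / fs
    cep_db = 20.0 * np.log10(np.maximum(mag, 10 ** (_DB_FLOOR / 20.0)))
    times = (starts + win / 2.0) / fs
    return Cepstrogram(quefrencies=q, frames=cep_db, frame_times=times)


def cpps(signal: MonoSignal, params: CepstralParams = CepstralParams()) -> tuple[float, int]:
    """Per-sample smoothed cepstral peak prominence in dB.

    The cepstrogram is smoothed across time (time_avg_window) and then
    across quefrency (quefrency_avg_window) in the linear magnitude domain
    (no trend subtraction before smoothing); each frame's peak is located
    within [1/peak_search_fmax, 1/peak_search_fmin] with parabolic
    interpolation and referred to a straight robust (Theil-Sen) trend line;
    the sample value is the mean over frames whose prominence exceeds the
    tolerance.  Returns (cpps_db, n_frames_used); an unusable input yields
    (nan, 0).
    """
    try:
        cg = cepstrogram(signal, params)
    except SignalError:
        return float("nan"), 0
    fs = signal.sample_rate
    mag = 10 ** (cg.frames / 20.0)
    t_win = max(1, int(round(params.time_avg_window / params.time_step)))
    q_win = max(1, int(round(params.quefrency_avg_window * fs)))
    mag = uniform_filter1d(mag, t_win, axis=0, mode="nearest")
    mag = uniform_filter1d(mag, q_win, axis=1, mode="nearest")
    cep_db = 20.0 * np.log10(np.maximum(mag, 10 ** (_DB_FLOOR / 20.0)))

    q = cg.quefrencies
    lo = np.searchsorted(q, 1.0 / params.peak_search_fmax)
    hi = np.searchsorted(q, 1.0 / params.peak_search_fmin)
    hi = min(hi, q.size - 2)
    if hi <= lo + 1:
        return float("nan"), 0
    trend_lo = np.searchsorted(q, params.trend_from_s)
    q_trend = q[trend_lo:]

    values = []
    for row in cep_db:
        seg = row[lo:hi]
        i = int(np.argmax(seg)) + lo
        # parabolic refinement of peak height and quefrency
        y0, y1, y2 = row[i - 1], row[i], row[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            d = 0.5 * (y0 - y2) / denom
            peak_db = y1 - 0.25 * (y0 - y2) * d
            peak_q = q[i] + d * (q[1] - q[0])
        else:
            peak_db, peak_q = y1, q[i]
        slope, intercept = _theil_sen_trend(q_trend, row[trend_lo:], params.trend_points)
        prom = peak_db - (intercept + slope * peak_q)
        if prom > params.tolerance:
            values.append(prom)
    if not values:
        return float("nan"), 0
    return float(np.mean(values)), len(values)
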