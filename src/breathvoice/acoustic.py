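"""The nine sub-measures of the Acoustic Breathiness Index and the index
itself.

ABI combines CPPS, local jitter, the glottal-to-noise excitation ratio
(GNE), high-frequency noise, a harmonics-to-noise ratio, the H1-H2
harmonic difference, local shimmer (% and dB), and the standard deviation
of the cycle period, in one fixed linear equation.  This module evaluates
the printed equation exactly; only the sub-measures are estimated.

Singing material rarely provides usable connected speech, so one sustained
signal feeds every sub-measure.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import MonoSignal, SignalError
from .pitchtrack import estimate_f0

ABI_INTERCEPT = 5.0447730915
ABI_SCALE = 2.9257400394
ABI_COEFFS = {
    "cpps": -0.172,
    "jit": -0.193,
    "gne_max_4500": -1.283,
    "hfno_6000": -0.396,
    "hnr_d": 0.01,
    "h1_h2": 0.017,
    "shim_db": 1.473,
    "shim": -0.088,
    "psd": -68.295,
}


@dataclass
class AcousticMeasures:
    """The nine ABI inputs; units follow the equation's conventions."""

    cpps: float = float("nan")          # dB
    jit: float = float("nan")           # local jitter, %
    gne_max_4500: float = float("nan")  # ratio in [0, 1]
    hfno_6000: float = float("nan")     # dB re total energy
    hnr_d: float = float("nan")         # dB
    h1_h2: float = float("nan")         # dB
    shim_db: float = float("nan")       # dB
    shim: float = float("nan")          # local shimmer, %
    psd: float = float("nan")           # period standard deviation, s


def abi(m: AcousticMeasures) -> float:
    """Evaluate the printed ABI equation exactly (no clipping).

    Raises if any of the nine measures is absent, naming the missing ones.
    """
    missing = [f.name for f in fields(m) if not np.isfinite(getattr(m, f.name))]
    if missing:
        raise SignalError(f"cannot evaluate ABI; missing measures: {', '.join(missing)}")
    total = ABI_INTERCEPT
    for name, coef in ABI_COEFFS.items():
        total += coef * getattr(m, name)
    return total * ABI_SCALE


def _refine_peak(x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak position and height by parabolic interpolation."""
    if i <= 0 or i >= x.size - 1:
        return float(i), float(x[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    d = 0.5 * (y0 - y2) / denom
    return i + d, float(y1 - 0.25 * (y0 - y2) * d)


def _peak_walk(fund: np.ndarray, fs: float, f0_hint: float) -> np.ndarray:
    """One fundamental-band peak per cycle, walked out from the strongest
    peak with a +-25% period search window — immune to missed or doubled
    cycles that plain peak picking produces under noise."""
    period = fs / f0_hint
    i0 = int(np.argmax(fund))
    peaks = [i0]
    i = i0
    while i + 1.3 * period < fund.size:
        lo, hi = int(i + 0.75 * period), int(i + 1.25 * period)
        j = lo + int(np.argmax(fund[lo:hi]))
        peaks.append(j)
        i = j
    i = i0
    while i - 1.3 * period > 0:
        lo, hi = int(i - 1.25 * period), int(i - 0.75 * period)
        j = lo + int(np.argmax(fund[lo:hi]))
        peaks.insert(0, j)
        i = j
    return np.asarray(peaks)


def _matched_periods(x: np.ndarray, peaks: np.ndarray, fs: float,
                     period: float) -> np.ndarray:
    """Cycle-to-cycle periods by waveform matching on the raw signal.

    For each pair of consecutive anchor instants, the lag maximizing the
    cross-correlation between the two cycle-long raw waveforms (searched
    within +-25% of the nominal period, refined parabolically) is the
    period.  Matching on the full-band waveform keeps fast frequency
    modulation — jitter — unattenuated, while correlating over a whole
    cycle averages additive noise away.
    """
    # Hann-tapered single-cycle template centered on the anchor: the taper
    # keeps the effective span inside one cycle (a rectangular full-cycle
    # window would straddle two periods and smooth the very jitter being
    # measured) and cancels the edge-truncation bias of the correlation
    # peak
    half = max(2, int(0.5 * period))
    dtau = max(2, int(0.25 * period))
    taper = np.hanning(2 * half)
    periods = []
    n = x.size
    for a, b in zip(peaks[:-1], peaks[1:]):
        if a - half < 0 or b + half + dtau >= n:
            continue
        w = x[a - half:a + half] * taper
        seg = x[b - half - dtau:b + half + dtau]
        c = np.correlate(seg, w, mode="valid")
        j = int(np.argmax(c))
        off, _ = _refine_peak(c, j)
        periods.append((b - a) + (off - dtau))
    return np.asarray(periods) / fs


def period_sequence(signal: MonoSignal,
                    f0_hint: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle periods and peak amplitudes.

    Anchor instants are the positive peaks of the signal band-passed
    around the fundamental, walked cycle by cycle so no cycle is missed
    or doubled under noise; the periods themselves come from raw-waveform
    matching between consecutive cycles (see _matched_periods), and the
    per-cycle amplitudes are the fundamental-band peak heights.  Needs
    >= 3 cycles.
    """
    fs = signal.sample_rate
    x = signal.samples
    if f0_hint is None:
        track = estimate_f0(signal)
        f0_hint = track.mean_f0
        if not np.isfinite(f0_hint):
            raise SignalError("cannot determine f0 for cycle segmentation")
    sos = sps.butter(4, [0.75 * f0_hint, min(1.3 * f0_hint, 0.45 * fs)],
                     btype="bandpass", fs=fs, output="sos")
    fund = sps.sosfiltfilt(sos, x)
    peaks = _peak_walk(fund, fs, f0_hint)
    # drop cycles inside the narrowband filter's edge transients
    margin = 3.0 * fs / f0_hint
    peaks = peaks[(peaks > margin) & (peaks < x.size - margin)]
    if peaks.size < 4:
        raise SignalError("need at least 3 cycles for period analysis")
    periods = _matched_periods(x, peaks, fs, fs / f0_hint)
    if periods.size < 3:
        raise SignalError("need at least 3 cycles for period analysis")
    # per-cycle amplitude: RMS of the raw waveform over the cycle —
    # integrating over the whole cycle keeps the noise floor uniform
    # across pitch, unlike single-sample peak heights
    half = max(1, int(0.5 * fs / f0_hint))
    amps = np.array([
        float(np.sqrt(np.mean(np.square(x[p - half:p + half])))) for p in peaks
    ])
    return periods, amps[1:]


def jitter_local(periods: np.ndarray) -> float:
    """Mean absolute consecutive period difference over the mean period, %."""
    periods = np.asarray(periods, dtype=float)
    if periods.size < 2:
        raise SignalError("need at least 2 periods for jitter")
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)


def shimmer_local(amplitudes: np.ndarray) -> tuple[float, float]:
    """(shimmer %, shimmer dB) over per-cycle peak amplitudes."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise SignalError("need at least 2 amplitudes for shimmer")
    if np.any(a <= 0):
        raise SignalError("amplitudes must be positive")
    pct = float(np.mean(np.abs(np.diff(a))) / np.mean(a) * 100.0)
    db = float(np.mean(np.abs(20.0 * np.log10(a[1:] / a[:-1]))))
    return pct, db


def psd(periods: np.ndarray) -> float:
    """Standard deviation of the cycle periods, in seconds."""
    periods = np.asarray(periods, dtype=float)
    if periods.size < 2:
        raise SignalError("need at least 2 periods")
    return float(np.std(periods, ddof=1))


def _spectrum(signal: MonoSignal) -> tuple[np.ndarray, np.ndarray]:
    x = signal.samples * np.hanning(len(signal))
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(signal), 1.0 / signal.sample_rate)
    return freqs, spec


def _harmonic_bins(freqs: np.ndarray, f0: float, fmax: float,
                   half_width_bins: int = 4) -> np.ndarray:
    """Comb mask around the harmonics of f0; the window widens with the
    harmonic number because period perturbation broadens high harmonics
    proportionally."""
    df = freqs[1] - freqs[0]
    mask = np.zeros(freqs.size, dtype=bool)
    k = 1
    while k * f0 < fmax:
        width = half_width_bins + k
        center = int(round(k * f0 / df))
        lo = max(0, center - width)
        hi = min(freqs.size, center + width + 1)
        mask[lo:hi] = True
        k += 1
    return mask


def _refine_f0_spectral(freqs: np.ndarray, spec: np.ndarray, f0: float) -> float:
    """Sharpen an f0 estimate against the strongest of the first three
    spectral harmonics (parabolically interpolated); a comb aligned this
    way stays on the harmonics across the whole band."""
    df = freqs[1] - freqs[0]
    best_k, best_amp, best_freq = 0, 0.0, f0
    for k in (1, 2, 3):
        center = int(round(k * f0 / df))
        w = max(2, int(round(0.04 * k * f0 / df)))
        lo, hi = max(1, center - w), min(freqs.size - 1, center + w + 1)
        if hi <= lo:
            continue
        j = lo + int(np.argmax(spec[lo:hi]))
        off, amp = _refine_peak(spec, j)
        if amp > best_amp:
            best_k, best_amp, best_freq = k, amp, off * df
    if best_k == 0:
        return f0
    return best_freq / best_k


def hnr_d(signal: MonoSignal, f0: float, band_max: float = 4500.0) -> float:
    """Harmonics-to-noise ratio by a spectral comb split.

    Energy in narrow windows around the harmonics of f0 (up to band_max)
    is the harmonic part; the remainder of the band is noise;
    HNR = 10 log10(Eh / En).
    """
    if f0 <= 0:
        raise SignalError("f0 must be positive")
    freqs, spec = _spectrum(signal)
    f0 = _refine_f0_spectral(freqs, spec, f0)
    band_max = min(band_max, 0.95 * signal.sample_rate / 2)
    band = freqs <= band_max
    harm = _harmonic_bins(freqs, f0, band_max) & band
    eh = float(np.sum(spec[harm]))
    en = float(np.sum(spec[band & ~harm]))
    if en <= 0:
        return float("inf")
    return 10.0 * np.log10(eh / en)


def h1_h2(signal: MonoSignal, f0: float) -> float:
    """Level difference (dB) between the first two harmonics."""
    if f0 <= 0:
        raise SignalError("f0 must be positive")
    freqs, spec = _spectrum(signal)
    df = freqs[1] - freqs[0]
    out = []
    for k in (1, 2):
        center = int(round(k * f0 / df))
        lo, hi = max(0, center - 4), min(freqs.size, center + 5)
        out.append(float(np.max(spec[lo:hi])))
    if out[0] <= 0 or out[1] <= 0:
        raise SignalError("harmonics not present for H1-H2")
    return 10.0 * np.log10(out[0] / out[1])


def gne_max(signal: MonoSignal, bandwidth: float = 4500.0,
            band_width_hz: float = 1000.0, n_bands: int = 21,
            work_rate: float = 10000.0, env_highpass_hz: float = 600.0) -> float:
    """Glottal-to-noise excitation ratio.

    The signal is resampled to 10 kHz and split into Hann-shaped frequency
    bands of width band_width_hz with centers spanning up to `bandwidth`;
    the GNE is the maximum Pearson correlation between Hilbert envelopes
    of band pairs whose centers differ by more than the full band width
    (overlapping bands share noise and would correlate trivially).

    The envelopes are high-passed at env_highpass_hz before correlating:
    slow shared loudness modulation (the cycle-rate rise and fall common
    to every band) is removed, so the coherence reflects the excitation
    fine structure — glottal closure impulses excite all bands in the
    same instant (GNE near 1) while turbulence is incoherent across bands
    (GNE near 0).
    """
    fs = signal.sample_rate
    x = signal.samples
    if fs != work_rate:
        g = np.gcd(int(fs), int(work_rate))
        x = sps.resample_poly(x, int(work_rate) // g, int(fs) // g)
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(n)))
    spec = np.fft.rfft(x, nfft)
    freqs = np.fft.rfftfreq(nfft, 1.0 / work_rate)
    top = min(bandwidth - band_width_hz / 2, work_rate / 2 - band_width_hz / 2)
    centers = np.linspace(band_width_hz / 2, top, n_bands)
    sos_hp = sps.butter(2, env_highpass_hz, btype="highpass", fs=work_rate,
                        output="sos")
    envelopes = []
    for c in centers:
        w = np.zeros(freqs.size)
        in_band = np.abs(freqs - c) <= band_width_hz / 2
        w[in_band] = np.hanning(int(np.sum(in_band)) or 1)
        band_sig = np.fft.irfft(spec * w, nfft)[:n]
        env = np.abs(sps.hilbert(band_sig))
        env = sps.sosfiltfilt(sos_hp, env - env.mean())
        envelopes.append(env)
    best = 0.0
    for i in range(n_bands):
        for j in range(i + 1, n_bands):
            if centers[j] - centers[i] <= band_width_hz:
                continue
            ei, ej = envelopes[i], envelopes[j]
            denom = np.linalg.norm(ei) * np.linalg.norm(ej)
            if denom == 0:
                continue
            best = max(best, float(np.dot(ei, ej) / denom))
    return best


def hf_noise(signal: MonoSignal, cutoff: float = 6000.0) -> float:
    """Energy above the cutoff relative to total energy, in dB."""
    freqs, spec = _spectrum(signal)
    total = float(np.sum(spec))
    if total <= 0:
        raise SignalError("signal has no energy")
    above = float(np.sum(spec[freqs >= cutoff]))
    if above <= 0:
        return -200.0
    return 10.0 * np.log10(above / total)


def measure_all(signal: MonoSignal, cpps_db: float,
                f0_hint: Optional[float] = None) -> AcousticMeasures:
    """All nine ABI inputs from one sustained signal.

    CPPS is passed in (computed by the cepstral module) so the two modules
    stay independent; the remaining eight are measured here.
    """
    periods, amps = period_sequence(signal, f0_hint)
    f0 = 1.0 / float(np.median(periods))
    shim_pct, shim_db_val = shimmer_local(amps)
    return AcousticMeasures(
        cpps=cpps_db,
        jit=jitter_local(periods),
        gne_max_4500=gne_max(signal),
        hfno_6000=hf_noise(signal),
        hnr_d=hnr_d(signal, f0),
        h1_h2=h1_h2(signal, f0),
        shim_db=shim_db_val,
        shim=shim_pct,
        psd=psd(periods),
    )
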