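"""Synthetic paired voice/EGG/respiration signals and simulated raters.

The generator emulates the statistical structure the downstream analysis
assumes: a quasi-periodic glottal-pulse voice with a controllable
aspiration-noise level (breathiness) recorded at ~45 dB SNR, a coupled EGG
waveform with a controllable open quotient at ~30 dB SNR, slow (<1 Hz)
respiratory circumference traces with a four-stage thoracic pattern, and
two raters scoring breathiness on a 0-4 half-point scale.

Breathiness is a single scalar in [0, 1].  It drives both the
aspiration-noise gain of the microphone channel and, through an affine map
onto open quotient (0.50 at level 0 up to 0.65 at level 1), the EGG cycle
shape — mirroring the observed covariation of turbulent noise and glottal
opening in breathy phonation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence, Union

import numpy as np
from scipy import signal as sps

from .core import (
    BREATHINESS_TARGETS,
    INTENSITIES,
    TRIAL_TYPES,
    MonoSignal,
    SignalError,
    TrialCondition,
    VoiceSample,
)

F0Spec = Union[float, tuple, np.ndarray, Callable[[np.ndarray], np.ndarray]]

#: breathiness 0 -> OQ 0.50, breathiness 1 -> OQ 0.65
OQ_SPAN = (0.50, 0.65)

#: aspiration-noise RMS relative to the voiced RMS at breathiness level 1
ASPIRATION_GAIN = 0.7

#: residual turbulence present even in non-breathy phonation, as a
#: fraction of the full aspiration gain
ASPIRATION_BASE = 0.05

#: cycle-to-cycle amplitude perturbation (relative sd) of the glottal
#: source at breathiness 0 and 1: turbulent airflow destabilizes the
#: pulse amplitudes, so shimmer rises with breathiness
SHIMMER_SD_SPAN = (0.01, 0.07)

#: vowel-like formant resonances (Hz) and bandwidths (Hz)
FORMANTS = ((660.0, 80.0), (1200.0, 90.0), (2600.0, 120.0), (3300.0, 150.0))

#: air-depletion model: lung capacity expressed as seconds of non-breathy
#: phonation, and the relative transglottal flow increase at full breathiness
LUNG_CAPACITY_S = 12.43
BREATHY_FLOW_FACTOR = 1.748


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the signal generator.

    f0_hz may be a scalar, a (start, end) pair for a linear glide, an array
    of per-sample frequencies, or a callable mapping times to Hz.
    """

    f0_hz: F0Spec = 220.0
    duration_s: float = 2.0
    breathiness_level: float = 0.0
    intensity_gain: float = 0.0
    oq_target: float = 0.5
    cm_snr_db: float = 45.0
    egg_snr_db: float = 30.0
    sample_rate: float = 48000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SignalError(f"duration_s must be positive, got {self.duration_s}")
        if not 0.0 <= self.breathiness_level <= 1.0:
            raise SignalError("breathiness_level must lie in [0, 1]")
        if not 0.0 < self.oq_target < 1.0:
            raise SignalError("oq_target must lie in (0, 1)")
        if self.sample_rate < 16000:
            raise SignalError("sample_rate must be at least 16000 Hz")


def breathiness_to_oq(level: float) -> float:
    """Affine map from breathiness level in [0, 1] to open-quotient target."""
    lo, hi = OQ_SPAN
    return lo + (hi - lo) * float(level)


def _f0_samples(spec: F0Spec, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    if callable(spec):
        f0 = np.asarray(spec(t), dtype=float)
    elif isinstance(spec, tuple) and len(spec) == 2:
        f0 = np.linspace(spec[0], spec[1], n)
    elif np.ndim(spec) == 0:
        f0 = np.full(n, float(spec))
    else:
        f0 = np.asarray(spec, dtype=float)
        if f0.size != n:
            raise SignalError("f0 trajectory length does not match signal length")
    if f0.min() < 50.0 or f0.max() > 1500.0:
        raise SignalError("f0 must stay within [50, 1500] Hz")
    return f0


def _cycle_phase(f0: np.ndarray, fs: float) -> np.ndarray:
    """Normalized cycle phase in [0, 1): integral of f0 modulo 1."""
    return np.mod(np.cumsum(f0) / fs, 1.0)


def _rosenberg_flow(x: np.ndarray, oq: float,
                    closing_frac: float = 0.4) -> np.ndarray:
    """Rosenberg-style glottal flow over normalized cycle phase.

    Open phase occupies the first `oq` fraction of the cycle: a
    raised-cosine rise followed by a cosine fall over `closing_frac` of
    the open phase.  A longer (softer) fall models incomplete glottal
    closure: the abrupt flow shut-off weakens, and with it the high
    harmonics of the source.
    """
    closing_frac = min(closing_frac, 0.75)
    tn = closing_frac * oq
    tp = oq - tn
    g = np.zeros_like(x)
    rising = x < tp
    falling = (x >= tp) & (x < oq)
    g[rising] = 0.5 * (1.0 - np.cos(np.pi * x[rising] / tp))
    g[falling] = np.cos(0.5 * np.pi * (x[falling] - tp) / tn)
    return g


def _formant_filter(x: np.ndarray, fs: float) -> np.ndarray:
    y = x
    for freq, bw in FORMANTS:
        if freq >= 0.45 * fs:
            continue
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * freq / fs
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        b = [1.0 - r]
        y = sps.lfilter(b, a, y)
    return y


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    lo: float = 500.0, hi: float = 8000.0) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, rng.standard_normal(n))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


def gen_voice_components(params: SynthParams, lead_silence_s: float = 0.0):
    """Clean voiced+aspiration signal and the background-noise floor.

    Returns (clean, background) arrays; their sum is the generated CM
    channel.  The background level realizes the requested clean-to-noise
    ratio (cm_snr_db).  `lead_silence_s` prepends a voice-free stretch so
    the noise floor can be measured from the output itself.
    """
    fs = params.sample_rate
    n_voice = int(round(params.duration_s * fs))
    n_lead = int(round(lead_silence_s * fs))
    rng = np.random.default_rng(params.seed)

    f0 = _f0_samples(params.f0_hz, n_voice, fs)
    x = _cycle_phase(f0, fs)
    # incomplete closure: the closing phase lengthens with breathiness
    closing = 0.4 + 0.25 * params.breathiness_level
    flow = _rosenberg_flow(x, params.oq_target, closing_frac=closing)
    # cycle-wise amplitude perturbation: stronger in breathy phonation
    lo_sd, hi_sd = SHIMMER_SD_SPAN
    amp_sd = lo_sd + (hi_sd - lo_sd) * params.breathiness_level
    cycle_idx = np.floor(np.cumsum(f0) / fs).astype(int)
    gains = 1.0 + amp_sd * rng.standard_normal(cycle_idx[-1] + 1)
    flow = flow * np.clip(gains[cycle_idx], 0.5, 1.5)
    excitation = np.diff(flow, prepend=flow[0])
    voiced = _formant_filter(excitation, fs)
    voiced_rms = _rms(voiced)

    # the turbulence source is shaped by the same vocal tract as the
    # glottal source: band-limited noise through the formant filter, with
    # the residual high band rolled off
    asp = _formant_filter(_bandpass_noise(rng, n_voice, fs), fs)
    open_mask = (x < params.oq_target).astype(float)
    # keep a small pedestal so the noise never fully gates off; the final
    # low-pass also removes the gating sidebands
    asp *= 0.25 + 0.75 * open_mask
    sos_lp = sps.butter(8, min(4800.0, 0.45 * fs), fs=fs, output="sos")
    asp = sps.sosfiltfilt(sos_lp, asp)
    asp_rms = _rms(asp)
    level = ASPIRATION_BASE + (1.0 - ASPIRATION_BASE) * params.breathiness_level
    if asp_rms > 0:
        asp *= ASPIRATION_GAIN * level * voiced_rms / asp_rms

    clean = voiced + asp
    clean *= 10.0 ** (params.intensity_gain / 20.0)
    peak = np.max(np.abs(clean))
    if peak > 0:
        clean *= 0.5 / peak
    clean = np.concatenate([np.zeros(n_lead), clean])

    bg = rng.standard_normal(n_lead + n_voice)
    clean_rms = _rms(clean[n_lead:])
    bg *= clean_rms / (10.0 ** (params.cm_snr_db / 20.0))
    return clean, bg


def gen_voice(params: SynthParams, lead_silence_s: float = 0.0) -> MonoSignal:
    """Quasi-periodic voice: glottal pulses through fixed formant resonances,
    aspiration noise scaled by breathiness_level, background noise at
    cm_snr_db.  Deterministic given the seed."""
    clean, bg = gen_voice_components(params, lead_silence_s)
    return MonoSignal(clean + bg, params.sample_rate)


def _egg_contact(x: np.ndarray, oq: float,
                 rise: float = 0.03, fall: float = 0.08) -> np.ndarray:
    """Contact-area waveform over normalized cycle phase.

    Laid out so that the positive dEGG peak (contacting, mid-rise) and the
    negative dEGG peak (de-contacting, mid-fall) are exactly (1 - oq) * T
    apart: raised-cosine rise over `rise`, plateau, raised-cosine fall over
    `fall`, open baseline at zero.
    """
    cq = 1.0 - oq
    plateau = cq - 0.5 * (rise + fall)
    if plateau <= 0:
        raise SignalError("oq_target leaves no contact plateau (must be < 0.95)")
    c = np.zeros_like(x)
    p_end = rise + plateau
    in_rise = x < rise
    c[in_rise] = 0.5 * (1.0 - np.cos(np.pi * x[in_rise] / rise))
    c[(x >= rise) & (x < p_end)] = 1.0
    in_fall = (x >= p_end) & (x < p_end + fall)
    c[in_fall] = 0.5 * (1.0 + np.cos(np.pi * (x[in_fall] - p_end) / fall))
    return c


def gen_egg(params: SynthParams, noise: bool = True) -> MonoSignal:
    """EGG waveform with a sharp contacting rise, a contact plateau, a
    de-contacting fall and an open baseline; additive noise at egg_snr_db.

    Open quotient outside (0.05, 0.95) leaves no resolvable cycle shape and
    is rejected.
    """
    if not 0.05 < params.oq_target < 0.95:
        raise SignalError("oq_target must lie in (0.05, 0.95) for a resolvable cycle")
    fs = params.sample_rate
    n = int(round(params.duration_s * fs))
    rng = np.random.default_rng(params.seed + 1)
    f0 = _f0_samples(params.f0_hz, n, fs)
    x = _cycle_phase(f0, fs)
    egg = _egg_contact(x, params.oq_target)
    if noise:
        w = rng.standard_normal(n)
        w *= _rms(egg) / (10.0 ** (params.egg_snr_db / 20.0))
        egg = egg + w
    return MonoSignal(egg, fs)


def breathiness_profile(cond: TrialCondition, n: int) -> np.ndarray:
    """Per-sample breathiness level across a trial.

    NBSV is non-breathy throughout, BSV fully breathy, GBSV ramps linearly
    from 0 to 1 across the trial.
    """
    if cond.breathiness_target == "NBSV":
        return np.zeros(n)
    if cond.breathiness_target == "BSV":
        return np.ones(n)
    return np.linspace(0.0, 1.0, n)


_INTENSITY_GAIN_DB = {"low": -6.0, "medium": 0.0, "high": 6.0}


def gen_paired_sample(cond: TrialCondition, params: SynthParams) -> VoiceSample:
    """CM and EGG channels sharing one f0 trajectory and one breathiness
    profile derived from the trial condition."""
    fs = params.sample_rate
    n = int(round(params.duration_s * fs))
    level = breathiness_profile(cond, n)
    mean_level = float(level.mean())
    oq = breathiness_to_oq(mean_level)
    gain = _INTENSITY_GAIN_DB[cond.intensity]
    p = replace(params, breathiness_level=mean_level, oq_target=oq,
                intensity_gain=params.intensity_gain + gain)
    cm = gen_voice(p)
    egg = gen_egg(p)
    return VoiceSample(
        sample_id="",
        cm=cm,
        egg=egg,
        condition=cond,
        meta={
            "breathiness_level": mean_level,
            "oq_target": oq,
            "f0_hz": p.f0_hz if np.ndim(p.f0_hz) == 0 else "trajectory",
            "seed": p.seed,
        },
    )


def gen_protocol() -> list[TrialCondition]:
    """The full deterministic protocol crossing: 3 breathiness targets x
    3 intensities x 6 trial types = 54 trials (9 conditions)."""
    return [
        TrialCondition(b, i, t)
        for b in BREATHINESS_TARGETS
        for i in INTENSITIES
        for t in TRIAL_TYPES
    ]


def phonation_duration_for(cond: TrialCondition,
                           capacity_s: float = LUNG_CAPACITY_S,
                           flow_factor: float = BREATHY_FLOW_FACTOR) -> float:
    """Sustainable phonation duration under an air-depletion model.

    Transglottal flow grows linearly with breathiness from 1 at level 0 to
    `flow_factor` at level 1; phonation stops when the integrated flow
    reaches the lung capacity (expressed in seconds of non-breathy
    phonation).  For a linear GBSV ramp the ramp completes within the trial,
    so the mean flow is the average over the ramp.
    """
    if cond.breathiness_target == "NBSV":
        mean_flow = 1.0
    elif cond.breathiness_target == "BSV":
        mean_flow = flow_factor
    else:  # GBSV: level ramps 0 -> 1 across the trial
        mean_flow = 0.5 * (1.0 + flow_factor)
    return capacity_s / mean_flow


def gen_sustained_trial(cond: TrialCondition, params: SynthParams,
                        pad_s: float = 1.0) -> MonoSignal:
    """A full sustained trial: phonation of air-depletion-limited duration
    padded by background-only stretches on both sides."""
    dur = phonation_duration_for(cond)
    n = int(round(dur * params.sample_rate))
    level = breathiness_profile(cond, n)
    mean_level = float(level.mean())
    p = replace(params, duration_s=dur, breathiness_level=mean_level,
                oq_target=breathiness_to_oq(mean_level))
    clean, bg = gen_voice_components(p)
    fs = params.sample_rate
    n_pad = int(round(pad_s * fs))
    rng = np.random.default_rng(params.seed + 2)
    floor = _rms(bg)
    out = np.concatenate([
        rng.standard_normal(n_pad) * floor,
        clean + bg,
        rng.standard_normal(n_pad) * floor,
    ])
    return MonoSignal(out, fs)


def gen_respiratory_trace(stage_durations: Sequence[float],
                          slopes: Sequence[float],
                          cycle_rest_hz: float = 0.25,
                          rest_s: float = 12.0,
                          sample_rate: float = 100.0,
                          noise_sd: float = 0.0,
                          seed: int = 0):
    """Thoracic circumference trace with the four-stage phonation pattern.

    Stages: (1) expansion to a local maximum before phonation onset,
    (2) slow linear decrease, (3) faster collapse, (4) plateau at a local
    minimum.  The pattern is embedded between resting tidal cycles at
    cycle_rest_hz.  Returns (MonoSignal, ground_truth dict) where the dict
    carries the stage boundary times and the phonation onset.

    All deterministic content is below 10 Hz; `noise_sd` adds white noise
    on top for filter-robustness tests.
    """
    stage_durations = [float(d) for d in stage_durations]
    slopes = [float(s) for s in slopes]
    if len(stage_durations) != 4 or len(slopes) != 4:
        raise SignalError("four stage durations and four slopes are required")
    if any(d <= 0 for d in stage_durations):
        raise SignalError("stage durations must be positive")
    if cycle_rest_hz > 0.3:
        raise SignalError("resting breathing rate must be at most 0.3 Hz")
    fs = sample_rate
    rng = np.random.default_rng(seed)

    tidal_amp = 0.3
    n_rest = int(round(rest_s * fs))
    t_rest = np.arange(n_rest) / fs
    rest = tidal_amp * np.sin(2 * np.pi * cycle_rest_hz * t_rest)

    seg_parts = []
    level = rest[-1] if n_rest else 0.0
    for d, s in zip(stage_durations, slopes):
        n_seg = int(round(d * fs))
        seg = level + s * np.arange(1, n_seg + 1) / fs
        seg_parts.append(seg)
        level = seg[-1]
    pattern = np.concatenate(seg_parts)

    rest_after = level + tidal_amp * 0.5 * np.sin(
        2 * np.pi * cycle_rest_hz * np.arange(n_rest) / fs
    )
    y = np.concatenate([rest, pattern, rest_after])
    # smooth the corners gently; deterministic content stays below ~8 Hz
    sos = sps.butter(2, 8.0, fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, y)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.size)

    t0 = rest_s
    bounds = np.cumsum([t0] + stage_durations)
    truth = {
        "stage1_end": bounds[1],          # pre-onset local maximum
        "stage2_end": bounds[2],          # slow/fast decline breakpoint
        "stage3_end": bounds[3],          # start of the plateau
        "pattern_end": bounds[4],
        "phonation_onset": bounds[1] + 0.2,
    }
    return MonoSignal(y, fs), truth


def snap_to_half_points(x: np.ndarray) -> np.ndarray:
    """Round to the nearest 0.5 and clip to the 0-4 rating range."""
    return np.clip(np.round(np.asarray(x, dtype=float) * 2.0) / 2.0, 0.0, 4.0)


def simulate_raters(true_degree, noise_sd: float, seed: int = 0):
    """Two independent raters: truth plus Gaussian noise, snapped to the
    half-point grid and clipped to [0, 4].  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_degree, dtype=float)
    r1 = snap_to_half_points(truth + noise_sd * rng.standard_normal(truth.shape))
    r2 = snap_to_half_points(truth + noise_sd * rng.standard_normal(truth.shape))
    if truth.ndim == 0:
        return float(r1), float(r2)
    return r1, r2
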