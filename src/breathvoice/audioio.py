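"""WAV I/O, channel splitting, 2-second segmentation, and the respiratory
low-pass filter.

Integer PCM at 16, 24 and 32 bits plus IEEE float32 are supported; 24-bit
frames are packed as 3-byte little-endian.  Integer samples are scaled to
[-1, 1) on read.
"""

from __future__ import annotations

import struct
import wave
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .core import MonoSignal, SignalError, VoiceSample


class WavFormatError(ValueError):
    """Malformed or unsupported WAV content."""


_INT_SCALES = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}


def read_wav(path) -> Union[MonoSignal, tuple[MonoSignal, MonoSignal]]:
    """Read a mono or stereo RIFF/WAVE file.

    Returns a MonoSignal, or a (left, right) pair for stereo files.
    Integer PCM is scaled to [-1, 1); float data passes through unchanged.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise WavFormatError(f"{path.name}: not a readable WAV file ({exc})") from exc
    if data.dtype in _INT_SCALES:
        data = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        data = data.astype(np.float64)
    else:
        raise WavFormatError(f"{path.name}: unsupported sample format {data.dtype}")
    if data.ndim == 1:
        return MonoSignal(data, rate)
    if data.ndim == 2 and data.shape[1] == 2:
        return MonoSignal(data[:, 0], rate), MonoSignal(data[:, 1], rate)
    raise WavFormatError(f"{path.name}: unsupported channel count {data.shape[1]}")


def write_wav(signal, path, bit_depth: Union[int, str] = 16) -> None:
    """Write one MonoSignal (or a pair, as stereo) at the given bit depth.

    bit_depth is 16, 24, 32 or "float32".  Integer depths clip to [-1, 1).
    """
    path = Path(path)
    if isinstance(signal, (tuple, list)):
        left, right = signal
        if len(left) != len(right) or left.sample_rate != right.sample_rate:
            raise SignalError("stereo channels must share length and sample rate")
        data = np.stack([left.samples, right.samples], axis=1)
        rate = int(left.sample_rate)
        n_channels = 2
    else:
        data = signal.samples
        rate = int(signal.sample_rate)
        n_channels = 1

    if bit_depth == "float32":
        wavfile.write(str(path), rate, data.astype(np.float32))
        return
    if bit_depth == 16:
        q = np.clip(np.round(data * 2 ** 15), -2 ** 15, 2 ** 15 - 1)
        wavfile.write(str(path), rate, q.astype(np.int16))
        return
    if bit_depth == 32:
        q = np.clip(np.round(data * 2 ** 31), -2 ** 31, 2 ** 31 - 1)
        wavfile.write(str(path), rate, q.astype(np.int32))
        return
    if bit_depth == 24:
        q = np.clip(np.round(data * 2 ** 23), -2 ** 23, 2 ** 23 - 1).astype(np.int32)
        frames = q.reshape(-1)
        raw = bytearray()
        for v in frames:
            raw += struct.pack("<i", int(v))[:3]
        with wave.open(str(path), "wb") as wf:
            wf.setnchannels(n_channels)
            wf.setsampwidth(3)
            wf.setframerate(rate)
            wf.writeframes(bytes(raw))
        return
    raise WavFormatError(f"unsupported bit depth {bit_depth!r}")


def segment_signal(signal: MonoSignal, window_s: float = 2.0,
                   start_index: int = 0) -> list[tuple[str, MonoSignal]]:
    """Cut consecutive non-overlapping full windows; the trailing remainder
    shorter than window_s is discarded.  Segments are numbered from
    start_index with zero-padded three-digit labels (continuing across
    participants by passing the next free index)."""
    if window_s <= 0:
        raise SignalError("window_s must be positive")
    win = int(round(window_s * signal.sample_rate))
    n_seg = len(signal) // win
    out = []
    for k in range(n_seg):
        seg = MonoSignal(signal.samples[k * win:(k + 1) * win], signal.sample_rate)
        out.append((f"{start_index + k:03d}", seg))
    return out


def segment_pair(cm: MonoSignal, egg: MonoSignal, window_s: float = 2.0,
                 start_index: int = 0, participant: str = "") -> list[VoiceSample]:
    """Segment both channels simultaneously into numbered VoiceSamples."""
    cm_segs = segment_signal(cm, window_s, start_index)
    egg_segs = segment_signal(egg, window_s, start_index)
    return [
        VoiceSample(sample_id=sid, cm=c, egg=e, participant=participant)
        for (sid, c), (_, e) in zip(cm_segs, egg_segs)
    ]


def lowpass_resp(signal: MonoSignal, cutoff_hz: float = 40.0) -> MonoSignal:
    """Zero-phase low-pass for respiratory traces.

    Order-6 Butterworth applied forward-backward: passband (<10 Hz) gain
    within +-1 dB, at least 20 dB attenuation at >=50 Hz, and extrema timing
    preserved by the zero-phase realization.
    """
    nyq = signal.sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise SignalError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(6, cutoff_hz, fs=signal.sample_rate, output="sos")
    return MonoSignal(sps.sosfiltfilt(sos, signal.samples), signal.sample_rate)


def estimate_snr(signal: MonoSignal, noise_region: tuple[float, float],
                 signal_region: Optional[tuple[float, float]] = None) -> float:
    """10*log10(P_signal / P_noise) from the two time regions (seconds).

    The signal region defaults to everything outside the noise region.
    A silent noise region yields +inf rather than an exception.
    """
    fs = signal.sample_rate
    n0, n1 = (int(round(t * fs)) for t in noise_region)
    noise = signal.samples[n0:n1]
    if signal_region is None:
        sig = np.concatenate([signal.samples[:n0], signal.samples[n1:]])
        if sig.size == 0:
            sig = signal.samples
    else:
        s0, s1 = (int(round(t * fs)) for t in signal_region)
        sig = signal.samples[s0:s1]
    if noise.size == 0 or sig.size == 0:
        raise SignalError("empty region for SNR estimation")
    p_noise = float(np.mean(np.square(noise)))
    p_signal = float(np.mean(np.square(sig)))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(p_signal / p_noise)
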