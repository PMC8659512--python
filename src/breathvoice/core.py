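"""Core containers shared across the analysis pipeline.

The unit of analysis is a 2-second paired excerpt: a condenser-microphone
(CM) channel carrying the acoustic voice and an electroglottograph (EGG)
channel carrying relative vocal-fold contact area, recorded at a common
sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BREATHINESS_TARGETS = ("NBSV", "BSV", "GBSV")
INTENSITIES = ("low", "medium", "high")
TRIAL_TYPES = (
    "sustained_comfortable",
    "sustained_high",
    "sustained_low",
    "glissando_up",
    "glissando_down",
    "arpeggio",
)


class SignalError(ValueError):
    """Raised for signals that violate a precondition (length, rate, values)."""


@dataclass(frozen=True)
class MonoSignal:
    """A single-channel signal: samples (nominally in [-1, 1]) plus rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise SignalError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.ndim != 1:
            raise SignalError(f"expected a 1-D array, got shape {samples.shape}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise SignalError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the recording protocol.

    The full crossing is 3 breathiness targets x 3 intensities = 9
    experimental conditions, each sung in 6 trial types (54 trials).
    """

    breathiness_target: str
    intensity: str
    trial_type: str

    def __post_init__(self) -> None:
        if self.breathiness_target not in BREATHINESS_TARGETS:
            raise ValueError(f"unknown breathiness target {self.breathiness_target!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")

    @property
    def label(self) -> str:
        return f"{self.breathiness_target}-{self.intensity}-{self.trial_type}"


@dataclass
class VoiceSample:
    """A numbered paired CM+EGG excerpt with optional condition metadata."""

    sample_id: str
    cm: MonoSignal
    egg: MonoSignal
    participant: str = ""
    condition: Optional[TrialCondition] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cm) != len(self.egg):
            raise SignalError(
                f"CM and EGG lengths differ: {len(self.cm)} vs {len(self.egg)}"
            )
        if self.cm.sample_rate != self.egg.sample_rate:
            raise SignalError("CM and EGG sample rates differ")

    @property
    def sample_rate(self) -> float:
        return self.cm.sample_rate

    @property
    def duration_s(self) -> float:
        return self.cm.duration_s
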