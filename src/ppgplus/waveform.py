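"""Core waveform container shared by every stage of the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform", "InvalidParameterError", "DegenerateSignalError"]


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class DegenerateSignalError(ValueError):
    """The signal cannot support the requested operation (constant, too short...)."""


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled 1-D physiological signal.

    Parameters
    ----------
    samples : array-like of float
        Signal values; must be finite and contain at least 2 samples.
    fs_hz : float
        Sampling rate in Hz, strictly positive.
    units : str
        Physical units of the samples (e.g. ``"a.u."`` for PPG, ``"mmHg"``
        for arterial pressure).
    """

    samples: np.ndarray
    fs_hz: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidParameterError("waveform needs a 1-D vector of >= 2 samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("waveform samples must be finite")
        if not (np.isfinite(self.fs_hz) and self.fs_hz > 0):
            raise InvalidParameterError("fs_hz must be a positive finite number")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs_hz

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "Waveform":
        """A new waveform with the same sampling rate but different samples."""
        return Waveform(samples, self.fs_hz, self.units if units is None else units)
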