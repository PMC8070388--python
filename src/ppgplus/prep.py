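"""Raw-signal conditioning: bandpass filtering, normalization, segmentation, derivatives.

The conditioning chain mirrors standard PPG practice: a zero-phase Butterworth
bandpass over the physiological band (0.4-8 Hz) removes baseline drift and
high-frequency noise, amplitudes are min-max rescaled per segment, 10-s records
are cut into non-overlapping 5-s segments, and first/second derivatives (the
velocity and acceleration plethysmograms) are taken by central finite
differences after denoising, since differentiating a noisy trace deforms the
derivative morphology badly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .waveform import Waveform, InvalidParameterError, DegenerateSignalError

__all__ = [
    "Segment",
    "DerivativeSet",
    "TooShortError",
    "bandpass",
    "normalize",
    "segment_record",
    "derivatives",
]


class TooShortError(ValueError):
    """Record shorter than one segment."""


@dataclass(frozen=True)
class Segment:
    """A fixed-duration slice of a parent record."""

    wave: Waveform
    start_index: int
    duration_s: float

    def __post_init__(self) -> None:
        expect = round(self.duration_s * self.wave.fs_hz)
        if len(self.wave) != expect:
            raise InvalidParameterError(
                f"segment length {len(self.wave)} != round(duration*fs) = {expect}"
            )


@dataclass(frozen=True)
class DerivativeSet:
    """A PPG waveform with its first (PPG') and second (PPG'') derivatives."""

    ppg: Waveform
    d1: Waveform
    d2: Waveform

    def __post_init__(self) -> None:
        if not (len(self.ppg) == len(self.d1) == len(self.d2)):
            raise InvalidParameterError("derivative set lengths differ")
        if not (self.ppg.fs_hz == self.d1.fs_hz == self.d2.fs_hz):
            raise InvalidParameterError("derivative set sampling rates differ")


def bandpass(wave: Waveform, low_hz: float = 0.4, high_hz: float = 8.0, order: int = 4) -> Waveform:
    """Zero-phase Butterworth bandpass.

    The filter is applied forward-backward (``sosfiltfilt``) so the passband
    morphology — on which the derivative channels depend — is not phase
    distorted. Output length equals input length.
    """
    nyq = wave.fs_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=wave.fs_hz, output="sos")
    # generous reflection padding: the low cutoff's transient is ~1/low_hz long
    padlen = min(len(wave) - 1, int(5 * wave.fs_hz))
    return wave.with_samples(sps.sosfiltfilt(sos, wave.samples, padlen=padlen))


def normalize(wave: Waveform) -> Waveform:
    """Min-max rescale to [0, 1]; rejects constant signals."""
    x = wave.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0.0:
        raise DegenerateSignalError("cannot normalize a constant signal")
    return wave.with_samples((x - lo) / (hi - lo))


def segment_record(wave: Waveform, seg_s: float = 5.0) -> list[Segment]:
    """Cut a record into consecutive non-overlapping segments of ``seg_s`` seconds.

    A trailing partial segment is discarded. Raises :class:`TooShortError` if
    the record cannot supply even one segment.
    """
    n_seg = round(seg_s * wave.fs_hz)
    if len(wave) < n_seg:
        raise TooShortError(f"record of {len(wave)} samples < one {n_seg}-sample segment")
    out = []
    for k in range(len(wave) // n_seg):
        sl = wave.samples[k * n_seg : (k + 1) * n_seg]
        out.append(Segment(wave.with_samples(sl), k * n_seg, seg_s))
    return out


def _finite_diff(x: np.ndarray, fs: float) -> np.ndarray:
    # central differences on the interior, one-sided at the boundaries
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    d[0] = (x[1] - x[0]) * fs
    d[-1] = (x[-1] - x[-2]) * fs
    return d


def derivatives(wave: Waveform) -> DerivativeSet:
    """First and second finite-difference derivatives of a (denoised) PPG.

    PPG' relates to blood-flow velocity, PPG'' (the acceleration plethysmogram,
    SDPTG) to vascular stiffness; both feed the green/blue spectrogram channels.
    """
    if len(wave) < 5:
        raise InvalidParameterError("need at least 5 samples to differentiate twice")
    d1 = _finite_diff(wave.samples, wave.fs_hz)
    d2 = _finite_diff(d1, wave.fs_hz)
    u = wave.units
    return DerivativeSet(
        ppg=wave,
        d1=wave.with_samples(d1, units=f"{u}/s"),
        d2=wave.with_samples(d2, units=f"{u}/s^2"),
    )
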