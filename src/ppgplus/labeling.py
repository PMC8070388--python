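"""JNC7 blood-pressure staging of PPG segments from paired arterial-pressure segments.

Each 5-s ABP segment yields one systolic/diastolic reading (segment extrema by
default), which JNC7 maps to one of three classes: normotension (NT),
prehypertension (PHT), hypertension (HT). The class is attached to the
time-aligned PPG segment as its training label.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .waveform import Waveform, InvalidParameterError

__all__ = [
    "BPClass",
    "BPReading",
    "LabeledSegment",
    "ImplausibleWaveformError",
    "AlignmentError",
    "extract_bp",
    "jnc7_classify",
    "label_record",
]

log = logging.getLogger(__name__)

# A pulse pressure below this is physiologically implausible for an arterial line.
_MIN_PULSE_PRESSURE_MMHG = 5.0


class ImplausibleWaveformError(ValueError):
    """ABP segment is too flat to be a real arterial pressure trace."""


class AlignmentError(ValueError):
    """PPG and ABP segment lists are not index-aligned."""


class BPClass(str, Enum):
    """JNC7 blood-pressure class."""

    NT = "NT"
    PHT = "PHT"
    HT = "HT"

    @property
    def rank(self) -> int:
        """Severity order NT < PHT < HT, used by the monotonicity property."""
        return {"NT": 0, "PHT": 1, "HT": 2}[self.value]


@dataclass(frozen=True)
class BPReading:
    """One systolic/diastolic pressure pair in mmHg."""

    sbp_mmHg: float
    dbp_mmHg: float

    def __post_init__(self) -> None:
        if not (self.sbp_mmHg > self.dbp_mmHg):
            raise InvalidParameterError("systolic pressure must exceed diastolic")
        for v in (self.sbp_mmHg, self.dbp_mmHg):
            if not (20.0 < v < 300.0):
                raise InvalidParameterError(f"pressure {v} mmHg outside plausible range")


@dataclass(frozen=True)
class LabeledSegment:
    """A PPG segment paired with the JNC7 class of its ABP segment."""

    ppg: Waveform
    bp_class: BPClass
    reading: BPReading
    segment_index: int


def extract_bp(abp_segment: Waveform) -> BPReading:
    """Read systolic/diastolic pressure off an ABP segment.

    Systolic pressure is the segment's global maximum and diastolic pressure its
    global minimum. A segment whose excursion is below 5 mmHg cannot be a
    pulsatile arterial trace and is rejected.
    """
    x = abp_segment.samples
    sbp = float(np.max(x))
    dbp = float(np.min(x))
    if sbp - dbp < _MIN_PULSE_PRESSURE_MMHG:
        raise ImplausibleWaveformError(
            f"pulse pressure {sbp - dbp:.2f} mmHg below {_MIN_PULSE_PRESSURE_MMHG} mmHg"
        )
    return BPReading(sbp, dbp)


def jnc7_classify(reading: BPReading, *, strict_bounds: bool = False) -> BPClass:
    """Stage a blood-pressure reading per JNC7.

    HT if sbp >= 140 or dbp >= 90; else PHT if sbp >= 120 or dbp >= 80; else NT.
    The staging table prints hypertension as ">140 or >90", which leaves the
    half-open gaps (139, 140) and (89, 90) unassigned; the default closes them
    on the hypertensive side, matching the JNC7 guideline itself.
    ``strict_bounds=True`` keeps the strict ``>`` reading.
    """
    sbp, dbp = reading.sbp_mmHg, reading.dbp_mmHg
    if strict_bounds:
        if sbp > 140 or dbp > 90:
            return BPClass.HT
    elif sbp >= 140 or dbp >= 90:
        return BPClass.HT
    if sbp >= 120 or dbp >= 80:
        return BPClass.PHT
    return BPClass.NT


def label_record(
    ppg_segments: Sequence[Waveform],
    abp_segments: Sequence[Waveform],
    *,
    strict_bounds: bool = False,
) -> tuple[list[LabeledSegment], int]:
    """Label index-aligned PPG segments with the class of their ABP segment.

    Segments whose ABP is implausibly flat are dropped from both lists; the
    second return value counts the drops (also logged).
    """
    if len(ppg_segments) != len(abp_segments):
        raise AlignmentError(
            f"{len(ppg_segments)} PPG segments vs {len(abp_segments)} ABP segments"
        )
    labeled: list[LabeledSegment] = []
    dropped = 0
    for i, (ppg, abp) in enumerate(zip(ppg_segments, abp_segments)):
        try:
            reading = extract_bp(abp)
        except ImplausibleWaveformError as exc:
            dropped += 1
            log.debug("dropping segment %d: %s", i, exc)
            continue
        labeled.append(
            LabeledSegment(ppg, jnc7_classify(reading, strict_bounds=strict_bounds), reading, i)
        )
    if dropped:
        log.info("dropped %d segment(s) with implausible ABP", dropped)
    return labeled, dropped
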