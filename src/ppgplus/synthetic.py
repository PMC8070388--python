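"""Synthetic paired PPG/ABP cohort generator.

Emulates the statistical and morphological structure the pipeline assumes so
every downstream stage is testable without any waveform download:

* quasi-periodic PPG beats built from three Gaussian bumps — systolic peak,
  tidal wave, dicrotic wave — at heart rates of 0.8-2 Hz, with +/-5% beat-to-beat
  period jitter;
* a hypertensive morphology in which the tidal wave has migrated toward (and
  merges with) the main wave and the descending branch is steeper, so the main
  wave looks more rounded;
* additive white noise and low-frequency sinusoidal baseline drift (below the
  0.4 Hz filter edge);
* ABP waveforms whose per-record systolic maximum and diastolic minimum are
  prescribed exactly, drawn from disjoint JNC7-consistent class boxes.

This is a morphological emulator, not a validated hemodynamic model.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .labeling import BPClass
from .waveform import Waveform, InvalidParameterError

__all__ = [
    "BeatMorphology",
    "CohortConfig",
    "SyntheticRecord",
    "BEAT_TEMPLATES",
    "make_beat",
    "make_beat_train",
    "make_abp",
    "generate_cohort",
    "write_cohort",
    "read_record",
]

# Widths of the tidal and dicrotic bumps as multiples of the systolic width.
_TIDAL_WIDTH_FACTOR = 1.6
_DICROTIC_WIDTH_FACTOR = 1.4


@dataclass(frozen=True)
class BeatMorphology:
    """Parametric single-beat PPG shape: three Gaussian bumps.

    Positions and widths are fractions of the beat period; amplitudes are
    dimensionless (the systolic amplitude sets the scale).
    ``descending_steepness`` > 1 narrows the right flank of the systolic bump,
    steepening the descending branch as seen in hypertensive pulses.
    """

    systolic_amp: float = 1.0
    systolic_pos: float = 0.18
    systolic_width: float = 0.06
    tidal_amp: float = 0.35
    tidal_pos: float = 0.42
    dicrotic_amp: float = 0.18
    dicrotic_pos: float = 0.62
    descending_steepness: float = 1.0

    def __post_init__(self) -> None:
        for name in ("systolic_amp", "tidal_amp", "dicrotic_amp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        for name in ("systolic_pos", "tidal_pos", "dicrotic_pos"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 < v < 1.0):
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")
        for name in ("systolic_width", "descending_steepness"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")


#: Class-specific beat templates. NT shows a distinct tidal wave and dicrotic
#: notch; PHT's tidal wave has grown and moved toward the main wave; in HT it
#: has effectively merged with the main wave and the descending branch is
#: steeper, giving the rounded hypertensive main wave.
BEAT_TEMPLATES: dict[BPClass, BeatMorphology] = {
    BPClass.NT: BeatMorphology(
        tidal_amp=0.40, tidal_pos=0.45, dicrotic_amp=0.35, dicrotic_pos=0.68,
    ),
    BPClass.PHT: BeatMorphology(
        systolic_pos=0.20, systolic_width=0.08, tidal_amp=0.65, tidal_pos=0.38,
        dicrotic_amp=0.18, dicrotic_pos=0.63, descending_steepness=2.5,
    ),
    BPClass.HT: BeatMorphology(
        systolic_pos=0.22, systolic_width=0.11, tidal_amp=1.05, tidal_pos=0.32,
        dicrotic_amp=0.02, dicrotic_pos=0.60, descending_steepness=6.0,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    ``class_probs`` orders the classes (NT, PHT, HT) and must sum to 1.
    ``noise_std`` and ``drift_amp`` are in units of the (unit) systolic
    amplitude; ``drift_freq_hz`` must sit below the 0.4 Hz edge of the
    preprocessing bandpass so drift is removable by construction.
    """

    n_records: int = 100
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    heart_rate_hz: tuple[float, float] = (0.8, 2.0)
    noise_std: float = 0.05
    drift_amp: float = 0.5
    drift_freq_hz: float = 0.15
    fs_hz: float = 125.0
    record_s: float = 10.0
    seed: int = 0
    hr_jitter: float = 0.05
    exact_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InvalidParameterError("n_records must be >= 1")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise InvalidParameterError("class_probs must be non-negative and sum to 1")
        if self.exact_counts is not None and sum(self.exact_counts) != self.n_records:
            raise InvalidParameterError("exact_counts must sum to n_records")
        lo, hi = self.heart_rate_hz
        if not (0 < lo <= hi):
            raise InvalidParameterError("heart_rate_hz range must satisfy 0 < lo <= hi")
        if not (0 <= self.drift_freq_hz < 0.4):
            raise InvalidParameterError("drift_freq_hz must lie below the 0.4 Hz filter edge")
        if self.fs_hz <= 26.0:
            raise InvalidParameterError("fs_hz must exceed twice the 13 Hz spectrum ceiling")
        if self.noise_std < 0 or self.drift_amp < 0:
            raise InvalidParameterError("noise_std and drift_amp must be >= 0")


@dataclass(frozen=True)
class SyntheticRecord:
    """One paired PPG/ABP record with its ground-truth pressures and class."""

    record_id: int
    ppg: Waveform
    abp: Waveform
    true_class: BPClass
    sbp_mmHg: float
    dbp_mmHg: float
    heart_rate_hz: float = float("nan")


def _asym_gaussian(t: np.ndarray, pos: float, amp: float, width: float, right_scale: float) -> np.ndarray:
    """Gaussian bump with independently scaled right-hand width."""
    w = np.where(t < pos, width, width * right_scale)
    return amp * np.exp(-0.5 * ((t - pos) / w) ** 2)


def make_beat(m: BeatMorphology, period_s: float, fs_hz: float) -> Waveform:
    """One PPG beat of ``round(period_s * fs_hz)`` samples.

    The beat is the sum of three Gaussian bumps (systolic, tidal, dicrotic) at
    the morphology's fractional positions. Tidal and dicrotic widths are fixed
    multiples (1.6x, 1.4x) of the systolic width. The systolic bump's right
    flank is narrowed by ``descending_steepness``.
    """
    if not (np.isfinite(period_s) and period_s > 0):
        raise InvalidParameterError(f"period_s must be > 0, got {period_s}")
    if not (np.isfinite(fs_hz) and fs_hz >= 50):
        raise InvalidParameterError(f"fs_hz must be >= 50, got {fs_hz}")
    n = round(period_s * fs_hz)
    frac = np.arange(n) / n  # fraction of the beat period
    w = m.systolic_width
    beat = _asym_gaussian(frac, m.systolic_pos, m.systolic_amp, w, 1.0 / m.descending_steepness)
    beat += _asym_gaussian(frac, m.tidal_pos, m.tidal_amp, w * _TIDAL_WIDTH_FACTOR, 1.0)
    beat += _asym_gaussian(frac, m.dicrotic_pos, m.dicrotic_amp, w * _DICROTIC_WIDTH_FACTOR, 1.0)
    return Waveform(beat, fs_hz)


def make_beat_train(
    m: BeatMorphology,
    heart_rate_hz: float,
    record_s: float,
    fs_hz: float,
    rng: np.random.Generator | None = None,
    hr_jitter: float = 0.0,
) -> Waveform:
    """Concatenate beats to a record of ``round(record_s * fs_hz)`` samples.

    Each beat's period is jittered by a uniform +/-``hr_jitter`` fraction to
    avoid degenerate perfectly periodic spectra.
    """
    n_total = round(record_s * fs_hz)
    base_period = 1.0 / heart_rate_hz
    chunks: list[np.ndarray] = []
    n = 0
    while n < n_total:
        period = base_period
        if hr_jitter > 0 and rng is not None:
            period *= 1.0 + rng.uniform(-hr_jitter, hr_jitter)
        b = make_beat(m, period, fs_hz).samples
        chunks.append(b)
        n += b.size
    return Waveform(np.concatenate(chunks)[:n_total], fs_hz)


#: ABP beat shape: pressure pulse with a systolic upstroke and dicrotic wave.
_ABP_MORPHOLOGY = BeatMorphology(
    systolic_amp=1.0, systolic_pos=0.25, systolic_width=0.11,
    tidal_amp=0.0, tidal_pos=0.5, dicrotic_amp=0.25, dicrotic_pos=0.62,
    descending_steepness=1.0,
)


def make_abp(
    sbp_mmHg: float,
    dbp_mmHg: float,
    heart_rate_hz: float,
    record_s: float,
    fs_hz: float,
    rng: np.random.Generator | None = None,
    hr_jitter: float = 0.0,
) -> Waveform:
    """Periodic arterial-pressure waveform with exact prescribed extrema.

    All beats share one amplitude profile (only the period is jittered), so the
    global rescaling that pins the record's maximum to ``sbp_mmHg`` and minimum
    to ``dbp_mmHg`` also pins the extrema of every full-beat segment — the
    segment-wise systolic/diastolic extraction then recovers (sbp, dbp) exactly.
    """
    if not (sbp_mmHg > dbp_mmHg > 0):
        raise InvalidParameterError(f"need sbp > dbp > 0, got ({sbp_mmHg}, {dbp_mmHg})")
    train = make_beat_train(_ABP_MORPHOLOGY, heart_rate_hz, record_s, fs_hz, rng, hr_jitter)
    x = train.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    scaled = dbp_mmHg + (x - lo) * (sbp_mmHg - dbp_mmHg) / (hi - lo)
    return Waveform(scaled, fs_hz, units="mmHg")


# Disjoint JNC7-consistent (SBP, DBP) sampling boxes; draws cannot be ambiguous.
_BP_BOXES: dict[BPClass, tuple[tuple[float, float], tuple[float, float]]] = {
    BPClass.NT: ((100.0, 119.0), (60.0, 79.0)),
    BPClass.PHT: ((120.0, 139.0), (80.0, 89.0)),
    BPClass.HT: ((140.0, 180.0), (90.0, 110.0)),
}

_CLASS_ORDER = (BPClass.NT, BPClass.PHT, BPClass.HT)


def generate_cohort(cfg: CohortConfig) -> list[SyntheticRecord]:
    """Generate ``cfg.n_records`` paired PPG/ABP records, reproducibly from the seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.exact_counts is not None:
        # deterministic stratification: exact per-class counts, shuffled order
        seq = np.repeat(np.arange(3), cfg.exact_counts)
        rng.shuffle(seq)
    else:
        seq = None
    records: list[SyntheticRecord] = []
    for rec_id in range(cfg.n_records):
        if seq is not None:
            cls = _CLASS_ORDER[seq[rec_id]]
        else:
            cls = _CLASS_ORDER[rng.choice(3, p=np.asarray(cfg.class_probs))]
        (sbp_lo, sbp_hi), (dbp_lo, dbp_hi) = _BP_BOXES[cls]
        sbp = float(rng.uniform(sbp_lo, sbp_hi))
        dbp = float(rng.uniform(dbp_lo, dbp_hi))
        hr = float(rng.uniform(*cfg.heart_rate_hz))

        ppg = make_beat_train(
            BEAT_TEMPLATES[cls], hr, cfg.record_s, cfg.fs_hz, rng, cfg.hr_jitter
        ).samples
        t = np.arange(ppg.size) / cfg.fs_hz
        if cfg.drift_amp > 0 and cfg.drift_freq_hz > 0:
            ppg = ppg + cfg.drift_amp * np.sin(
                2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if cfg.noise_std > 0:
            ppg = ppg + rng.normal(0.0, cfg.noise_std, size=ppg.size)

        abp = make_abp(sbp, dbp, hr, cfg.record_s, cfg.fs_hz, rng, cfg.hr_jitter)
        records.append(
            SyntheticRecord(rec_id, Waveform(ppg, cfg.fs_hz), abp, cls, sbp, dbp, hr)
        )
    return records


# ---------------------------------------------------------------------------
# Plain-text persistence: one two-column file per record plus a cohort manifest.

def write_cohort(records: list[SyntheticRecord], out_dir: str | Path) -> Path:
    """Write each record as a two-column CSV plus a cohort manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as mf:
        writer = csv.writer(mf)
        writer.writerow(["record_id", "class", "sbp_mmHg", "dbp_mmHg", "path"])
        for rec in records:
            path = out / f"record_{rec.record_id:04d}.csv"
            with open(path, "w", newline="") as f:
                f.write(
                    f"# fs_hz={rec.ppg.fs_hz} class={rec.true_class.value} "
                    f"sbp={rec.sbp_mmHg:.3f} dbp={rec.dbp_mmHg:.3f}\n"
                )
                f.write("ppg,abp\n")
                for p, a in zip(rec.ppg.samples, rec.abp.samples):
                    f.write(f"{p:.6g},{a:.6g}\n")
            writer.writerow(
                [rec.record_id, rec.true_class.value, f"{rec.sbp_mmHg:.3f}",
                 f"{rec.dbp_mmHg:.3f}", path.name]
            )
    return manifest


def read_record(path: str | Path) -> SyntheticRecord:
    """Read one record file written by :func:`write_cohort`."""
    path = Path(path)
    with open(path) as f:
        header = f.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        data = np.genfromtxt(f, delimiter=",", skip_header=1)
    fs = float(meta["fs_hz"])
    rec_id = int(path.stem.split("_")[-1]) if "_" in path.stem else 0
    return SyntheticRecord(
        record_id=rec_id,
        ppg=Waveform(data[:, 0], fs),
        abp=Waveform(data[:, 1], fs, units="mmHg"),
        true_class=BPClass(meta["class"]),
        sbp_mmHg=float(meta["sbp"]),
        dbp_mmHg=float(meta["dbp"]),
    )
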