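"""Empirical mode decomposition (EMD) and its ensemble variant (EEMD).

EMD adaptively sifts a nonstationary signal into intrinsic mode functions
(IMFs): oscillatory components whose extrema and zero-crossing counts differ by
at most one and whose local envelope mean is (near) zero. Sifting repeatedly
subtracts the mean of the cubic-spline envelopes through the local maxima and
minima until the candidate satisfies the IMF conditions or a Cauchy-type
stopping ratio falls below threshold; the accepted IMF is removed and sifting
restarts on the remainder until fewer than two extrema are left (the monotonic
residue).

EEMD suppresses mode mixing — a single IMF straddling disparate scales on
intermittent signals — by decomposing many white-noise-perturbed copies of the
signal and averaging IMF k across the ensemble; the added noise populates the
whole time-frequency plane uniformly and cancels in the mean.

Here the decomposition removes high-frequency noise/motion artifact and
low-frequency baseline drift from PPG: reconstruction keeps only IMFs whose
mean instantaneous frequency falls in the physiological 0.4-13 Hz band.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .waveform import Waveform, InvalidParameterError, DegenerateSignalError

__all__ = [
    "SiftConfig",
    "EEMDConfig",
    "EMDResult",
    "EmptyReconstructionError",
    "find_extrema",
    "envelope_mean",
    "is_imf",
    "emd",
    "eemd",
    "mean_instantaneous_frequency",
    "denoise",
    "dump_imfs",
]


class EmptyReconstructionError(ValueError):
    """Every IMF was rejected by the band-selection rule."""


@dataclass(frozen=True)
class SiftConfig:
    """Sifting control: Cauchy stopping ratio, iteration cap, IMF cap."""

    sd_threshold: float = 0.2
    max_sift_iters: int = 50
    max_imfs: int = 10

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise InvalidParameterError("sd_threshold must be > 0")
        if self.max_sift_iters < 1 or self.max_imfs < 1:
            raise InvalidParameterError("iteration caps must be >= 1")


@dataclass(frozen=True)
class EEMDConfig:
    """Ensemble control: member count, relative noise amplitude, seed."""

    ensemble_size: int = 100
    noise_std: float = 0.2
    seed: int = 0
    sift: SiftConfig = field(default_factory=SiftConfig)

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise InvalidParameterError("ensemble_size must be >= 1")
        if self.noise_std < 0:
            raise InvalidParameterError("noise_std must be >= 0")


@dataclass(frozen=True)
class EMDResult:
    """Ordered IMFs (high to low frequency) plus the residual trend."""

    imfs: list[Waveform]
    residue: Waveform

    @property
    def fs_hz(self) -> float:
        return self.residue.fs_hz

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residue; equals the input by construction."""
        out = self.residue.samples.copy()
        for imf in self.imfs:
            out += imf.samples
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus collapse to their midpoint)."""
    dx = np.diff(x)
    # treat exact plateaus by propagating the previous slope sign
    sign = np.sign(dx)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def _mirrored_spline(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through ``x[idx]`` with the two edge extrema mirrored
    across each endpoint to suppress end swings."""
    xi = idx.astype(float)
    yi = x[idx]
    k = min(2, idx.size)
    left_x = -xi[1 : k + 1][::-1]
    left_y = yi[1 : k + 1][::-1]
    right_x = 2 * (n - 1) - xi[-k - 1 : -1][::-1]
    right_y = yi[-k - 1 : -1][::-1]
    ex = np.concatenate([left_x, xi, right_x])
    ey = np.concatenate([left_y, yi, right_y])
    ex, keep = np.unique(ex, return_index=True)
    ey = ey[keep]
    t = np.arange(n, dtype=float)
    if ex.size < 2:
        return np.full(n, ey[0])
    if ex.size < 4:  # too few knots for a cubic; fall back to linear
        return np.interp(t, ex, ey)
    return CubicSpline(ex, ey)(t)


def envelope_mean(wave: Waveform) -> Waveform:
    """Mean of the upper (maxima) and lower (minima) cubic-spline envelopes."""
    x = wave.samples
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise DegenerateSignalError(
            "signal has fewer than 2 maxima or 2 minima; not siftable"
        )
    upper = _mirrored_spline(x, maxima, x.size)
    lower = _mirrored_spline(x, minima, x.size)
    return wave.with_samples(0.5 * (upper + lower))


def is_imf(wave: Waveform) -> bool:
    """IMF test: extrema and zero-crossing counts within one of each other, and
    envelope-mean magnitude at most 10% of the signal's peak magnitude."""
    x = wave.samples
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if abs(n_ext - _zero_crossings(x)) > 1:
        return False
    try:
        m = envelope_mean(wave).samples
    except DegenerateSignalError:
        return False
    peak = np.max(np.abs(x))
    if peak == 0:
        return False
    return bool(np.max(np.abs(m)) <= 0.1 * peak)


def _sift(r: np.ndarray, wave: Waveform, cfg: SiftConfig) -> np.ndarray | None:
    """Extract one IMF from ``r``; None if ``r`` is not siftable (becomes residue)."""
    h = r.copy()
    for _ in range(cfg.max_sift_iters):
        try:
            m = envelope_mean(wave.with_samples(h)).samples
        except DegenerateSignalError:
            return None if np.array_equal(h, r) else h
        h_new = h - m
        denom = float(np.sum(h * h))
        if denom == 0.0:
            return None
        sd = float(np.sum(m * m)) / denom  # Cauchy ratio between sift iterations
        h = h_new
        if sd < cfg.sd_threshold and is_imf(wave.with_samples(h)):
            break
    return h


def emd(wave: Waveform, cfg: SiftConfig | None = None) -> EMDResult:
    """Decompose a waveform into IMFs plus a residue (see module docstring).

    The telescoping construction guarantees sum(imfs) + residue == input to
    floating-point accuracy regardless of where sifting stops.
    """
    cfg = cfg or SiftConfig()
    x = wave.samples
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("input must be finite")
    if x.size < 16:
        raise InvalidParameterError("need at least 16 samples to decompose")
    imfs: list[Waveform] = []
    r = x.copy()
    while len(imfs) < cfg.max_imfs:
        maxima, minima = find_extrema(r)
        if maxima.size < 2 or minima.size < 2:
            break  # monotonic-enough remainder: it is the residue
        h = _sift(r, wave, cfg)
        if h is None:
            break
        imfs.append(wave.with_samples(h))
        r = r - h
    return EMDResult(imfs=imfs, residue=wave.with_samples(r))


def eemd(wave: Waveform, cfg: EEMDConfig | None = None) -> EMDResult:
    """Ensemble EMD: average IMF k over decompositions of noise-perturbed copies.

    Each ensemble member adds fresh white Gaussian noise of standard deviation
    ``noise_std * std(input)`` (deterministic per-member sub-seeds), is
    decomposed by :func:`emd`, and IMF k is averaged across members, padding
    members with fewer IMFs with zeros. The residue is defined as input minus
    the summed averaged IMFs, preserving exact reconstruction.
    """
    cfg = cfg or EEMDConfig()
    x = wave.samples
    scale = cfg.noise_std * float(np.std(x))
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.ensemble_size)
    stacks: list[list[np.ndarray]] = []
    for ss in seeds:
        noisy = x
        if scale > 0:
            noisy = x + np.random.default_rng(ss).normal(0.0, scale, size=x.size)
        member = emd(wave.with_samples(noisy), cfg.sift)
        stacks.append([imf.samples for imf in member.imfs])
    n_imfs = max((len(s) for s in stacks), default=0)
    avg: list[Waveform] = []
    for k in range(n_imfs):
        acc = np.zeros_like(x)
        for s in stacks:
            if k < len(s):
                acc += s[k]
        avg.append(wave.with_samples(acc / cfg.ensemble_size))
    residue = x - sum((imf.samples for imf in avg), np.zeros_like(x))
    return EMDResult(imfs=avg, residue=wave.with_samples(residue))


def mean_instantaneous_frequency(imf: Waveform) -> float:
    """Amplitude-weighted mean instantaneous frequency of one IMF, in Hz."""
    from .hht import analytic_signal  # local import avoids a cycle

    attrs = analytic_signal(imf)
    a = attrs.amplitude
    w = float(np.sum(a))
    if w == 0:
        return 0.0
    return float(np.sum(a * attrs.frequency_hz) / w)


def denoise(
    result: EMDResult,
    fs_hz: float | None = None,
    band_hz: tuple[float, float] = (0.4, 13.0),
) -> Waveform:
    """Reconstruct from IMFs whose mean instantaneous frequency lies in ``band_hz``.

    Faster IMFs carry noise and motion artifact; slower IMFs and the residue
    carry baseline drift. The default band matches the preprocessing bandpass
    edge (0.4 Hz) and the spectrogram ceiling (13 Hz).
    """
    if not result.imfs:
        raise EmptyReconstructionError("decomposition has no IMFs")
    lo, hi = band_hz
    kept = [
        imf for imf in result.imfs
        if lo <= mean_instantaneous_frequency(imf) <= hi
    ]
    if not kept:
        raise EmptyReconstructionError(f"no IMF has mean frequency in [{lo}, {hi}] Hz")
    out = np.zeros(len(result.residue))
    for imf in kept:
        out += imf.samples
    return result.residue.with_samples(out)


def dump_imfs(result: EMDResult, path) -> None:
    """Write IMFs and residue to a delimited text file, one column per component."""
    cols = [imf.samples for imf in result.imfs] + [result.residue.samples]
    header = ",".join([f"imf{k + 1}" for k in range(len(result.imfs))] + ["residue"])
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")
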