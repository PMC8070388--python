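"""Hilbert spectral analysis of IMFs and the binned time-frequency-energy map.

After EMD, each IMF is narrowband enough for its analytic signal to define a
meaningful instantaneous amplitude and frequency. Accumulating amplitude into a
time x frequency grid over 0-5 s x 0-13 Hz gives the Hilbert spectrum, which is
rendered as an 8-bit grayscale raster (1247 x 770 by default) and later
composed with the derivative channels into the RGB PPG+ image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .emd import EMDResult
from .waveform import Waveform, InvalidParameterError

__all__ = [
    "InstAttributes",
    "SpectrumGrid",
    "HilbertSpectrum",
    "analytic_signal",
    "hilbert_spectrum",
    "render_channel",
    "write_channel_png",
]


@dataclass(frozen=True)
class InstAttributes:
    """Per-sample instantaneous amplitude (envelope) and frequency of one IMF."""

    amplitude: np.ndarray
    frequency_hz: np.ndarray

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.frequency_hz.shape:
            raise InvalidParameterError("amplitude/frequency length mismatch")
        if np.any(self.amplitude < 0) or np.any(self.frequency_hz < 0):
            raise InvalidParameterError("instantaneous attributes must be >= 0")


@dataclass(frozen=True)
class SpectrumGrid:
    """Binning grid: 0..freq_max_hz in ``n_freq`` rows, 0..duration_s in ``n_time`` columns.

    The default (130 x 625) gives 0.1 Hz frequency resolution and one time bin
    per sample of a 5-s segment at 125 Hz — finer than the rendered raster.
    """

    freq_max_hz: float = 13.0
    duration_s: float = 5.0
    n_freq: int = 130
    n_time: int = 625


@dataclass(frozen=True)
class HilbertSpectrum:
    """Accumulated amplitude over the time x frequency grid; all entries >= 0."""

    matrix: np.ndarray  # (n_freq, n_time), row 0 = lowest frequency
    grid: SpectrumGrid

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.grid.n_freq, self.grid.n_time):
            raise InvalidParameterError("matrix shape does not match grid")
        if np.any(self.matrix < 0):
            raise InvalidParameterError("spectrum entries must be >= 0")

    @property
    def total_mass(self) -> float:
        return float(self.matrix.sum())


def _ar_extend(x: np.ndarray, n_ext: int, order: int) -> np.ndarray:
    """Extrapolate both ends with a Yule-Walker AR model.

    The FFT-based Hilbert transform assumes a periodic window; for tones with
    a non-integer number of cycles the resulting spectral leakage modulates the
    instantaneous attributes across the whole segment. Continuing the signal
    autoregressively before transforming suppresses that end effect for the
    quasi-periodic, narrowband signals IMFs are."""
    order = min(order, max(2, x.size // 4))
    mu = x.mean()
    xm = x - mu
    r = np.correlate(xm, xm, "full")[x.size - 1 : x.size + order]
    if r[0] <= 1e-30:  # (near-)zero signal: nothing to extrapolate
        return np.concatenate([np.zeros(n_ext), xm, np.zeros(n_ext)]) + mu
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    try:
        a = np.linalg.solve(R + 1e-9 * r[0] * np.eye(order), r[1 : order + 1])
    except np.linalg.LinAlgError:
        a = np.zeros(order)
    fwd = list(xm)
    for _ in range(n_ext):
        fwd.append(float(np.dot(a, fwd[-1 : -order - 1 : -1])))
    bwd = list(xm[::-1])
    for _ in range(n_ext):
        bwd.append(float(np.dot(a, bwd[-1 : -order - 1 : -1])))
    out = np.concatenate([np.array(bwd[x.size :])[::-1], xm, np.array(fwd[x.size :])])
    return out + mu


def analytic_signal(imf: Waveform, smooth: int | None = 5, ar_order: int = 32) -> InstAttributes:
    """Instantaneous amplitude and frequency via the analytic signal.

    The Hilbert transform zeroes negative frequencies and doubles positive
    ones; amplitude is the modulus and frequency the forward difference of the
    unwrapped phase times fs/2pi, clamped at zero. Both ends are extended by
    one second of AR(``ar_order``) extrapolation before the transform to
    suppress window-leakage end effects. A short median filter (``smooth``
    samples, odd) tames isolated unwrap glitches and a quarter-second moving
    average cancels residual leakage ripple; pass ``smooth=None`` for the raw
    phase-difference estimate.
    """
    x = imf.samples
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("input must be finite")
    n_ext = int(round(imf.fs_hz))
    xe = _ar_extend(x, n_ext, ar_order)
    z = sps.hilbert(xe)[n_ext : n_ext + x.size]
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.empty_like(phase)
    freq[:-1] = np.diff(phase) * imf.fs_hz / (2 * np.pi)
    freq[-1] = freq[-2]
    if smooth is not None and smooth >= 3:
        freq = sps.medfilt(freq, kernel_size=smooth | 1)
        from scipy.ndimage import uniform_filter1d

        freq = uniform_filter1d(freq, size=max(3, round(imf.fs_hz / 4)) | 1,
                                mode="nearest")
    return InstAttributes(amplitude=amplitude, frequency_hz=np.maximum(freq, 0.0))


def hilbert_spectrum(
    imfs: list[Waveform],
    grid: SpectrumGrid | None = None,
    smooth: int | None = 5,
) -> HilbertSpectrum:
    """Bin every IMF sample's amplitude at its instantaneous (time, frequency) cell.

    Samples whose instantaneous frequency falls outside [0, freq_max_hz] are
    discarded, so the binned mass never exceeds the summed amplitudes.
    """
    if not imfs:
        raise InvalidParameterError("need at least one IMF")
    n = len(imfs[0])
    fs = imfs[0].fs_hz
    for imf in imfs:
        if len(imf) != n or imf.fs_hz != fs:
            raise InvalidParameterError("all IMFs must share length and sampling rate")
    grid = grid or SpectrumGrid()
    mat = np.zeros((grid.n_freq, grid.n_time))
    # sample index -> time bin (uniform over the grid duration)
    tbin = np.minimum(
        (np.arange(n) / fs / grid.duration_s * grid.n_time).astype(int),
        grid.n_time - 1,
    )
    for imf in imfs:
        attrs = analytic_signal(imf, smooth=smooth)
        f = attrs.frequency_hz
        ok = (f >= 0) & (f <= grid.freq_max_hz)
        fbin = np.minimum(
            (f[ok] / grid.freq_max_hz * grid.n_freq).astype(int), grid.n_freq - 1
        )
        np.add.at(mat, (fbin, tbin[ok]), attrs.amplitude[ok])
    return HilbertSpectrum(matrix=mat, grid=grid)


def spectrum_of(result: EMDResult, grid: SpectrumGrid | None = None) -> HilbertSpectrum:
    """Hilbert spectrum of a full decomposition (IMFs only; the residue is a trend)."""
    return hilbert_spectrum(result.imfs, grid=grid)


def render_channel(spec: HilbertSpectrum, width: int = 1247, height: int = 770) -> np.ndarray:
    """Render the spectrum as an 8-bit grayscale raster of exactly height x width.

    Frequency increases upward and time rightward. The grid is upsampled by
    nearest-neighbour index mapping (a pure data raster, so every pixel equals
    one cell and cell ordering is preserved), then linearly scaled so the
    maximum amplitude maps to 255. An all-zero spectrum renders all-zero.
    """
    mat = spec.matrix[::-1, :]  # row 0 = highest frequency = top of image
    rows = (np.arange(height) * mat.shape[0] // height).astype(int)
    cols = (np.arange(width) * mat.shape[1] // width).astype(int)
    img = mat[np.ix_(rows, cols)]
    peak = img.max()
    if peak > 0:
        img = img * (255.0 / peak)
    return np.round(img).astype(np.uint8)


def write_channel_png(spec: HilbertSpectrum, path, width: int = 1247, height: int = 770) -> None:
    """Write a single-channel spectrogram as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(render_channel(spec, width, height), mode="L").save(path)
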