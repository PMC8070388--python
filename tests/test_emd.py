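"""EMD/EEMD: envelopes, sifting, reconstruction, ensemble behaviour, denoising."""
import numpy as np
import pytest
from scipy import signal as sps

from ppgplus.emd import (
    EEMDConfig, EMDResult, EmptyReconstructionError, SiftConfig, denoise, eemd,
    emd, envelope_mean, is_imf, mean_instantaneous_frequency,
)
from ppgplus.hht import analytic_signal
from ppgplus.waveform import DegenerateSignalError, Waveform

from conftest import FS, tone


class TestEnvelopeMean:
    def interior(self, x, frac=0.15):
        n = int(len(x) * frac)
        return x[n:-n]

    def test_pure_sinusoid_mean_near_zero(self):
        m = envelope_mean(tone(2.0, duration_s=5))
        assert np.abs(self.interior(m.samples)).max() < 0.05

    def test_shift_equivariance(self):
        w = tone(2.0, duration_s=5)
        m = envelope_mean(w.with_samples(w.samples + 1.7))
        assert np.abs(self.interior(m.samples) - 1.7).max() < 0.05

    def test_tracks_slow_ramp(self):
        w = tone(3.0, duration_s=5)
        ramp = 0.5 * w.times
        m = envelope_mean(w.with_samples(w.samples + ramp)).samples
        inner = slice(len(ramp) // 6, -len(ramp) // 6)
        np.testing.assert_allclose(m[inner], ramp[inner], atol=0.05 * ramp.max())

    def test_too_few_extrema_rejected(self):
        with pytest.raises(DegenerateSignalError):
            envelope_mean(Waveform(np.arange(100.0), FS))


class TestEmd:
    def test_reconstruction_identity_on_random_signals(self, rng):
        for _ in range(10):
            x = rng.standard_normal(400)
            res = emd(Waveform(x, FS))
            err = np.abs(res.reconstruct() - x).max() / np.abs(x).max()
            assert err < 1e-8

    def test_two_tone_separation(self):
        t = np.arange(1250) / FS
        fast, slow = np.sin(2 * np.pi * 5 * t), np.sin(2 * np.pi * 0.5 * t)
        res = emd(Waveform(fast + slow, FS))
        corr_fast = abs(np.corrcoef(res.imfs[0].samples, fast)[0, 1])
        assert corr_fast >= 0.9
        assert max(
            abs(np.corrcoef(imf.samples, slow)[0, 1]) for imf in res.imfs[1:]
        ) >= 0.9

    def test_monotonic_input_has_no_imfs(self):
        ramp = Waveform(np.linspace(0, 1, 200), FS)
        res = emd(ramp)
        assert res.imfs == []
        np.testing.assert_array_equal(res.residue.samples, ramp.samples)

    def test_frequency_ordering_of_imfs(self):
        t = np.arange(1250) / FS
        x = (np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 2.4 * t)
             + np.sin(2 * np.pi * 0.7 * t))
        res = emd(Waveform(x, FS))
        freqs = [mean_instantaneous_frequency(imf) for imf in res.imfs]
        pairs = list(zip(freqs, freqs[1:]))
        ok = sum(a >= b for a, b in pairs)
        assert ok / len(pairs) >= 0.9


class TestIsImf:
    def test_sinusoid_is_imf(self):
        assert is_imf(tone(3.0, duration_s=5))

    def test_offset_sinusoid_is_not(self):
        w = tone(3.0, duration_s=5)
        assert not is_imf(w.with_samples(w.samples + 5.0))

    def test_every_emd_imf_satisfies_the_conditions(self, rng):
        x = rng.standard_normal(600)
        for imf in emd(Waveform(x, FS)).imfs:
            assert is_imf(imf)


class TestEemd:
    def test_degenerate_ensemble_equals_emd(self):
        w = tone(1.3)
        a = emd(w)
        b = eemd(w, EEMDConfig(ensemble_size=1, noise_std=0.0, seed=0))
        assert len(a.imfs) == len(b.imfs)
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_allclose(ia.samples, ib.samples, atol=1e-12)
        np.testing.assert_allclose(a.residue.samples, b.residue.samples, atol=1e-12)

    def test_seeded_reproducibility(self):
        w = tone(1.1)
        cfg = EEMDConfig(ensemble_size=5, noise_std=0.2, seed=42)
        a, b = eemd(w, cfg), eemd(w, cfg)
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ia.samples, ib.samples)

    def test_reconstruction_identity(self, rng):
        x = rng.standard_normal(500)
        res = eemd(Waveform(x, FS), EEMDConfig(ensemble_size=4, seed=1))
        np.testing.assert_allclose(res.reconstruct(), x, atol=1e-10)

    def test_converges_to_emd_at_vanishing_noise(self):
        w = Waveform(
            np.sin(2 * np.pi * 1.3 * np.arange(1250) / FS)
            + 0.4 * np.sin(2 * np.pi * 4.2 * np.arange(1250) / FS), FS)
        a = emd(w)
        b = eemd(w, EEMDConfig(ensemble_size=2, noise_std=1e-5, seed=0))
        assert len(a.imfs) == len(b.imfs)
        for ia, ib in zip(a.imfs, b.imfs):
            assert np.abs(ia.samples - ib.samples).max() < 1e-3

    def test_ensemble_reduces_mode_mixing(self):
        # intermittent high-frequency burst on a tone: the classic mode-mixing
        # construction; the ensemble confines the burst scale to IMF1
        t = np.arange(512) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        burst = np.zeros_like(t)
        burst[200:280] = 0.5 * np.sin(2 * np.pi * 20 * t[200:280])
        w = Waveform(x + burst, FS)

        def masked_freq_var(imf):
            a = analytic_signal(imf)
            mask = a.amplitude > 0.1 * a.amplitude.max()
            return float(np.var(a.frequency_hz[mask]))

        v_emd = masked_freq_var(emd(w).imfs[0])
        v_eemd = masked_freq_var(
            eemd(w, EEMDConfig(ensemble_size=100, noise_std=0.2, seed=5)).imfs[0]
        )
        assert v_eemd < v_emd


class TestDenoise:
    def test_clean_tone_survives(self):
        w = tone(1.2)
        out = denoise(emd(w))
        assert np.corrcoef(out.samples, w.samples)[0, 1] >= 0.99

    def test_drift_removed(self):
        w = tone(1.2)
        drift = 0.8 * np.sin(2 * np.pi * 0.1 * w.times)
        out = denoise(emd(w.with_samples(w.samples + drift)))
        assert abs(np.corrcoef(out.samples, drift)[0, 1]) < 0.1

    def test_high_frequency_noise_attenuated(self, rng):
        w = tone(1.2)
        hf = 0.3 * np.sin(2 * np.pi * 30 * w.times)
        noisy = w.with_samples(w.samples + hf)
        out = denoise(eemd(noisy, EEMDConfig(ensemble_size=8, seed=2)))

        def band_power(x):
            f, p = sps.periodogram(x, fs=FS)
            return p[f > 13].sum()

        assert band_power(out.samples) < band_power(noisy.samples) / 10

    def test_all_rejected_raises(self):
        res = emd(Waveform(np.sin(2 * np.pi * 0.2 * np.arange(1250) / FS), FS))
        with pytest.raises(EmptyReconstructionError):
            denoise(res, band_hz=(5.0, 13.0))


class TestDumpImfs:
    def test_writes_one_column_per_component(self, tmp_path, rng):
        import numpy as np
        from ppgplus.emd import dump_imfs

        res = emd(Waveform(rng.standard_normal(300), FS))
        path = tmp_path / "imfs.csv"
        dump_imfs(res, path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (300, len(res.imfs) + 1)
        np.testing.assert_allclose(data.sum(axis=1), res.reconstruct(), atol=1e-5)
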