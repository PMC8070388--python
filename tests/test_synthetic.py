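"""Synthetic cohort generator: beat morphology, ABP extrema, reproducibility."""
import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from ppgplus.labeling import BPClass, extract_bp, jnc7_classify
from ppgplus.synthetic import (
    BEAT_TEMPLATES, BeatMorphology, CohortConfig, generate_cohort, make_abp,
    make_beat, make_beat_train, read_record, write_cohort,
)
from ppgplus.waveform import InvalidParameterError


class TestMakeBeat:
    def test_single_bump_peaks_at_systolic_position(self):
        m = BeatMorphology(tidal_amp=0.0, dicrotic_amp=0.0)
        beat = make_beat(m, period_s=1.0, fs_hz=125)
        assert len(beat) == 125
        assert abs(int(np.argmax(beat.samples)) - round(m.systolic_pos * 125)) <= 1
        assert beat.samples.max() == pytest.approx(m.systolic_amp, rel=0.01)

    def test_ht_tidal_merges_into_single_maximum(self):
        # tidal wave migrated onto the main wave: one merged maximum remains
        m = dataclasses.replace(BEAT_TEMPLATES[BPClass.HT], tidal_pos=0.24)
        beat = make_beat(m, period_s=1.0, fs_hz=125).samples
        thresh = 0.1 * beat.max()
        maxima = [
            i for i in range(1, beat.size - 1)
            if beat[i] > beat[i - 1] and beat[i] >= beat[i + 1] and beat[i] > thresh
        ]
        assert len(maxima) == 1

    def test_nt_template_orders_waves(self):
        m = BEAT_TEMPLATES[BPClass.NT]
        assert m.systolic_pos < m.tidal_pos < m.dicrotic_pos

    def test_deterministic(self):
        m = BEAT_TEMPLATES[BPClass.PHT]
        a = make_beat(m, 0.8, 125).samples
        b = make_beat(m, 0.8, 125).samples
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [
        dict(systolic_amp=-1.0), dict(systolic_pos=0.0), dict(tidal_pos=1.5),
        dict(systolic_width=float("nan")),
    ])
    def test_invalid_morphology_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            BeatMorphology(**bad)

    def test_invalid_period_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_beat(BeatMorphology(), period_s=-1.0, fs_hz=125)


class TestMakeAbp:
    def test_exact_extrema_and_length(self):
        abp = make_abp(150, 95, 1.2, 10, 125)
        assert len(abp) == 1250
        assert abp.samples.max() == pytest.approx(150, abs=1e-9)
        assert abp.samples.min() == pytest.approx(95, abs=1e-9)

    @pytest.mark.parametrize("sbp,dbp,expected", [
        (115, 75, BPClass.NT),
        (125, 70, BPClass.PHT),
        (150, 95, BPClass.HT),
    ])
    def test_labels_recoverable_from_waveform(self, sbp, dbp, expected):
        abp = make_abp(sbp, dbp, 1.2, 5, 125)
        assert jnc7_classify(extract_bp(abp)) is expected

    def test_rejects_inverted_pressures(self):
        with pytest.raises(InvalidParameterError):
            make_abp(80, 95, 1.2, 10, 125)


class TestGenerateCohort:
    def test_seeded_cohorts_identical(self):
        cfg = CohortConfig(n_records=20, class_probs=(0.5, 0, 0.5), seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ppg.samples, rb.ppg.samples)
            np.testing.assert_array_equal(ra.abp.samples, rb.abp.samples)
            assert ra.true_class is rb.true_class

    def test_noise_free_ppg_equals_clean_beat_train(self):
        cfg = CohortConfig(n_records=5, noise_std=0.0, drift_amp=0.0,
                           hr_jitter=0.0, seed=3)
        for rec in generate_cohort(cfg):
            clean = make_beat_train(
                BEAT_TEMPLATES[rec.true_class], rec.heart_rate_hz,
                cfg.record_s, cfg.fs_hz,
            )
            np.testing.assert_allclose(rec.ppg.samples, clean.samples)

    def test_class_counts_near_uniform(self):
        cfg = CohortConfig(n_records=1000, class_probs=(1 / 3, 1 / 3, 1 / 3), seed=1)
        counts = {c: 0 for c in BPClass}
        for rec in generate_cohort(cfg):
            counts[rec.true_class] += 1
        sd = np.sqrt(1000 * (1 / 3) * (2 / 3))
        for c in BPClass:
            assert abs(counts[c] - 1000 / 3) < 4 * sd

    def test_exact_counts_are_exact(self):
        cfg = CohortConfig(n_records=30, exact_counts=(10, 8, 12), seed=0)
        got = [r.true_class for r in generate_cohort(cfg)]
        assert (got.count(BPClass.NT), got.count(BPClass.PHT),
                got.count(BPClass.HT)) == (10, 8, 12)

    def test_stored_pressures_match_waveform_and_class(self):
        cfg = CohortConfig(n_records=30, seed=5)
        for rec in generate_cohort(cfg):
            assert rec.abp.samples.max() == pytest.approx(rec.sbp_mmHg, abs=0.5)
            assert rec.abp.samples.min() == pytest.approx(rec.dbp_mmHg, abs=0.5)
            from ppgplus.labeling import BPReading
            assert jnc7_classify(BPReading(rec.sbp_mmHg, rec.dbp_mmHg)) is rec.true_class

    @pytest.mark.parametrize("bad", [
        dict(class_probs=(0.5, 0.5, 0.5)),
        dict(drift_freq_hz=0.5),
        dict(fs_hz=20.0),
        dict(n_records=0),
        dict(exact_counts=(1, 1, 1)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            CohortConfig(n_records=bad.pop("n_records", 10), **bad)


class TestSpectralStructure:
    @pytest.mark.parametrize("cls", list(BPClass))
    def test_clean_ppg_energy_confined_below_13hz(self, cls):
        # the 0-13 Hz spectrogram ceiling captures >= 98% of clean-beat energy
        # even at the fastest heart rate
        wave = make_beat_train(BEAT_TEMPLATES[cls], 2.0, 10, 125,
                               np.random.default_rng(0), 0.05)
        f, p = sps.periodogram(wave.samples - wave.samples.mean(), fs=125)
        assert p[f > 13].sum() / p.sum() < 10 ** (-18 / 10)

    def test_drift_changes_only_sub_04hz_band(self):
        base = make_beat_train(BEAT_TEMPLATES[BPClass.NT], 1.2, 10, 125,
                               np.random.default_rng(1), 0.05).samples
        t = np.arange(base.size) / 125
        drift = 0.8 * np.sin(2 * np.pi * 0.15 * t)
        f, p0 = sps.periodogram(base, fs=125, window="hann")
        _, p1 = sps.periodogram(base + drift, fs=125, window="hann")
        hi = f >= 0.4
        assert np.abs(p1[hi] - p0[hi]).sum() / p0[hi].sum() < 0.01
        assert p1[~hi].sum() > 100 * p0[~hi].sum()


class TestPersistence:
    def test_round_trip_through_text_files(self, tmp_path):
        cfg = CohortConfig(n_records=3, seed=9)
        records = generate_cohort(cfg)
        manifest = write_cohort(records, tmp_path)
        assert manifest.exists()
        for rec in records:
            back = read_record(tmp_path / f"record_{rec.record_id:04d}.csv")
            assert back.true_class is rec.true_class
            assert back.sbp_mmHg == pytest.approx(rec.sbp_mmHg, abs=1e-3)
            np.testing.assert_allclose(back.ppg.samples, rec.ppg.samples, atol=1e-4)
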