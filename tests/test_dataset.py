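"""PPG+ image composition, augmentation, network inputs, splits and folds."""
import numpy as np
import pandas as pd
import pytest

from ppgplus.dataset import (
    CHANNEL_MEAN, CHANNEL_STD, AugmentConfig, PPGPlusImage, StratificationError,
    augment, center_crop_square, compose_ppgplus, hflip, load_image, make_folds,
    save_image, to_network_input,
)
from ppgplus.hht import SpectrumGrid, hilbert_spectrum
from ppgplus.labeling import BPClass
from ppgplus.waveform import InvalidParameterError

from conftest import tone


@pytest.fixture(scope="module")
def three_spectra():
    return tuple(hilbert_spectrum([tone(f, duration_s=5)]) for f in (1.0, 3.0, 6.0))


class TestCompose:
    def test_identical_spectra_give_equal_channels(self, three_spectra):
        s = three_spectra[0]
        img = compose_ppgplus((s, s, s), BPClass.NT)
        assert np.array_equal(img.rgb[:, :, 0], img.rgb[:, :, 1])
        assert np.array_equal(img.rgb[:, :, 1], img.rgb[:, :, 2])

    def test_resolution(self, three_spectra):
        img = compose_ppgplus(three_spectra, BPClass.HT)
        assert img.rgb.shape == (770, 1247, 3)
        assert img.rgb.dtype == np.uint8

    def test_ppg_only_mode_zeroes_derivative_channels(self, three_spectra):
        img = compose_ppgplus(three_spectra, BPClass.NT, ppg_only=True)
        assert img.rgb[:, :, 0].any()
        assert not img.rgb[:, :, 1].any()
        assert not img.rgb[:, :, 2].any()

    def test_channel_permutation_property(self, three_spectra):
        a, b, c = three_spectra
        img = compose_ppgplus((a, b, c), BPClass.NT)
        perm = compose_ppgplus((c, a, b), BPClass.NT)
        assert np.array_equal(perm.rgb[:, :, 0], img.rgb[:, :, 2])
        assert np.array_equal(perm.rgb[:, :, 1], img.rgb[:, :, 0])
        assert np.array_equal(perm.rgb[:, :, 2], img.rgb[:, :, 1])

    def test_mismatched_extents_rejected(self, three_spectra):
        other = hilbert_spectrum(
            [tone(1.0, duration_s=4)],
            grid=SpectrumGrid(duration_s=4.0, n_time=500),
        )
        with pytest.raises(InvalidParameterError):
            compose_ppgplus((three_spectra[0], three_spectra[1], other), BPClass.NT)


class TestAugment:
    def img(self, three_spectra):
        return compose_ppgplus(three_spectra, BPClass.NT)

    def test_seeded_determinism(self, three_spectra):
        img = self.img(three_spectra)
        a = augment(img, seed=3).rgb
        b = augment(img, seed=3).rgb
        assert np.array_equal(a, b)

    def test_flip_is_involution(self, three_spectra):
        img = self.img(three_spectra)
        assert np.array_equal(hflip(hflip(img)).rgb, img.rgb)

    def test_output_is_square(self, three_spectra):
        out = augment(self.img(three_spectra), AugmentConfig(), seed=11)
        assert out.rgb.shape[0] == out.rgb.shape[1]


class TestNetworkInput:
    def test_shape_and_dtype(self, three_spectra):
        x = to_network_input(compose_ppgplus(three_spectra, BPClass.NT))
        assert x.shape == (3, 224, 224)
        assert x.dtype == np.float32

    def test_all_zero_image_standardizes_to_constants(self):
        img = PPGPlusImage(np.zeros((770, 1247, 3), np.uint8), BPClass.NT, "z")
        x = to_network_input(img)
        for c in range(3):
            np.testing.assert_allclose(
                x[c], (0.0 - CHANNEL_MEAN[c]) / CHANNEL_STD[c], rtol=1e-5
            )

    def test_deterministic(self, three_spectra):
        img = compose_ppgplus(three_spectra, BPClass.NT)
        assert np.array_equal(to_network_input(img), to_network_input(img))


class TestMakeFolds:
    def manifest(self, n_records=50, classes=("NT", "HT")):
        rows = []
        for r in range(n_records):
            cls = classes[r % len(classes)]
            for s in range(2):
                rows.append({"segment_id": f"r{r}s{s}", "record_id": f"r{r}",
                             "label": cls, "image_path": f"r{r}s{s}.png"})
        return pd.DataFrame(rows)

    def test_seventy_thirty_split(self):
        out = make_folds(self.manifest(), k=5, train_ratio=0.7, seed=0)
        counts = out["split"].value_counts()
        assert abs(counts["train"] - 70) <= 1
        assert counts["train"] + counts["test"] == 100

    def test_equal_fold_sizes(self):
        out = make_folds(self.manifest(), k=5, seed=1)
        sizes = out[out["split"] == "train"]["fold"].value_counts()
        assert sorted(sizes) == [14] * 5

    def test_records_never_straddle(self):
        out = make_folds(self.manifest(), k=5, seed=2)
        per_record = out.groupby("record_id")[["split", "fold"]].nunique()
        assert (per_record <= 1).all().all()

    def test_folds_partition_training_rows(self):
        out = make_folds(self.manifest(), k=5, seed=3)
        train = out[out["split"] == "train"]
        assert set(train["fold"]) == set(range(5))
        assert (out.loc[out["split"] == "test", "fold"] == -1).all()

    def test_small_class_rejected(self):
        man = self.manifest(n_records=4, classes=("NT", "NT", "NT", "HT"))
        with pytest.raises(StratificationError):
            make_folds(man, k=5)

    def test_stratification_approximate_by_class(self):
        out = make_folds(self.manifest(), k=5, seed=4)
        train = out[out["split"] == "train"]
        by_class = train["label"].value_counts()
        assert abs(by_class["NT"] - by_class["HT"]) <= 2


class TestPngRoundTrip:
    def test_save_and_load(self, three_spectra, tmp_path):
        img = compose_ppgplus(three_spectra, BPClass.PHT, segment_id="s1")
        path = tmp_path / "s1.png"
        save_image(img, path)
        back = load_image(path, BPClass.PHT, "s1")
        assert np.array_equal(back.rgb, img.rgb)
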