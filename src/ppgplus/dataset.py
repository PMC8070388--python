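"""PPG+ image composition, preprocessing/augmentation, and split management.

A PPG+ image stacks the Hilbert spectrograms of a segment's PPG, PPG' and PPG''
as the red, green and blue channels of one RGB image, so a single picture
carries the signal and the vascular information in its derivatives. The control
("PPG-only") variant zeroes the derivative channels. Images are augmented on
the training side only (random aspect-ratio crop, random horizontal flip,
center crop) and standardized to 3 x 224 x 224 network inputs. Splits are
stratified by class at a 7:3 train/test ratio with k folds over the training
rows, grouping the two segments of each record on the same side throughout so
twin segments never leak across the split.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image

from .hht import HilbertSpectrum, render_channel
from .labeling import BPClass
from .waveform import InvalidParameterError

__all__ = [
    "PPGPlusImage",
    "AugmentConfig",
    "StratificationError",
    "IMAGE_WIDTH",
    "IMAGE_HEIGHT",
    "NETWORK_SIZE",
    "CHANNEL_MEAN",
    "CHANNEL_STD",
    "compose_ppgplus",
    "hflip",
    "center_crop_square",
    "augment",
    "to_network_input",
    "make_folds",
    "save_image",
    "load_image",
]

IMAGE_WIDTH = 1247
IMAGE_HEIGHT = 770
NETWORK_SIZE = 224

# Per-channel standardization constants: the widely used pretrained-backbone
# (ImageNet) channel statistics, applied after scaling intensities to [0, 1].
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class StratificationError(ValueError):
    """A class has too few members to stratify into k folds."""


@dataclass(frozen=True)
class PPGPlusImage:
    """An RGB image whose channels are the spectrograms of PPG, PPG', PPG''.

    ``rgb`` is a (height, width, 3) uint8 array; freshly composed images are
    exactly 770 x 1247 x 3, augmented crops may be smaller.
    """

    rgb: np.ndarray
    label: BPClass
    segment_id: str

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.dtype != np.uint8:
            raise InvalidParameterError("rgb must be a (H, W, 3) uint8 array")

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def height(self) -> int:
        return self.rgb.shape[0]


@dataclass(frozen=True)
class AugmentConfig:
    """Training-side augmentation: random aspect-ratio crop then random flip.

    ``scale`` bounds the crop area as a fraction of the source image;
    ``ratio`` bounds the crop's aspect ratio (log-uniform draw).
    """

    scale: tuple[float, float] = (0.7, 1.0)
    ratio: tuple[float, float] = (3 / 4, 4 / 3)
    flip_p: float = 0.5


def compose_ppgplus(
    specs: tuple[HilbertSpectrum, HilbertSpectrum, HilbertSpectrum],
    label: BPClass,
    segment_id: str = "",
    width: int = IMAGE_WIDTH,
    height: int = IMAGE_HEIGHT,
    ppg_only: bool = False,
) -> PPGPlusImage:
    """Render (PPG, PPG', PPG'') spectra to the R, G, B channels in order.

    With ``ppg_only=True`` the derivative channels are zeroed (the control
    experiment keeps only the PPG spectrogram in the red channel).
    """
    if len(specs) != 3:
        raise InvalidParameterError("need exactly three spectra (PPG, PPG', PPG'')")
    extents = {(s.grid.duration_s, s.grid.freq_max_hz) for s in specs}
    if len(extents) != 1:
        raise InvalidParameterError(f"mismatched spectrum extents: {extents}")
    chans = []
    for i, spec in enumerate(specs):
        if ppg_only and i > 0:
            chans.append(np.zeros((height, width), dtype=np.uint8))
        else:
            chans.append(render_channel(spec, width=width, height=height))
    return PPGPlusImage(rgb=np.stack(chans, axis=-1), label=label, segment_id=segment_id)


def hflip(img: PPGPlusImage) -> PPGPlusImage:
    """Horizontal (time-axis) flip; an involution."""
    return replace(img, rgb=np.ascontiguousarray(img.rgb[:, ::-1, :]))


def center_crop_square(img: PPGPlusImage) -> PPGPlusImage:
    """Center crop to the largest square."""
    h, w = img.rgb.shape[:2]
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    return replace(img, rgb=np.ascontiguousarray(img.rgb[top : top + side, left : left + side, :]))


def _random_resized_crop(img: PPGPlusImage, cfg: AugmentConfig, rng: np.random.Generator) -> PPGPlusImage:
    h, w = img.rgb.shape[:2]
    area = h * w
    for _ in range(10):
        target_area = area * rng.uniform(*cfg.scale)
        aspect = float(np.exp(rng.uniform(np.log(cfg.ratio[0]), np.log(cfg.ratio[1]))))
        cw = int(round(np.sqrt(target_area * aspect)))
        ch = int(round(np.sqrt(target_area / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            crop = img.rgb[top : top + ch, left : left + cw, :]
            return replace(img, rgb=np.ascontiguousarray(crop))
    return center_crop_square(img)


def augment(
    img: PPGPlusImage,
    cfg: AugmentConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> PPGPlusImage:
    """Seeded training augmentation: random aspect-ratio crop, random horizontal
    flip, then center crop to square. Identical seeds give identical outputs."""
    cfg = cfg or AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _random_resized_crop(img, cfg, rng)
    if rng.uniform() < cfg.flip_p:
        out = hflip(out)
    return center_crop_square(out)


def to_network_input(img: PPGPlusImage) -> np.ndarray:
    """Deterministic evaluation path: center crop to square, resize to 224 x 224,
    scale intensities to [0, 1], standardize per channel. Returns float32
    (3, 224, 224)."""
    square = center_crop_square(img)
    pil = Image.fromarray(square.rgb, mode="RGB").resize(
        (NETWORK_SIZE, NETWORK_SIZE), Image.BILINEAR
    )
    arr = np.asarray(pil, dtype=np.float32) / 255.0
    arr = (arr - CHANNEL_MEAN) / CHANNEL_STD
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def make_folds(
    manifest: pd.DataFrame,
    k: int = 5,
    train_ratio: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign ``split`` (train/test) and ``fold`` (0..k-1; -1 on test rows).

    Stratified by class at the requested train ratio, then k folds over the
    training rows. Both segments of one record always land on the same side of
    the split and in the same fold (record-level grouping prevents twin-segment
    leakage). Requires columns ``segment_id``, ``record_id``, ``label``.
    """
    if len(manifest) < k:
        raise StratificationError(f"{len(manifest)} segments < k={k}")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    out["fold"] = -1
    records = out.groupby("record_id")["label"].first()
    shuffled: dict = {}
    for cls, rec_ids in records.groupby(records):
        n_cls_segments = int((out["label"] == cls).sum())
        if n_cls_segments < k:
            raise StratificationError(f"class {cls} has {n_cls_segments} segments < k={k}")
        ids = np.array(sorted(rec_ids.index))
        rng.shuffle(ids)
        shuffled[cls] = ids
    # per-class train counts by largest remainder, so the train total equals
    # round(ratio * records) exactly despite stratification rounding
    classes = sorted(shuffled)
    total_train = int(round(train_ratio * records.size))
    quotas = {c: train_ratio * shuffled[c].size for c in classes}
    counts = {c: int(np.floor(quotas[c])) for c in classes}
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True):
        if sum(counts.values()) >= total_train:
            break
        counts[c] += 1
    pos = 0  # global round-robin keeps fold sizes equal across classes
    for cls in classes:
        train_ids = shuffled[cls][: counts[cls]]
        test_ids = shuffled[cls][counts[cls]:]
        out.loc[out["record_id"].isin(test_ids), "split"] = "test"
        out.loc[out["record_id"].isin(train_ids), "split"] = "train"
        for rid in train_ids:
            out.loc[out["record_id"] == rid, "fold"] = pos % k
            pos += 1
    return out


def save_image(img: PPGPlusImage, path) -> None:
    Image.fromarray(img.rgb, mode="RGB").save(path)


def load_image(path, label: BPClass, segment_id: str = "") -> PPGPlusImage:
    rgb = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    return PPGPlusImage(rgb=rgb, label=label, segment_id=segment_id)
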