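"""Resolution normalization, cropping, and intensity standardization.

Every ROI is brought to a common physical resolution (microns per pixel),
cropped to fixed dimensions, and standardized against per-channel statistics
computed on the training pool only — holdout images reuse the frozen training
statistics so no information leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .legend import LabelMap, RoiSample

__all__ = [
    "DatasetStats",
    "resize_to_mpp",
    "center_crop",
    "compute_stats",
    "standardize",
]

#: Floor on the per-channel standard deviation; guards constant-color inputs.
STD_EPS = 1e-6


class PreprocessingError(ValueError):
    pass


@dataclass
class DatasetStats:
    """Per-channel mean/std of the training-pool images (0-255 scale)."""

    per_channel_mean: np.ndarray
    per_channel_std: np.ndarray
    computed_over: list = field(default_factory=list)

    def __post_init__(self):
        self.per_channel_mean = np.asarray(self.per_channel_mean, dtype=np.float64)
        self.per_channel_std = np.maximum(
            np.asarray(self.per_channel_std, dtype=np.float64), STD_EPS
        )

    def to_dict(self) -> dict:
        return {
            "per_channel_mean": self.per_channel_mean.tolist(),
            "per_channel_std": self.per_channel_std.tolist(),
            "computed_over": list(self.computed_over),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetStats":
        return cls(d["per_channel_mean"], d["per_channel_std"], d.get("computed_over", []))


def resize_to_mpp(sample: RoiSample, target_mpp: float) -> RoiSample:
    """Resample a ROI to ``target_mpp`` microns per pixel.

    The image is interpolated bilinearly; the label map is resampled with
    nearest-neighbor so no new class indices can appear. Aspect ratio is
    preserved (both axes share the scale factor source_mpp / target_mpp).
    """
    if target_mpp <= 0:
        raise PreprocessingError("target_mpp must be positive")
    scale = sample.microns_per_pixel / target_mpp
    if np.isclose(scale, 1.0):
        return sample
    h, w = sample.labels.shape
    out_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
    image = _sk_resize(
        sample.image.astype(np.float64), out_shape, order=1, preserve_range=True,
        anti_aliasing=scale < 1,
    )
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    labels = _sk_resize(
        sample.labels.indices, out_shape, order=0, preserve_range=True,
        anti_aliasing=False,
    ).astype(sample.labels.indices.dtype)
    return RoiSample(
        roi_id=sample.roi_id,
        patient_id=sample.patient_id,
        image=image,
        labels=LabelMap(labels, sample.labels.legend),
        microns_per_pixel=target_mpp,
    )


def center_crop(
    sample: RoiSample,
    height: int,
    width: int,
    pad_policy: str = "reject",
    image_fill=None,
) -> RoiSample:
    """Crop (or pad) a ROI to exactly ``height x width`` about its center.

    When the input is smaller along an axis, ``pad_policy='pad'`` pads that
    axis symmetrically (extra pixel goes to the bottom/right): padded label
    pixels are avoid-class, padded image pixels take ``image_fill`` (a
    per-channel color, e.g. the dataset mean; mid-gray 128 if omitted).
    ``pad_policy='reject'`` raises instead.
    """
    if height <= 0 or width <= 0:
        raise PreprocessingError("crop dimensions must be positive")
    h, w = sample.labels.shape
    if (h < height or w < width) and pad_policy != "pad":
        raise PreprocessingError(
            f"input {h}x{w} smaller than crop {height}x{width} and pad_policy={pad_policy!r}"
        )
    image = sample.image
    labels = sample.labels.indices
    if h < height or w < width:
        pt = max(0, (height - h) // 2)
        pb = max(0, height - h - pt)
        pl = max(0, (width - w) // 2)
        pr = max(0, width - w - pl)
        fill = np.asarray(image_fill if image_fill is not None else [128, 128, 128])
        image = np.stack(
            [
                np.pad(image[..., c], ((pt, pb), (pl, pr)), constant_values=fill[c])
                for c in range(image.shape[2])
            ],
            axis=-1,
        ).astype(image.dtype)
        labels = np.pad(
            labels, ((pt, pb), (pl, pr)),
            constant_values=sample.labels.legend.avoid_index,
        )
        h, w = labels.shape
    top = (h - height) // 2
    left = (w - width) // 2
    image = image[top : top + height, left : left + width]
    labels = labels[top : top + height, left : left + width]
    return RoiSample(
        roi_id=sample.roi_id,
        patient_id=sample.patient_id,
        image=image,
        labels=LabelMap(labels, sample.labels.legend),
        microns_per_pixel=sample.microns_per_pixel,
    )


def compute_stats(train_samples) -> DatasetStats:
    """Per-channel mean and std over every pixel of the training-pool images."""
    train_samples = list(train_samples)
    if not train_samples:
        raise PreprocessingError("cannot compute statistics from an empty list")
    n = 0
    s1 = np.zeros(3)
    s2 = np.zeros(3)
    for s in train_samples:
        x = s.image.reshape(-1, 3).astype(np.float64)
        n += x.shape[0]
        s1 += x.sum(axis=0)
        s2 += (x * x).sum(axis=0)
    mean = s1 / n
    var = np.maximum(s2 / n - mean * mean, 0.0)
    return DatasetStats(
        per_channel_mean=mean,
        per_channel_std=np.sqrt(var),
        computed_over=[s.roi_id for s in train_samples],
    )


def standardize(image: np.ndarray, stats: DatasetStats, mean_only: bool = False) -> np.ndarray:
    """Standardize an RGB image against frozen dataset statistics.

    Default is (image - mean) / std per channel; ``mean_only`` subtracts the
    mean without scaling, the literal reading of mean-standardization.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise PreprocessingError(f"expected (H, W, 3), got {image.shape}")
    out = image.astype(np.float32) - stats.per_channel_mean.astype(np.float32)
    if not mean_only:
        out = out / stats.per_channel_std.astype(np.float32)
    return out
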