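"""Geometric augmentation of labeled tiles.

Per input image the augmenter emits the original (optional) plus exactly one
scaled copy, one vertically flipped copy, and ``n_rotations`` randomly rotated
copies, so the output count is ``N * (include_original + 2 + n_rotations)``.
Labels propagate unchanged and output order is original-first per input.

Geometry conventions (the source procedure leaves these open):

* "scaling by 20%" = resize by ``scale_factor`` (default 1.20) then
  center-crop back to the original height x width, so every output shares one
  geometry with its input;
* rotation angles are drawn uniformly from ``[-rotation_range_deg,
  +rotation_range_deg]`` (a draw of exactly 0 is redrawn), rotating about the
  center with reflection padding and bilinear interpolation;
* the vertical flip is a pure index reversal, hence an exact involution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from .datatypes import LabeledImageSet


@dataclass(frozen=True)
class AugmentationConfig:
    scale_factor: float = 1.20
    rotation_range_deg: float = 50.0
    n_rotations: int = 3
    include_original: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.rotation_range_deg <= 0:
            raise ValueError("rotation_range_deg must be > 0")
        if self.n_rotations < 0:
            raise ValueError("n_rotations must be >= 0")

    @property
    def variants_per_image(self) -> int:
        return int(self.include_original) + 2 + self.n_rotations


def vertical_flip(image: np.ndarray) -> np.ndarray:
    """Flip top-to-bottom; exact involution (no interpolation)."""
    return image[::-1].copy()


def scale_and_crop(image: np.ndarray, factor: float) -> np.ndarray:
    """Resize by ``factor`` (bilinear) then center-crop to the input shape."""
    h, w = image.shape[:2]
    nh, nw = max(h, round(h * factor)), max(w, round(w * factor))
    big = resize(image, (nh, nw), order=1, preserve_range=True,
                 anti_aliasing=factor < 1)
    top, left = (nh - h) // 2, (nw - w) // 2
    out = big[top:top + h, left:left + w]
    return np.clip(np.rint(out), 0, 255).astype(image.dtype)


def rotate_reflect(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the center with reflection padding, keeping the geometry."""
    out = rotate(image.astype(float), angle_deg, resize=False, order=1,
                 mode="reflect", preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(image.dtype)


class ImageAugmenter:
    """Estimator-style wrapper: ``transform`` applies the augmentation plan."""

    def __init__(self, scale_factor: float = 1.20, rotation_range_deg: float = 50.0,
                 n_rotations: int = 3, include_original: bool = True,
                 seed: int = 0):
        self.scale_factor = scale_factor
        self.rotation_range_deg = rotation_range_deg
        self.n_rotations = n_rotations
        self.include_original = include_original
        self.seed = seed

    @property
    def config(self) -> AugmentationConfig:
        return AugmentationConfig(self.scale_factor, self.rotation_range_deg,
                                  self.n_rotations, self.include_original,
                                  self.seed)

    def _draw_angles(self, rng: np.random.Generator) -> list[float]:
        angles = []
        r = self.rotation_range_deg
        for _ in range(self.n_rotations):
            a = 0.0
            while a == 0.0:  # exact 0 would duplicate the original
                a = float(rng.uniform(-r, r))
            angles.append(a)
        return angles

    def transform(self, image_set: LabeledImageSet) -> LabeledImageSet:
        cfg = self.config
        cfg.validate()
        if len(image_set) == 0:
            return LabeledImageSet(images=[], labels=np.array([], dtype=int),
                                   provenance=[])
        rng = np.random.default_rng(self.seed)
        images, labels, prov = [], [], []
        for img, lab in zip(image_set.images, image_set.labels):
            if img.size == 0:
                raise ValueError("degenerate image with zero pixels")
            if self.include_original:
                images.append(img.copy())
                prov.append("original")
                labels.append(lab)
            images.append(scale_and_crop(img, self.scale_factor))
            prov.append("scaled")
            labels.append(lab)
            images.append(vertical_flip(img))
            prov.append("flipped")
            labels.append(lab)
            for a in self._draw_angles(rng):
                images.append(rotate_reflect(img, a))
                prov.append(f"rotated({a:.3f})")
                labels.append(lab)
        return LabeledImageSet(images=images, labels=np.array(labels),
                               provenance=prov)


def augment(image_set: LabeledImageSet,
            cfg: AugmentationConfig | None = None) -> LabeledImageSet:
    """Functional entry point over :class:`ImageAugmenter`."""
    cfg = cfg or AugmentationConfig()
    return ImageAugmenter(cfg.scale_factor, cfg.rotation_range_deg,
                          cfg.n_rotations, cfg.include_original,
                          cfg.seed).transform(image_set)


def augmented_count(n_images: int, cfg: AugmentationConfig | None = None,
                    include_original: bool | None = None) -> int:
    """Expected output size; ``include_original=False`` counts new images only.

    Originals are tallied separately from the augmented copies (a dataset of
    481 tiles yields 5 x 481 = 2,405 new images under the defaults).
    """
    cfg = cfg or AugmentationConfig()
    inc = cfg.include_original if include_original is None else include_original
    return n_images * (int(inc) + 2 + cfg.n_rotations)
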