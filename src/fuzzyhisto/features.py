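"""Deep-feature extraction behind a pluggable backbone interface.

Preprocessing resizes every tile to ``input_size`` x ``input_size`` and
subtracts a per-channel reference intensity.  Extraction then maps each tile
to a fixed-length vector:

* ``backbone="resnet50"`` — the published 50-layer residual architecture,
  consumed through torchvision (never re-derived here).  At input 224 the
  final convolutional map is 7 x 7 x 2048, i.e. a 100,352-long flattened
  vector; the dimensionality is a pure function of (backbone, input_size)
  because the network downsamples by a factor of 32.
* ``backbone="stub"`` — a deterministic, dependency-free extractor (pooled
  per-channel block means and standard deviations) of configurable width,
  so the whole pipeline runs with zero network access.  Output SHAPE, not
  weight values, is the contract the rest of the pipeline depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .datatypes import FeatureTable, LabeledImageSet

#: Per-channel reference intensities (RGB, 0-255 scale) subtracted by default;
#: the conventional ImageNet channel means.  ``mean_subtraction="dataset"``
#: recomputes the mean from the batch instead.
DEFAULT_CHANNEL_MEAN = (123.68, 116.779, 103.939)

_RESNET50_DOWNSAMPLE = 32
_RESNET50_CHANNELS = 2048


@dataclass(frozen=True)
class FeatureExtractorConfig:
    input_size: int = 224
    backbone: str = "resnet50"
    pretrained: bool = False
    batch_size: int = 32
    mean_subtraction: tuple[float, float, float] | str = DEFAULT_CHANNEL_MEAN
    stub_width: int = 64

    def validate(self) -> None:
        if self.input_size <= 0:
            raise ValueError("input_size must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.backbone not in ("resnet50", "stub"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def expected_feature_dim(backbone: str, input_size: int = 224,
                         stub_width: int = 64) -> int:
    """Feature-vector length as a pure function of (backbone, input_size).

    The residual backbone downsamples by 32 and ends in 2048 channels, so at
    input 224 the flattened final map has 7*7*2048 = 100,352 entries.
    """
    if backbone == "resnet50":
        side = input_size // _RESNET50_DOWNSAMPLE
        if side < 1:
            raise ValueError("input_size too small for the resnet50 backbone")
        return side * side * _RESNET50_CHANNELS
    if backbone == "stub":
        return stub_width
    raise ValueError(f"unknown backbone {backbone!r}")


def preprocess(image_set: LabeledImageSet,
               cfg: FeatureExtractorConfig | None = None) -> LabeledImageSet:
    """Resize to ``input_size`` squared and subtract the per-channel mean.

    Order and labels are preserved; outputs are float rasters (mean
    subtraction makes negative values meaningful).
    """
    cfg = cfg or FeatureExtractorConfig()
    cfg.validate()
    if len(image_set) == 0:
        raise ValueError("empty image set")
    for img in image_set.images:
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("non-RGB input image")
    if cfg.mean_subtraction == "dataset":
        stacked = [
            resize(img.astype(float), (cfg.input_size, cfg.input_size),
                   order=1, preserve_range=True, anti_aliasing=True)
            for img in image_set.images
        ]
        mean = np.mean(stacked, axis=(0, 1, 2))
        out = [im - mean for im in stacked]
    else:
        mean = np.asarray(cfg.mean_subtraction, dtype=float)
        out = [
            resize(img.astype(float), (cfg.input_size, cfg.input_size),
                   order=1, preserve_range=True, anti_aliasing=True) - mean
            for img in image_set.images
        ]
    return LabeledImageSet(images=out, labels=image_set.labels.copy(),
                           provenance=list(image_set.provenance))


def _stub_features(image: np.ndarray, width: int) -> np.ndarray:
    """Spatial-pyramid intensity descriptor, truncated/padded to ``width``.

    Per-channel block means (then block standard deviations) over pyramid
    grids 1x1, 2x2, 4x4, 8x8, ... until ``width`` values exist.  Coarse
    levels come first, so the leading features are global intensity
    statistics — the highest-signal summary of tile texture density — and
    finer levels add localization.  Deterministic and a pure function of
    the pixel values.
    """
    h, w = image.shape[:2]
    chunks: list[np.ndarray] = []
    n = 0
    g = 1
    while n < width:
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, w, g + 1).astype(int)
        means, stds = [], []
        for i in range(g):
            for j in range(g):
                block = image[ys[i]:max(ys[i + 1], ys[i] + 1),
                              xs[j]:max(xs[j + 1], xs[j] + 1)]
                means.append(block.mean(axis=(0, 1)))
                stds.append(block.std(axis=(0, 1)))
        level = np.concatenate([np.ravel(means), np.ravel(stds)])
        chunks.append(level)
        n += level.size
        g *= 2
    vec = np.concatenate(chunks)
    return vec[:width]


def _resnet50_features(images: list[np.ndarray], cfg: FeatureExtractorConfig
                       ) -> np.ndarray:
    try:
        import torch
        from torchvision.models import resnet50
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "The 'resnet50' backbone requires torch and torchvision, which "
            "are not installed. Install them (pip install torch torchvision) "
            "or use backbone='stub' for a dependency-free extractor."
        ) from exc
    weights = "IMAGENET1K_V2" if cfg.pretrained else None
    model = resnet50(weights=weights)
    body = torch.nn.Sequential(*list(model.children())[:-2])  # drop pool+fc
    body.eval()
    rows = []
    with torch.no_grad():
        for start in range(0, len(images), cfg.batch_size):
            batch = np.stack(images[start:start + cfg.batch_size])
            t = torch.from_numpy(batch.transpose(0, 3, 1, 2)).float() / 255.0
            rows.append(body(t).numpy().reshape(len(batch), -1))
    return np.concatenate(rows, axis=0)


class DeepFeatureExtractor:
    """Images -> :class:`FeatureTable` through the configured backbone."""

    def __init__(self, cfg: FeatureExtractorConfig | None = None):
        self.cfg = cfg or FeatureExtractorConfig()

    def transform(self, image_set: LabeledImageSet,
                  preprocessed: bool = False) -> FeatureTable:
        cfg = self.cfg
        cfg.validate()
        imgs = image_set if preprocessed else preprocess(image_set, cfg)
        if cfg.backbone == "stub":
            rows = np.array([_stub_features(im, cfg.stub_width)
                             for im in imgs.images])
        else:
            rows = _resnet50_features(imgs.images, cfg)
        dim = expected_feature_dim(cfg.backbone, cfg.input_size, cfg.stub_width)
        assert rows.shape[1] == dim, (
            f"backbone produced {rows.shape[1]} features, expected {dim}"
        )
        ids = [f"{cfg.backbone}_{j}" for j in range(rows.shape[1])]
        return FeatureTable(rows, imgs.labels.copy(), ids)


def extract(image_set: LabeledImageSet,
            cfg: FeatureExtractorConfig | None = None) -> FeatureTable:
    """Preprocess then extract one feature row per image."""
    return DeepFeatureExtractor(cfg).transform(image_set)
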