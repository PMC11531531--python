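"""Seeded synthetic fixtures: blob-texture images and Gaussian feature tables.

Every downstream stage of the pipeline is exercised on these generators, so no
slide download is ever required.  The images are blob/texture fields — not
realistic tissue — whose blob density differs between classes by a controlled
effect size; the feature tables are Gaussian class-conditional draws with a
known set of informative dimensions.  Only statistical separability matters
for testing pipeline mechanics, not pathology realism.

Determinism contract: a fixed ``seed`` plus a fixed spec yields bit-identical
output.  Each generator derives its own named RNG stream from the seed, so
image and table generation never share or mutate global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureTable, LabeledImageSet

# Stream salts so the two generators draw from independent streams of one seed.
_IMAGE_STREAM = 101
_TABLE_STREAM = 202


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    class_separation is the standardized difference between class means
    (informative feature columns) or between per-class blob densities
    (images); noise_sd scales the additive Gaussian noise.
    """

    n_per_class: int = 50
    image_size: int = 64
    n_features: int = 50
    n_informative: int = 5
    class_separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_informative < 1 or self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative={self.n_informative} must lie in "
                f"[1, n_features={self.n_features}]"
            )


def _render_blobs(rng: np.random.Generator, size: int, n_blobs: int,
                  noise_sd: float) -> np.ndarray:
    """One RGB tile: soft Gaussian blobs on a bright background plus noise.

    Blobs are placed fully inside the tile with a narrow radius range so the
    total "ink" stays near-linear in the blob count — the count is the
    class-separating statistic, and heavy per-blob area variance or edge
    clipping would dilute it.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size))
    r_lo, r_hi = size / 16, size / 12
    for _ in range(n_blobs):
        r = rng.uniform(r_lo, r_hi)
        cy, cx = rng.uniform(r, size - r, 2)
        field += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
    img = 230.0 - 110.0 * np.minimum(field, 2.0)
    img = img[..., None] * np.array([1.0, 0.85, 0.95])  # faint stain-like tint
    img = img + rng.normal(0, 8.0 * noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_images(spec: FixtureSpec) -> LabeledImageSet:
    """Generate ``2 * n_per_class`` labeled tiles (labels 0...0,1...1).

    Class 1 tiles carry a higher blob density than class 0; the densities
    differ by ``class_separation`` standard deviations of the per-image
    blob-count jitter, so downstream extractors see a real textural signal.
    """
    spec.validate()
    rng = np.random.default_rng([_IMAGE_STREAM, spec.seed])
    base = max(4, spec.image_size // 8)
    jitter_sd = max(1.0, base / 6)
    shift = spec.class_separation * jitter_sd
    images, labels = [], []
    for cls in (0, 1):
        mean_blobs = base + (shift if cls == 1 else 0.0)
        for _ in range(spec.n_per_class):
            n_blobs = max(0, int(round(rng.normal(mean_blobs, jitter_sd))))
            images.append(_render_blobs(rng, spec.image_size, n_blobs, spec.noise_sd))
            labels.append(cls)
    return LabeledImageSet(images=images, labels=np.array(labels),
                           provenance=["original"] * len(images))


def make_feature_table(spec: FixtureSpec) -> FeatureTable:
    """Gaussian class-conditional feature table with planted informative dims.

    Exactly ``n_informative`` columns (indices recorded in the returned
    table's ``informative_ids`` attribute) have class means separated by
    ``class_separation * noise_sd``; every other column is pure
    ``N(0, noise_sd)`` noise in both classes.
    """
    spec.validate()
    rng = np.random.default_rng([_TABLE_STREAM, spec.seed])
    n = 2 * spec.n_per_class
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    y = np.repeat([0, 1], spec.n_per_class)
    X[np.ix_(y == 1, informative)] += spec.class_separation * spec.noise_sd
    ids = [f"f{j}" for j in range(spec.n_features)]
    table = FeatureTable(X, y, ids)
    table.informative_ids = [f"f{j}" for j in informative]  # type: ignore[attr-defined]
    return table
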