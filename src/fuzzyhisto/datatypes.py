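"""Shared data containers used between pipeline stages.

Two currencies flow through the pipeline: :class:`LabeledImageSet` (tiles with
binary labels, consumed by augmentation and feature extraction) and
:class:`FeatureTable` (samples x features matrix plus label vector, consumed by
selection, rule induction and classification).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class LabeledImageSet:
    """Images with binary class labels (0 = non-cancer, 1 = cancer).

    ``images`` holds height x width x 3 rasters (uint8 for raw tiles; float
    after mean subtraction).  ``provenance`` tags each image with how it was
    produced: ``"original"``, ``"scaled"``, ``"flipped"`` or ``"rotated(θ)"``.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if len(self.labels) and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        if not self.provenance:
            self.provenance = ["original"] * len(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def write(self, out_dir: str | Path, prefix: str = "img") -> Path:
        """Write PNGs plus a ``labels.csv`` (columns filename,label,provenance)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, lab, prov) in enumerate(
            zip(self.images, self.labels, self.provenance)
        ):
            name = f"{prefix}_{i:05d}.png"
            arr = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / name)
            rows.append({"filename": name, "label": int(lab), "provenance": prov})
        labels_path = out_dir / "labels.csv"
        pd.DataFrame(rows).to_csv(labels_path, index=False)
        return labels_path

    @classmethod
    def read(cls, image_dir: str | Path, labels_csv: str | Path) -> "LabeledImageSet":
        image_dir = Path(image_dir)
        df = pd.read_csv(labels_csv)
        images = [
            np.asarray(Image.open(image_dir / fn).convert("RGB"))
            for fn in df["filename"]
        ]
        prov = (
            list(df["provenance"])
            if "provenance" in df.columns
            else ["original"] * len(df)
        )
        return cls(images=images, labels=df["label"].to_numpy(), provenance=prov)


@dataclass
class FeatureTable:
    """Samples x features matrix with a label per row.

    ``feature_ids`` are stable per-column identifiers, preserved through
    selection so retained columns can be traced back to the extractor.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("row count does not match label count")
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError("column count does not match feature_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.matrix.size and not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_columns(self, ids: list[str]) -> "FeatureTable":
        index = {fid: j for j, fid in enumerate(self.feature_ids)}
        cols = [index[i] for i in ids]
        return FeatureTable(self.matrix[:, cols], self.labels.copy(), list(ids))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_ids)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        if "label" not in df.columns:
            raise ValueError("expected a 'label' column")
        feats = [c for c in df.columns if c != "label"]
        return cls(df[feats].to_numpy(float), df["label"].to_numpy(), feats)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def as_dict(obj) -> dict:
    """Dataclass -> plain dict (for manifests)."""
    return dataclasses.asdict(obj)
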