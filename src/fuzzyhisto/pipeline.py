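"""End-to-end orchestration: fixtures -> augmentation -> extraction ->
selection -> rule induction -> classifier -> evaluation.

Every stage writes its artifact into the run directory (feature tables as
CSV, rule bases and reports as JSON) together with a manifest recording the
full configuration, its hash and the seed, so a manifest fully determines a
run.  The membership-function comparison harness trains the classifier once
per membership kind under a shared seed and split and reports
rule-generation time plus train/test error per kind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures as fx
from .augmentation import AugmentationConfig, augment
from .classifier import FuzzyDeepClassifier
from .datatypes import FeatureTable
from .evaluation import confusion, metrics
from .features import FeatureExtractorConfig, extract
from .membership import build_partitions
from .rules import prefilter_and_rank, wang_mendel
from .selection import RFEConfig, rfe


@dataclass(frozen=True)
class RuleConfig:
    n_levels: int = 9
    mf_kind: str = "triangular"
    placement: str = "uniform"
    zero_frac_threshold: float = 0.10
    top_k: int = 8


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_dim: int = 128
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    validation_fraction: float = 0.2


@dataclass(frozen=True)
class PipelineConfig:
    """Nested stage configs plus the global seed and stage toggles."""

    seed: int = 0
    fixtures: fx.FixtureSpec = field(default_factory=fx.FixtureSpec)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    extractor: FeatureExtractorConfig = field(
        default_factory=lambda: FeatureExtractorConfig(
            input_size=64, backbone="stub", stub_width=48))
    rfe: RFEConfig = field(default_factory=lambda: RFEConfig(
        target_n_features=16))
    rules: RuleConfig = field(default_factory=RuleConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    do_augment: bool = True
    do_select: bool = True
    write_images: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = dict(d.get(key, {}))
            if "mean_subtraction" in sub and isinstance(
                    sub["mean_subtraction"], list):
                sub["mean_subtraction"] = tuple(sub["mean_subtraction"])
            return klass(**sub)

        return cls(
            seed=d.get("seed", 0),
            fixtures=build(fx.FixtureSpec, "fixtures"),
            augmentation=build(AugmentationConfig, "augmentation"),
            extractor=build(FeatureExtractorConfig, "extractor"),
            rfe=build(RFEConfig, "rfe"),
            rules=build(RuleConfig, "rules"),
            classifier=build(ClassifierConfig, "classifier"),
            do_augment=d.get("do_augment", True),
            do_select=d.get("do_select", True),
            write_images=d.get("write_images", False),
        )

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if "\n" not in text and Path(text).exists():  # a file path
                text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _reseed(cfg: PipelineConfig) -> PipelineConfig:
    """Propagate the global seed into every stage config."""
    return dataclasses.replace(
        cfg,
        fixtures=dataclasses.replace(cfg.fixtures, seed=cfg.seed),
        augmentation=dataclasses.replace(cfg.augmentation, seed=cfg.seed),
        rfe=dataclasses.replace(cfg.rfe, seed=cfg.seed),
    )


def _make_classifier(cfg: PipelineConfig, **overrides) -> FuzzyDeepClassifier:
    kw = dict(
        hidden_dim=cfg.classifier.hidden_dim,
        n_levels=cfg.rules.n_levels,
        mf_kind=cfg.rules.mf_kind,
        placement=cfg.rules.placement,
        top_k_rule_features=cfg.rules.top_k,
        zero_frac_threshold=cfg.rules.zero_frac_threshold,
        learning_rate=cfg.classifier.learning_rate,
        batch_size=cfg.classifier.batch_size,
        epochs=cfg.classifier.epochs,
        validation_fraction=cfg.classifier.validation_fraction,
        random_state=cfg.seed,
    )
    kw.update(overrides)
    return FuzzyDeepClassifier(**kw)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all enabled stages and write artifacts plus a report.

    Returns the report dict (also written to ``report.json``); the manifest
    in ``manifest.json`` carries the config, its hash and the seed.
    """
    cfg_in = cfg  # manifest records the caller's config; reseeding is derived
    cfg = _reseed(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    images = fx.make_images(cfg.fixtures)
    n_original = len(images)
    if cfg.do_augment:
        images = augment(images, cfg.augmentation)
    if cfg.write_images:
        images.write(out / "images")

    table = extract(images, cfg.extractor)
    table.to_csv(out / "features.csv")

    if cfg.do_select:
        rfe_cfg = dataclasses.replace(
            cfg.rfe,
            target_n_features=min(cfg.rfe.target_n_features, table.n_features))
        ranking, table = rfe(table, rfe_cfg)
        pd.DataFrame({"rank": np.arange(1, len(ranking.ranked_ids) + 1),
                      "feature_id": ranking.ranked_ids}).to_csv(
            out / "ranking.csv", index=False)
        table.to_csv(out / "selected.csv")

    model = _make_classifier(cfg)
    model.fit(table.matrix, table.labels, table.feature_ids)
    model.rule_base_.to_json(out / "rules.json")

    val_idx = model.val_indices_
    y_pred = model.predict(table.matrix[val_idx])
    report_metrics = metrics(confusion(table.labels[val_idx], y_pred))
    cm = confusion(table.labels[val_idx], y_pred)

    report = {
        "n_images_original": n_original,
        "n_images_total": len(images),
        "n_features_extracted": int(np.shape(
            pd.read_csv(out / "features.csv").columns)[0]) - 1,
        "n_features_selected": table.n_features,
        "rule_provenance": model.rule_base_.provenance,
        "final_train_accuracy": model.history_["train_accuracy"][-1],
        "final_val_accuracy": model.history_["val_accuracy"][-1],
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "metrics": report_metrics.to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    manifest = {"config": cfg_in.to_dict(), "config_hash": cfg_in.hash(),
                "seed": cfg.seed, "stages": {
                    "augment": cfg.do_augment, "select": cfg.do_select}}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return report


def compare_membership_functions(cfg: PipelineConfig,
                                 kinds: list[str]) -> pd.DataFrame:
    """Train once per membership kind under a shared seed and split.

    Returns a table with one row per kind: rule-generation time (seconds,
    hardware-dependent and reported only), final train error and test
    (validation) error.  Everything except the membership kind is held
    fixed, so differences are attributable to the kind alone.
    """
    if len(kinds) < 2:
        raise ValueError("need at least 2 membership kinds to compare")
    cfg = _reseed(cfg)
    images = fx.make_images(cfg.fixtures)
    if cfg.do_augment:
        images = augment(images, cfg.augmentation)
    table = extract(images, cfg.extractor)
    if cfg.do_select:
        rfe_cfg = dataclasses.replace(
            cfg.rfe,
            target_n_features=min(cfg.rfe.target_n_features, table.n_features))
        _, table = rfe(table, rfe_cfg)
    rows = []
    for kind in kinds:
        model = _make_classifier(cfg, mf_kind=kind)
        # time rule induction alone (the harness's reported "generation time")
        t0 = time.perf_counter()
        k = min(cfg.rules.top_k, table.n_features)
        ranked = prefilter_and_rank(table, cfg.rules.zero_frac_threshold, k,
                                    seed=cfg.seed)
        parts = build_partitions(ranked.matrix, ranked.feature_ids,
                                 n_levels=cfg.rules.n_levels, mf_kind=kind,
                                 placement=cfg.rules.placement, seed=cfg.seed)
        wang_mendel(ranked.matrix, ranked.labels, parts)
        rule_time = time.perf_counter() - t0
        model.fit(table.matrix, table.labels, table.feature_ids)
        rows.append({
            "membership_function": kind,
            "rule_time_s": rule_time,
            "train_error": 1.0 - model.history_["train_accuracy"][-1],
            "test_error": 1.0 - model.history_["val_accuracy"][-1],
        })
    return pd.DataFrame(rows)
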