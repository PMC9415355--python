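"""Orchestration of the two study designs.

**Sample-size sweep.** A fixed test set (default ten specimens per taxon) is
drawn once. For each training size n, a balanced subsample of n specimens
per taxon is taken from the remaining pool (nested across sizes, so larger
training sets strictly extend smaller ones), 10% of its specimens are carved
out for validation, one scorer is fitted, and every test frame is scored.
Metrics are reported for three decision schemes: per-image (each frame
judged alone), majority vote and max scoring sum (specimen level). The test
set is asserted — not assumed — to be identical across sizes, and no test
frame ever reaches the fitting routine.

**Grouped k-fold cross-validation.** Specimens are partitioned into k
stratified folds; each fold in turn is the test set, the remainder is split
into training and validation as in the sweep, and the fold's majority-vote
accuracy is recorded, yielding a mean and range over resampled test sets.

Frames whose blob detection fails are dropped with a logged count; a
specimen with no valid frame is excluded and reported. All randomness flows
from the config seed; sub-seeds are deterministic offsets so re-runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets as ds
from .classification import FeatureExtractor, ReferenceScorer, TrainConfig
from .evaluation import confusion, precision_recall
from .imaging import NoBlobFoundError, crop_with_mask, detect_blob, estimate_body_size
from .synthetic import SpecimenRecord, SyntheticTaxonSpec, generate_specimen
from .voting import SpecimenPrediction

__all__ = [
    "SweepConfig",
    "SweepResult",
    "SpecimenFeatures",
    "prepare_features",
    "synthesize_features",
    "run_sweep",
    "run_cv",
    "report",
    "SCHEMES",
]

logger = logging.getLogger(__name__)

SCHEMES = ("per_image", "majority", "score_sum")


@dataclass
class SweepConfig:
    sizes: tuple = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    n_test_per_taxon: int = 10
    validation_fraction: float = 0.10
    seed: int = 0
    voting_schemes: tuple = SCHEMES
    train: TrainConfig = field(default_factory=TrainConfig)
    crop_height: int = 496
    threshold: str | float = "otsu"

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")
        unknown = set(self.voting_schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown voting schemes: {sorted(unknown)}")


@dataclass
class SpecimenFeatures:
    """Per-frame feature matrix and silhouette areas for one specimen."""

    specimen_id: str
    taxon_id: int
    X: np.ndarray  # (n_valid_frames, n_features)
    areas_px: np.ndarray
    n_dropped: int


@dataclass
class SweepResult:
    sizes: list
    schemes: list
    class_labels: list
    test_ids: list
    reports: dict  # (size, scheme) -> MetricsReport
    confusions: dict  # (size, scheme) -> ConfusionMatrix
    training_summaries: dict  # size -> {best_epoch, n_epochs, val_accuracy}
    mean_size_mm2: dict  # taxon_id -> mean test-specimen body size (mm2)
    config: SweepConfig


def _manifest_of(items: dict) -> pd.DataFrame:
    """Manifest from SpecimenRecords or SpecimenFeatures (both carry taxon)."""
    rows = []
    for sid, rec in sorted(items.items()):
        n = rec.n_frames if isinstance(rec, SpecimenRecord) else len(rec.X) + rec.n_dropped
        rows.append({"specimen_id": sid, "taxon": rec.taxon_id, "n_frames": n})
    return pd.DataFrame(rows, columns=["specimen_id", "taxon", "n_frames"])


def prepare_features(
    records: dict[str, SpecimenRecord],
    extractor: FeatureExtractor,
    threshold: str | float = "otsu",
    crop_height: int = 496,
) -> dict[str, SpecimenFeatures]:
    """Detect, crop and featurize every frame of every specimen, once.

    Frames with no detectable blob are dropped (logged); specimens losing all
    frames are excluded with a warning.
    """
    out: dict[str, SpecimenFeatures] = {}
    total_dropped = 0
    for sid, rec in sorted(records.items()):
        feats, areas = [], []
        dropped = 0
        for frame in rec.frames:
            try:
                blob = detect_blob(frame, threshold)
            except NoBlobFoundError:
                dropped += 1
                continue
            cropped, mask = crop_with_mask(frame, blob, crop_height)
            feats.append(extractor.from_mask(cropped, mask))
            areas.append(blob.n_foreground)
        total_dropped += dropped
        if not feats:
            logger.warning("specimen %s has no valid frames; excluded", sid)
            continue
        out[sid] = SpecimenFeatures(
            sid, rec.taxon_id, np.array(feats), np.array(areas, dtype=float), dropped
        )
    if total_dropped:
        logger.info("dropped %d frames with failed blob detection", total_dropped)
    return out


def synthesize_features(
    specs: list[SyntheticTaxonSpec],
    n_specimens_per_taxon: int,
    frames_base: float,
    seed: int,
    extractor: FeatureExtractor | None = None,
    threshold: str | float = "otsu",
    crop_height: int = 496,
) -> dict[str, SpecimenFeatures]:
    """Generate a synthetic dataset and featurize it specimen by specimen.

    Frames are discarded as soon as they are featurized, so memory stays
    proportional to one specimen's sequence rather than the whole archive.
    """
    extractor = extractor or FeatureExtractor()
    out: dict[str, SpecimenFeatures] = {}
    for spec in specs:
        for j in range(n_specimens_per_taxon):
            sid = f"{spec.name}_s{j:03d}"
            rec = generate_specimen(spec, sid, frames_base, seed)
            feats = prepare_features({sid: rec}, extractor, threshold, crop_height)
            out.update(feats)
    return out


def _stack(features: dict[str, SpecimenFeatures], ids) -> tuple[np.ndarray, np.ndarray]:
    blocks, labels = [], []
    for sid in sorted(ids):
        sf = features[sid]
        blocks.append(sf.X)
        labels.append(np.full(len(sf.X), sf.taxon_id, dtype=int))
    return np.vstack(blocks), np.concatenate(labels)


def _fit_one(
    features: dict[str, SpecimenFeatures],
    train_ids: set,
    val_ids: set,
    class_labels: list,
    train_cfg: TrainConfig,
) -> ReferenceScorer:
    X, y = _stack(features, train_ids)
    Xv, yv = _stack(features, val_ids)
    lut = {lab: i for i, lab in enumerate(class_labels)}
    scorer = ReferenceScorer(train_cfg)
    scorer.fit_matrix(
        X,
        np.array([lut[v] for v in y]),
        Xv,
        np.array([lut[v] for v in yv]),
        class_labels=class_labels,
    )
    return scorer


def _evaluate(
    scorer: ReferenceScorer,
    features: dict[str, SpecimenFeatures],
    test_ids: set,
    class_labels: list,
    schemes,
) -> tuple[dict, dict]:
    """Score all test frames and tally metrics for each decision scheme."""
    img_true, img_pred = [], []
    spec_true, spec_maj, spec_sum = [], [], []
    for sid in sorted(test_ids):
        sf = features[sid]
        scores = scorer.score_matrix(sf.X)
        pred = SpecimenPrediction.from_scores(sid, scores)
        img_true.extend([sf.taxon_id] * len(sf.X))
        img_pred.extend(class_labels[c] for c in pred.per_image_classes)
        spec_true.append(sf.taxon_id)
        spec_maj.append(class_labels[pred.voted_class_majority])
        spec_sum.append(class_labels[pred.voted_class_scoresum])
    reports, confusions = {}, {}
    tallies = {
        "per_image": (img_true, img_pred),
        "majority": (spec_true, spec_maj),
        "score_sum": (spec_true, spec_sum),
    }
    for scheme in schemes:
        cm = confusion(*tallies[scheme], class_labels)
        reports[scheme] = precision_recall(cm)
        confusions[scheme] = cm
    return reports, confusions


def run_sweep(
    records: dict[str, SpecimenRecord] | None,
    cfg: SweepConfig,
    features: dict[str, SpecimenFeatures] | None = None,
) -> SweepResult:
    """Run the balanced sample-size sweep.

    Give either raw ``records`` (featurized here) or precomputed ``features``
    (e.g. from :func:`synthesize_features`, shared across several sweeps).
    """
    if records is None and features is None:
        raise ValueError("either records or features required")
    manifest = _manifest_of(records if records is not None else features)
    class_labels = sorted(manifest["taxon"].unique())
    split = ds.assign_test_split(manifest, cfg.n_test_per_taxon, cfg.seed)
    pool, test_ids = split.train, split.test
    # fail fast on infeasible sizes, before any training
    per_taxon_pool = manifest[manifest["specimen_id"].isin(pool)].groupby("taxon").size()
    max_usable = int(per_taxon_pool.min())
    for n in cfg.sizes:
        if n > max_usable:
            raise ds.InsufficientSpecimensError(
                f"size {n} exceeds smallest per-taxon pool {max_usable}"
            )
    if features is None:
        features = prepare_features(
            records, FeatureExtractor(cfg.train.pixel_side), cfg.threshold, cfg.crop_height
        )
    test_ids = {t for t in test_ids if t in features}

    reports, confusions, summaries = {}, {}, {}
    reference_test = sorted(test_ids)
    for n in cfg.sizes:
        chosen = ds.subsample_balanced(manifest, pool, n, cfg.seed)
        train_ids, val_ids = ds.split_validation(
            manifest, chosen, cfg.validation_fraction, cfg.seed
        )
        assert not (chosen & test_ids), "leakage: training subsample met test set"
        assert sorted(test_ids) == reference_test, "test set drifted across sizes"
        scorer = _fit_one(
            features,
            train_ids & features.keys(),
            val_ids & features.keys(),
            class_labels,
            cfg.train,
        )
        size_reports, size_cms = _evaluate(
            scorer, features, test_ids, class_labels, cfg.voting_schemes
        )
        for scheme in cfg.voting_schemes:
            reports[(n, scheme)] = size_reports[scheme]
            confusions[(n, scheme)] = size_cms[scheme]
        log = scorer.training_log
        summaries[n] = {
            "best_epoch": scorer.best_epoch,
            "n_epochs": len(log),
            "val_accuracy": log[scorer.best_epoch]["val_accuracy"],
        }

    mean_sizes = {}
    for taxon in class_labels:
        areas = [
            features[sid].areas_px.mean()
            for sid in test_ids
            if features[sid].taxon_id == taxon
        ]
        if areas:
            mean_sizes[taxon] = estimate_body_size(areas).mean_area_mm2
    return SweepResult(
        sizes=list(cfg.sizes),
        schemes=list(cfg.voting_schemes),
        class_labels=class_labels,
        test_ids=reference_test,
        reports=reports,
        confusions=confusions,
        training_summaries=summaries,
        mean_size_mm2=mean_sizes,
        config=cfg,
    )


def run_cv(
    records: dict[str, SpecimenRecord] | None,
    k: int = 10,
    cfg: SweepConfig | None = None,
    features: dict[str, SpecimenFeatures] | None = None,
) -> dict:
    """Grouped k-fold cross-validation; reports per-fold majority accuracy."""
    cfg = cfg or SweepConfig()
    if records is None and features is None:
        raise ValueError("either records or features required")
    manifest = _manifest_of(records if records is not None else features)
    class_labels = sorted(manifest["taxon"].unique())
    folds = ds.grouped_kfold(manifest, k, cfg.seed)
    if features is None:
        features = prepare_features(
            records, FeatureExtractor(cfg.train.pixel_side), cfg.threshold, cfg.crop_height
        )
    accuracies = []
    for fold in range(k):
        test_ids = folds.fold_members(fold) & features.keys()
        pool = set(manifest["specimen_id"]) - folds.fold_members(fold)
        train_ids, val_ids = ds.split_validation(
            manifest, pool, cfg.validation_fraction, cfg.seed + fold
        )
        scorer = _fit_one(
            features,
            train_ids & features.keys(),
            val_ids & features.keys(),
            class_labels,
            cfg.train,
        )
        _, cms = _evaluate(scorer, features, test_ids, class_labels, ("majority",))
        cm = cms["majority"]
        accuracies.append(float(np.trace(cm.counts) / cm.total))
    return {
        "per_fold_accuracy": accuracies,
        "mean": float(np.mean(accuracies)),
        "min": float(np.min(accuracies)),
        "max": float(np.max(accuracies)),
        "k": k,
    }


def report(result: SweepResult, out_dir: str | Path) -> dict[str, Path]:
    """Write metrics JSON, confusion CSVs, learning-curve and size tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    metrics = {
        f"{size}_{scheme}": rep.to_dict() for (size, scheme), rep in sorted(result.reports.items())
    }
    paths["metrics"] = out / "metrics.json"
    paths["metrics"].write_text(json.dumps(metrics, indent=1))

    curve_rows = []
    for (size, scheme), rep in sorted(result.reports.items()):
        curve_rows.append(
            {
                "size": size,
                "scheme": scheme,
                "accuracy": rep.accuracy,
                "macro_precision": rep.macro_precision,
                "macro_recall": rep.macro_recall,
                "ci95_precision_lo": rep.ci95_precision[0],
                "ci95_precision_hi": rep.ci95_precision[1],
                "ci95_recall_lo": rep.ci95_recall[0],
                "ci95_recall_hi": rep.ci95_recall[1],
            }
        )
    paths["learning_curve"] = out / "learning_curve.csv"
    pd.DataFrame(curve_rows).to_csv(paths["learning_curve"], index=False)

    for (size, scheme), cm in sorted(result.confusions.items()):
        path = out / f"confusion_{size:02d}_{scheme}.csv"
        cm.to_frame().to_csv(path)
        paths[f"confusion_{size}_{scheme}"] = path

    size_rows = []
    for (size, scheme), rep in sorted(result.reports.items()):
        if scheme != "majority":
            continue
        for i, taxon in enumerate(result.class_labels):
            size_rows.append(
                {
                    "taxon": taxon,
                    "mean_size_mm2": result.mean_size_mm2.get(taxon),
                    "precision": float(rep.per_class_precision[i]),
                    "training_size": size,
                }
            )
    paths["size_precision"] = out / "size_precision.csv"
    pd.DataFrame(size_rows).to_csv(paths["size_precision"], index=False)

    run_manifest = {
        "seed": result.config.seed,
        "sizes": result.sizes,
        "schemes": result.schemes,
        "n_test_per_taxon": result.config.n_test_per_taxon,
        "validation_fraction": result.config.validation_fraction,
        "test_ids": result.test_ids,
        "training_summaries": {str(k): v for k, v in result.training_summaries.items()},
    }
    paths["run_manifest"] = out / "run_manifest.json"
    paths["run_manifest"].write_text(json.dumps(run_manifest, indent=1))
    return paths
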