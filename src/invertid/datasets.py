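"""Specimen-grouped dataset splits.

All frames of a specimen stay in exactly one partition (train, validation or
test), so no pixel-level information leaks between partitions. The module
builds, from a manifest (``specimen_id``, ``taxon``, ``n_frames``):

* a fixed test set of ``n_test_per_taxon`` specimens per taxon, identical for
  every model in an experiment;
* balanced training subsamples for the sample-size sweep, *nested* so the
  subsample for n specimens per taxon is a subset of the one for n' > n under
  the same seed — learning curves then differ only by added data;
* a stratified validation carve-out (per-taxon count = max(1, round-half-up
  of fraction x n));
* stratified grouped k-fold assignments whose per-taxon fold sizes differ by
  at most one.

Everything is deterministic given (manifest, seed). Splits serialize to JSON
as ``{"test": [...], "sweeps": {"5": {"train": [...], "val": [...]}, ...}}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetSplit",
    "FoldAssignment",
    "InsufficientSpecimensError",
    "assign_test_split",
    "subsample_balanced",
    "split_validation",
    "grouped_kfold",
    "save_splits",
]


class InsufficientSpecimensError(ValueError):
    """A taxon has too few specimens for the requested split."""


@dataclass
class DatasetSplit:
    train: set = field(default_factory=set)
    validation: set = field(default_factory=set)
    test: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.train & self.validation) or (self.train & self.test) or (
            self.validation & self.test
        ):
            raise ValueError("train/validation/test must be pairwise disjoint")


@dataclass
class FoldAssignment:
    fold_of: dict  # specimen_id -> fold index
    k: int

    def fold_members(self, fold: int) -> set:
        return {s for s, f in self.fold_of.items() if f == fold}


def _by_taxon(manifest: pd.DataFrame) -> dict[str, list[str]]:
    """Specimen ids per taxon, in manifest order (stable)."""
    groups: dict[str, list[str]] = {}
    for sid, taxon in zip(manifest["specimen_id"], manifest["taxon"]):
        groups.setdefault(taxon, []).append(sid)
    return groups


def _shuffled(ids: list[str], rng: np.random.Generator) -> list[str]:
    ids = sorted(ids)  # stable base order independent of manifest row order
    perm = rng.permutation(len(ids))
    return [ids[i] for i in perm]


def assign_test_split(
    manifest: pd.DataFrame, n_test_per_taxon: int = 10, seed: int = 0
) -> DatasetSplit:
    """Draw the fixed test set: n specimens per taxon, uniformly without
    replacement; the remainder is the training pool (returned in ``train``).
    """
    if n_test_per_taxon < 0:
        raise ValueError("n_test_per_taxon must be >= 0")
    rng = np.random.default_rng(seed)
    test: set = set()
    pool: set = set()
    for taxon, ids in sorted(_by_taxon(manifest).items()):
        if len(ids) <= n_test_per_taxon and n_test_per_taxon > 0:
            raise InsufficientSpecimensError(
                f"taxon {taxon!r} has {len(ids)} specimens, needs "
                f"> {n_test_per_taxon} to keep a training pool"
            )
        shuffled = _shuffled(ids, rng)
        test.update(shuffled[:n_test_per_taxon])
        pool.update(shuffled[n_test_per_taxon:])
    return DatasetSplit(train=pool, test=test)


def subsample_balanced(
    manifest: pd.DataFrame, pool: set, n_per_taxon: int, seed: int = 0
) -> set:
    """Balanced subsample: exactly n specimens per taxon from the pool.

    Nested under a fixed seed: each taxon's pool is shuffled once and the
    first n taken, so subsample(n) is a subset of subsample(n') for n' > n.
    """
    if n_per_taxon < 1:
        raise ValueError("n_per_taxon must be positive")
    rng = np.random.default_rng(seed)
    chosen: set = set()
    for taxon, ids in sorted(_by_taxon(manifest).items()):
        avail = [s for s in ids if s in pool]
        if len(avail) < n_per_taxon:
            raise InsufficientSpecimensError(
                f"taxon {taxon!r} has {len(avail)} pool specimens < {n_per_taxon}"
            )
        chosen.update(_shuffled(avail, rng)[:n_per_taxon])
    return chosen


def split_validation(
    manifest: pd.DataFrame, training_ids: set, fraction: float = 0.10, seed: int = 0
) -> tuple[set, set]:
    """Carve a stratified validation set out of the training specimens.

    Per-taxon validation count = max(1, round-half-up(fraction x n_taxon)).
    Returns (train, validation): disjoint and exhaustive over the input.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: set = set()
    val: set = set()
    for taxon, ids in sorted(_by_taxon(manifest).items()):
        members = [s for s in ids if s in training_ids]
        if not members:
            continue
        if len(members) < 2:
            raise InsufficientSpecimensError(
                f"taxon {taxon!r} has a single training specimen; cannot carve "
                "validation"
            )
        n_val = max(1, int(np.floor(fraction * len(members) + 0.5)))
        shuffled = _shuffled(members, rng)
        val.update(shuffled[:n_val])
        train.update(shuffled[n_val:])
    return train, val


def grouped_kfold(manifest: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified specimen-level k-fold partition.

    Each taxon's specimens are shuffled and dealt round-robin across folds,
    so per-taxon fold sizes differ by at most one and no specimen (hence no
    frame) appears in two folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups = _by_taxon(manifest)
    short = [t for t, ids in groups.items() if len(ids) < k]
    if short:
        raise ValueError(f"taxa with fewer than k={k} specimens: {sorted(short)}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for taxon, ids in sorted(groups.items()):
        shuffled = _shuffled(ids, rng)
        offset = int(rng.integers(k))  # rotate so remainders spread across folds
        for i, sid in enumerate(shuffled):
            fold_of[sid] = (i + offset) % k
    return FoldAssignment(fold_of, k)


def save_splits(path: str | Path, test: set, sweeps: dict[int, tuple[set, set]]) -> None:
    """Serialize a test set and per-size (train, validation) splits to JSON."""
    payload = {
        "test": sorted(test),
        "sweeps": {
            str(n): {"train": sorted(tr), "val": sorted(va)}
            for n, (tr, va) in sorted(sweeps.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
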