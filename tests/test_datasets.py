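"""Split logic: grouping, balance, nesting, leakage impossibility."""

import json

import numpy as np
import pytest

from invertid import datasets as ds

from conftest import make_manifest


def image_ids(manifest, specimen_ids):
    """Expand specimen ids to (specimen, frame) pairs for image-level checks."""
    frames = dict(zip(manifest["specimen_id"], manifest["n_frames"]))
    return {(s, k) for s in specimen_ids for k in range(frames[s])}


class TestAssignTestSplit:
    def test_ten_per_taxon_from_16x60(self, manifest_16x60):
        split = ds.assign_test_split(manifest_16x60, 10, seed=1)
        assert len(split.test) == 160
        assert len(split.train) == 800
        per_taxon = manifest_16x60.set_index("specimen_id").loc[sorted(split.test)]
        assert per_taxon.groupby("taxon").size().eq(10).all()

    def test_zero_test_specimens_is_identity_pool(self, manifest_16x60):
        split = ds.assign_test_split(manifest_16x60, 0, seed=1)
        assert split.test == set()
        assert len(split.train) == 960

    def test_taxon_too_small_is_an_error(self):
        manifest = make_manifest(3, 10)
        with pytest.raises(ds.InsufficientSpecimensError, match="t00"):
            ds.assign_test_split(manifest, 10, seed=0)

    def test_deterministic(self, manifest_16x60):
        a = ds.assign_test_split(manifest_16x60, 10, seed=5)
        b = ds.assign_test_split(manifest_16x60, 10, seed=5)
        assert a.test == b.test and a.train == b.train


class TestSubsampleBalanced:
    def test_balanced_counts(self, manifest_16x60):
        pool = ds.assign_test_split(manifest_16x60, 10, seed=0).train
        sub = ds.subsample_balanced(manifest_16x60, pool, 5, seed=0)
        assert len(sub) == 80
        taxa = manifest_16x60.set_index("specimen_id").loc[sorted(sub), "taxon"]
        assert taxa.value_counts().eq(5).all()

    def test_saturation_returns_whole_pool(self):
        manifest = make_manifest(2, 8)
        pool = set(manifest["specimen_id"])
        assert ds.subsample_balanced(manifest, pool, 8, seed=1) == pool

    def test_nested_across_sizes(self, manifest_16x60):
        """subsample(n) is contained in subsample(n') for n < n', many seeds."""
        pool = ds.assign_test_split(manifest_16x60, 10, seed=0).train
        for seed in range(20):
            small = ds.subsample_balanced(manifest_16x60, pool, 10, seed=seed)
            large = ds.subsample_balanced(manifest_16x60, pool, 20, seed=seed)
            assert small < large

    def test_infeasible_size_is_an_error(self):
        manifest = make_manifest(2, 4)
        with pytest.raises(ds.InsufficientSpecimensError):
            ds.subsample_balanced(manifest, set(manifest["specimen_id"]), 5, seed=0)


class TestSplitValidation:
    def test_ten_percent_of_50_is_5(self, manifest_16x60):
        pool = ds.assign_test_split(manifest_16x60, 10, seed=0).train
        chosen = ds.subsample_balanced(manifest_16x60, pool, 50, seed=0)
        train, val = ds.split_validation(manifest_16x60, chosen, 0.10, seed=0)
        assert len(val) == 80  # 5 per taxon x 16
        assert len(train) == 720

    def test_floor_of_one_validation_specimen(self):
        manifest = make_manifest(2, 5)
        train, val = ds.split_validation(
            manifest, set(manifest["specimen_id"]), 0.10, seed=0
        )
        taxa = manifest.set_index("specimen_id").loc[sorted(val), "taxon"]
        assert taxa.value_counts().eq(1).all()  # max(1, round(0.5)) = 1

    def test_partition_exact(self, manifest_16x60):
        ids = set(manifest_16x60["specimen_id"])
        train, val = ds.split_validation(manifest_16x60, ids, 0.10, seed=3)
        assert train | val == ids
        assert train & val == set()

    def test_singleton_taxon_is_an_error(self):
        manifest = make_manifest(2, 3)
        ids = set(manifest["specimen_id"]) - {"t00_s001", "t00_s002"}
        with pytest.raises(ds.InsufficientSpecimensError):
            ds.split_validation(manifest, ids, 0.10, seed=0)


class TestGroupedKFold:
    def test_60_specimens_10_folds_means_6_each(self, manifest_16x60):
        folds = ds.grouped_kfold(manifest_16x60, 10, seed=0)
        by_taxon = dict(zip(manifest_16x60["specimen_id"], manifest_16x60["taxon"]))
        for fold in range(10):
            members = folds.fold_members(fold)
            counts = {}
            for sid in members:
                counts[by_taxon[sid]] = counts.get(by_taxon[sid], 0) + 1
            assert all(v == 6 for v in counts.values())

    def test_degenerate_k_rejected(self, manifest_16x60):
        with pytest.raises(ValueError):
            ds.grouped_kfold(manifest_16x60, 1, seed=0)

    def test_k_larger_than_smallest_taxon_rejected(self):
        with pytest.raises(ValueError):
            ds.grouped_kfold(make_manifest(3, 5), 8, seed=0)

    def test_partition_and_balance_over_random_manifests(self):
        """Every specimen in exactly one fold; per-taxon fold sizes within 1."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            n_taxa = int(rng.integers(2, 6))
            n_spec = int(rng.integers(5, 30))
            k = int(rng.integers(2, min(n_spec, 8) + 1))
            manifest = make_manifest(n_taxa, n_spec, rng)
            folds = ds.grouped_kfold(manifest, k, seed=int(rng.integers(1000)))
            assert set(folds.fold_of) == set(manifest["specimen_id"])
            by_taxon = dict(zip(manifest["specimen_id"], manifest["taxon"]))
            for taxon in set(by_taxon.values()):
                sizes = [
                    sum(
                        1
                        for s, f in folds.fold_of.items()
                        if f == fold and by_taxon[s] == taxon
                    )
                    for fold in range(k)
                ]
                assert max(sizes) - min(sizes) <= 1


class TestLeakage:
    def test_image_sets_pairwise_disjoint(self, manifest_16x60):
        split = ds.assign_test_split(manifest_16x60, 10, seed=2)
        chosen = ds.subsample_balanced(manifest_16x60, split.train, 20, seed=2)
        train, val = ds.split_validation(manifest_16x60, chosen, 0.10, seed=2)
        imgs = [image_ids(manifest_16x60, s) for s in (train, val, split.test)]
        assert not (imgs[0] & imgs[1])
        assert not (imgs[0] & imgs[2])
        assert not (imgs[1] & imgs[2])


def test_save_splits_roundtrip(tmp_path, manifest_16x60):
    split = ds.assign_test_split(manifest_16x60, 10, seed=0)
    chosen = ds.subsample_balanced(manifest_16x60, split.train, 5, seed=0)
    tr, va = ds.split_validation(manifest_16x60, chosen, 0.10, seed=0)
    path = tmp_path / "splits.json"
    ds.save_splits(path, split.test, {5: (tr, va)})
    payload = json.loads(path.read_text())
    assert set(payload["test"]) == split.test
    assert set(payload["sweeps"]["5"]["train"]) == tr
    assert set(payload["sweeps"]["5"]["val"]) == va
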