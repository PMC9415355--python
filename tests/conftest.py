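"""Shared fixtures: tiny synthetic communities and manifests.

Image-bearing fixtures are deliberately small (few taxa, few frames) so the
unit suite stays fast; the heavier desk-scale experiments live in the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from invertid.classification import FeatureExtractor
from invertid.experiment import prepare_features
from invertid.synthetic import Frame, generate_specimen, make_taxon_specs


@pytest.fixture(scope="session")
def specs4():
    """Four distinct taxa with comparable sinking speeds (few frames each)."""
    return make_taxon_specs(4, seed=11, speed_range=(2.5, 5.0))


@pytest.fixture(scope="session")
def tiny_records(specs4):
    """4 taxa x 6 specimens, ~4-8 frames each, in memory."""
    records = {}
    for spec in specs4:
        for j in range(6):
            sid = f"{spec.name}_s{j:03d}"
            records[sid] = generate_specimen(spec, sid, frames_base=20.0, seed=7)
    return records


@pytest.fixture(scope="session")
def tiny_features(tiny_records):
    return prepare_features(tiny_records, FeatureExtractor(8))


def make_manifest(n_taxa: int, n_specimens: int, rng=None) -> pd.DataFrame:
    """Synthetic manifest (no images) for split logic tests."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for t in range(n_taxa):
        for j in range(n_specimens):
            rows.append(
                {
                    "specimen_id": f"t{t:02d}_s{j:03d}",
                    "taxon": f"t{t:02d}",
                    "n_frames": int(rng.integers(1, 30)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def manifest_16x60():
    return make_manifest(16, 60)


def block_frame(
    height: int = 64,
    width: int = 64,
    block=(20, 30, 20, 30),
    fg: float = 0.1,
    bg: float = 0.95,
) -> Frame:
    """A frame with one dark rectangle; block = (r0, r1, c0, c1) half-open."""
    pixels = np.full((height, width), bg)
    r0, r1, c0, c1 = block
    pixels[r0:r1, c0:c1] = fg
    return Frame(pixels)
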