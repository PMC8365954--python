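"""Shared fixtures: a small deterministic synthetic study and its datasets."""

from __future__ import annotations

import numpy as np
import pytest

from chromloop import dataset_builder as db
from chromloop.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study: 4 x 3 Mb chromosomes, 300 convergent loops."""
    cfg = SimConfig(
        chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 5)},
        n_open_regions=2000,
        n_positive_loops=300,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_datasets(small_study):
    """Distance-matched dataset + split built from the small study."""
    pos = db.extract_positive_pairs(small_study.loops, small_study.regions)
    pool = db.regions_without_loop_anchors(small_study.regions, pos)
    neg = db.sample_distance_matched_negatives(pos, ratio=5, seed=7, anchors=pool)
    split = db.DatasetSplit.default(sorted(small_study.genome.chrom_lengths))
    return {"positives": pos, "negatives": neg, "pool": pool, "split": split}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
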