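"""Shared fixtures: one simulated demo dataset reused across the suite."""

import numpy as np
import pytest

from spatmet import simulate_dataset
from spatmet.qc import noise_scores, remove_background
from spatmet.regions import RegionMask

DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo():
    """Demo-scale synthetic dataset with planted ground truth."""
    fm, truth = simulate_dataset(seed=DEMO_SEED)
    return fm, truth


@pytest.fixture(scope="session")
def demo_filtered(demo):
    """Demo dataset after background removal and noise filtering.

    Returns a dict with the tissue-only matrix, the noise-score table,
    the filtered matrix, and the index maps needed to compare filtered
    ion indices against the ground truth.
    """
    fm, truth = demo
    tissue = RegionMask("tissue", truth.tissue_pixels)
    table = noise_scores(fm, tissue)
    fm_tissue = remove_background(fm, tissue)
    keep = np.flatnonzero(table["noise_score"].to_numpy() >= 30)
    fm_filtered = fm_tissue.subset_ions(keep)
    return {
        "fm": fm,
        "truth": truth,
        "tissue": tissue,
        "table": table,
        "fm_tissue": fm_tissue,
        "keep": keep,                       # filtered index -> original index
        "orig_of": {int(n): int(o) for n, o in enumerate(keep)},
        "fm_filtered": fm_filtered,
    }


@pytest.fixture
def tiny_fm():
    """A 2x2 grid with 3 ions and hand-set intensities."""
    from spatmet import FeatureMatrix

    coords = [(0, 0), (1, 0), (0, 1), (1, 1)]
    mz = [100.0, 200.0, 300.0]
    inten = np.array(
        [[1.0, 10.0, 0.0],
         [2.0, 20.0, 0.0],
         [3.0, 30.0, 5.0],
         [4.0, 40.0, 0.0]]
    )
    return FeatureMatrix(coords, mz, inten)
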