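import logging

import numpy as np
import pytest

from stsradiomics.cohort import CohortSpec, generate_cohort

logging.getLogger("stsradiomics").setLevel(logging.ERROR)
logging.getLogger("stsradiomics.impute").setLevel(logging.ERROR)

# small, fast learner for tests that only exercise plumbing, not ranking power
TINY_LEARNER = {
    "n_estimators": 20,
    "max_depth": 2,
    "learning_rate": 0.4,
    "objective": "multi:softprob",
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
}


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects (10 per class), 60 features, strong planted signal."""
    spec = CohortSpec(
        class_counts=(10, 10, 10, 10, 10, 10),
        n_features_total=60,
        n_informative_per_class=3,
        effect_size=2.5,
        n_redundant_pairs=3,
        volume_link_fraction=0.1,
        missing_fraction=0.2,
    )
    subjects, table = generate_cohort(spec, seed=42)
    return spec, subjects, table


@pytest.fixture(scope="session")
def texture_fixtures():
    """Small discretized volumes (<= 6x6x6) with masks, for oracle sweeps."""
    rng = np.random.default_rng(7)
    cases = []
    # structured 4x4x1 slice from the quadrant pattern
    quad = np.array([[[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]]])
    cases.append((quad, np.ones_like(quad, bool), 4))
    # random small volumes, full and ragged masks
    for shape, n_bins in [((3, 3, 3), 3), ((4, 4, 4), 4), ((6, 6, 6), 5), ((5, 6, 4), 6)]:
        lv = rng.integers(1, n_bins + 1, size=shape)
        full = np.ones(shape, bool)
        ragged = rng.random(shape) > 0.3
        if not ragged.any():
            ragged[0, 0, 0] = True
        cases.append((lv.copy(), full, n_bins))
        cases.append((lv.copy(), ragged, n_bins))
    # constant volume
    cases.append((np.ones((3, 3, 3), int), np.ones((3, 3, 3), bool), 3))
    out = []
    for lv, mask, n_bins in cases:
        lv = lv.astype(np.int32)
        lv[~mask] = 0
        out.append((lv, mask, n_bins))
    return out
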