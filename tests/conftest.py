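import warnings

import numpy as np
import pandas as pd
import pytest

from omicage import CohortConfig, simulate_annotations, simulate_cohort

warnings.filterwarnings("ignore", message="dropped .* zero-variance")
warnings.filterwarnings("ignore", message="multiblock sPLS-DA did not converge")


@pytest.fixture(scope="session")
def subset_cohort():
    """Multi-omic-subset-sized cohort (12/11/12/6) with planted effects."""
    cfg = CohortConfig.multiomic_subset(seed=11, effect_size=1.5)
    dataset, truth = simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def subset_annotation(subset_cohort):
    cfg, dataset, truth = subset_cohort
    return simulate_annotations(cfg, n_pathways=40, planted_enriched=3, truth=truth, dataset=dataset)


@pytest.fixture(scope="session")
def full_cohort():
    """Full-study-sized cohort (41/41/35/6), default effects."""
    cfg = CohortConfig(seed=5)
    dataset, truth = simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def two_group_blocks(rng):
    """Two 40-sample noise blocks with a planted 5-feature signal in each."""
    idx = [f"S{i:02d}" for i in range(40)]
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=idx)
    shift = (labels == "A").to_numpy(float)[:, None] * 2.0
    blocks = {}
    for name in ("x1", "x2"):
        Z = rng.normal(size=(40, 30))
        Z[:, :5] += shift
        blocks[name] = pd.DataFrame(Z, index=idx, columns=[f"{name}_f{j}" for j in range(30)])
    return blocks, labels
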