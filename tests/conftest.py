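import numpy as np
import pytest

from methmark import io as mio
from methmark import simulate as sim


@pytest.fixture(scope="session")
def regions():
    return mio.default_regions()


@pytest.fixture(scope="session")
def small_cohort():
    """Two cancer types, one strongly differential planted probe."""
    cfg = sim.ArraySimConfig(
        n_cancer_types=2,
        n_tumor=30,
        n_normal=30,
        n_wbc=40,
        n_probes=100,
        planted_markers=[
            sim.PlantedMarker(5, (8, 2), (2, 8), (2, 8)),
            sim.PlantedMarker(17, (12, 3), (2, 10), (2, 10)),
        ],
        seed=42,
    )
    return sim.gen_beta_cohorts(cfg)


@pytest.fixture(scope="session")
def plasma_readsets(regions):
    cfg = sim.ReadSimConfig(
        n_case=10, n_control=10, reads_per_sample=60, cpgs_per_region=10,
        tumor_read_fraction=0.3, p_hi=0.9, p_lo=0.05, seed=3,
    )
    return sim.gen_plasma_readsets(cfg, regions)


def pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney AUC with ties counted 1/2 (independent oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    case, ctrl = scores[labels], scores[~labels]
    wins = 0.0
    for c in case:
        for d in ctrl:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (case.size * ctrl.size)
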