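import numpy as np
import pytest

from partclus import ClusterSizeDistribution, TrialDataset


@pytest.fixture
def dist_unequal():
    """70% singletons, 15/10/5% clusters of sizes 2-4 (cluster-level)."""
    return ClusterSizeDistribution.from_delta([0.70, 0.15, 0.10, 0.05])


@pytest.fixture
def dist_equal():
    return ClusterSizeDistribution.from_delta([0.25, 0.25, 0.25, 0.25])


@pytest.fixture
def dist_neonatal():
    """Unit-level mix: 70% singleton infants, 25% twins, 5% triplets."""
    return ClusterSizeDistribution.from_gamma([0.70, 0.25, 0.05])


@pytest.fixture
def dist_rerand():
    """Re-randomisation example: cluster-level (0.50,0.20,0.20,0.05,0.05)."""
    return ClusterSizeDistribution.from_delta([0.50, 0.20, 0.20, 0.05, 0.05])


@pytest.fixture
def fixture_dataset():
    """Small printed dataset: 8 observations in 3 clusters, mixed arms."""
    return TrialDataset(
        cluster_id=np.array([1, 1, 1, 2, 2, 3, 3, 3]),
        member_id=np.array([1, 2, 3, 1, 2, 1, 2, 3]),
        arm=np.array([1, 1, 0, 0, 0, 1, 0, 1]),
        y=np.array([1.63, 0.92, -0.31, 0.28, -1.05, 0.47, 1.10, -0.22]),
        outcome="continuous",
    )


@pytest.fixture
def fixture_dataset_binary():
    return TrialDataset(
        cluster_id=np.array([1, 1, 1, 2, 2, 3, 3, 3, 4, 4]),
        member_id=np.array([1, 2, 3, 1, 2, 1, 2, 3, 1, 2]),
        arm=np.array([1, 1, 0, 0, 0, 1, 0, 1, 1, 0]),
        y=np.array([1, 0, 0, 1, 0, 1, 1, 0, 0, 1]),
        outcome="binary",
    )
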