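import numpy as np
import pytest

from somsite.config import RunConfig
from somsite.model import BindingSiteModel
from somsite.synthetic import PocketSpec, sample_poses

TWO_POCKETS = [
    PocketSpec((15.0, 0.0, 0.0), 1.5, 0.8, "major"),
    PocketSpec((-15.0, 0.0, 0.0), 1.5, 0.15, "minor"),
]


def two_pocket_model(seed: int) -> tuple[BindingSiteModel, object]:
    """50 ligands x 20 poses: 80% major pocket, 15% minor, 5% background."""
    pose_sets, truth = sample_poses(TWO_POCKETS, n_ligands=50, seed=seed)
    model = BindingSiteModel(pose_sets, reference_ligand=truth.reference_ligand,
                             config=RunConfig(n_randomizations=1000))
    return model, truth


@pytest.fixture(scope="session")
def two_pocket_fixture():
    return two_pocket_model(seed=1)


@pytest.fixture(scope="session")
def two_pocket_results(two_pocket_fixture):
    model, truth = two_pocket_fixture
    return model.fit(seed=1), truth


@pytest.fixture(scope="session")
def two_cluster_points():
    """Two tight Gaussian clouds of 500 points each at (+-20, 0, 0)."""
    rng = np.random.default_rng(7)
    a = rng.normal((-20.0, 0.0, 0.0), 1.0, size=(500, 3))
    b = rng.normal((20.0, 0.0, 0.0), 1.0, size=(500, 3))
    return np.concatenate([a, b]), np.array([0] * 500 + [1] * 500)
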