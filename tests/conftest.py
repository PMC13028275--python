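import numpy as np
import pytest

from fusecyte.dataio import AugmentConfig, load_manifest
from fusecyte.models import HybridModel
from fusecyte.syndata import generate_dataset


@pytest.fixture(scope="session")
def small_aug():
    """Desk-scale dual-view resolutions matching the tiny branches."""
    return AugmentConfig(size_t=64, size_c=96)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """60-image balanced synthetic dataset at 96 px."""
    out = tmp_path_factory.mktemp("tiny_data")
    generate_dataset({"astrocyte": 20, "cortical": 20, "shsy5y": 20},
                     image_size=96, seed=7, out_dir=out)
    return out


@pytest.fixture(scope="session")
def tiny_manifest(tiny_dataset_dir):
    return load_manifest(tiny_dataset_dir)


@pytest.fixture(scope="session")
def learn_dataset_dir(tmp_path_factory):
    """300-image balanced separable set at 128 px used for training checks."""
    out = tmp_path_factory.mktemp("learn_data")
    generate_dataset({"astrocyte": 100, "cortical": 100, "shsy5y": 100},
                     image_size=128, seed=11, out_dir=out)
    return out


@pytest.fixture(scope="session")
def learn_manifest(learn_dataset_dir):
    return load_manifest(learn_dataset_dir)


@pytest.fixture()
def tiny_model():
    return HybridModel.tiny(seed=5, projection_dim=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
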