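import numpy as np
import pytest

from mbranet.synthetic import SyntheticSpec, generate_synthetic_dataset
from mbranet.data import read_chestxray14_csv


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synthetic(tmp_path_factory):
    """A small 64x64 synthetic dataset shared across tests (120 images)."""
    out = tmp_path_factory.mktemp("synth")
    spec = SyntheticSpec(n_images=120, image_size=64, seed=42,
                         images_per_patient=2)
    csv_path = generate_synthetic_dataset(spec, out)
    records = read_chestxray14_csv(csv_path)
    return {"spec": spec, "csv": csv_path, "records": records, "dir": out}
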