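import numpy as np
import pandas as pd
import pytest

from nanozeta.datasets import apply_split
from nanozeta.models import design_frame
from nanozeta.synthetic import SynthConfig, generate_dataset, worked_micro_example


@pytest.fixture(scope="session")
def micro():
    """The fixed 12-record hand-checkable table."""
    return worked_micro_example()


@pytest.fixture(scope="session")
def study():
    """The default study-condition synthetic library (71 records, 53/18)."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def study_split(study):
    train, test = apply_split(study, mode="flags")
    X_tr, y_tr = design_frame(train)
    X_te, y_te = design_frame(test)
    return X_tr, y_tr, X_te, y_te


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def canonical_frame():
    """A tiny canonical feature frame for encoder/scaler tests."""
    return pd.DataFrame({
        "ID": ["a", "b", "c", "d"],
        "CF": ["CuO", "Au", "CeO2", "Ag"],
        "Dsph": [10.0, 20.0, 30.0, 40.0],
        "Shape": ["spherical", "rod", "spherical", "square_plate"],
        "CT": ["PVP", "citrate-XYZ", "uncoated", "sodium citrate"],
        "DLS": [100.0, 150.0, 200.0, 250.0],
        "MW": [79.545, 196.967, 172.114, 107.868],
        "A11": [10.0, 25.0, 14.0, 22.0],
        "A132": [2.5, 7.0, 3.9, 6.0],
        "Nmetal": [1.0, 1.0, 1.0, 1.0],
        "Noxygen": [1, 0, 2, 0],
        "Metals_SumIP": [745.5, 890.1, 534.4, 731.0],
        "ZP": [-20.0, -5.0, -25.0, -30.0],
        "Split": ["train", "train", "train", "test"],
    })
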