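import numpy as np
import pandas as pd
import pytest

from phosphopair import make_design
from phosphopair.tables_io import IntensityMatrix, PairedDesign


@pytest.fixture
def design10() -> PairedDesign:
    """The study layout: 5 IDC + 5 ILC patients, tumor+NAT each."""
    return make_design(5)


@pytest.fixture
def design2() -> PairedDesign:
    """Tiny 1 IDC + 1 ILC design for parser toys."""
    return make_design(1)


def random_matrix(rng: np.random.Generator, design: PairedDesign,
                  n_features: int = 20, missing_rate: float = 0.2) -> IntensityMatrix:
    values = 2.0 ** rng.normal(20, 2, (n_features, len(design.sample_ids)))
    mask = rng.random(values.shape) < missing_rate
    index = pd.Index([f"F{i}" for i in range(n_features)], name="feature_id")
    data = pd.DataFrame(values, index=index, columns=design.sample_ids).mask(
        pd.DataFrame(mask, index=index, columns=design.sample_ids))
    return IntensityMatrix(data, "linear")


def write_design_file(design: PairedDesign, path) -> str:
    design.entries.to_csv(path, sep="\t", index=False)
    return str(path)
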