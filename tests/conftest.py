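import numpy as np
import pandas as pd
import pytest

from morphoscreen import ProfileTable, ScreenDesign


def random_profile_table(
    rng: np.random.Generator,
    n_rows: int = 20,
    n_features: int = 5,
    nan_rate: float = 0.0,
) -> ProfileTable:
    """A randomized table with plate/well metadata and Gaussian features."""
    values = rng.standard_normal((n_rows, n_features))
    if nan_rate > 0:
        values[rng.random(values.shape) < nan_rate] = np.nan
    frame = pd.DataFrame(values, columns=[f"Feat_{i}" for i in range(n_features)])
    frame.insert(0, "Metadata_Plate", [f"p{i % 3}" for i in range(n_rows)])
    frame.insert(1, "Metadata_Well", [f"A{(i % 12) + 1:02d}" for i in range(n_rows)])
    return ProfileTable.from_dataframe(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_design() -> ScreenDesign:
    """A compact screen: 6 plates x 24 wells, 3 injury classes."""
    return ScreenDesign(
        n_plates=6,
        plate_rows=4,
        plate_cols=6,
        classes=("Cytoskeletal", "Hsp90", "Kinase"),
        treatments_per_class=12,
        n_informative=20,
        n_near_constant=3,
        n_duplicated=3,
        n_high_missing=3,
        effect_size=3.0,
        cells_per_well=10,
        seed=11,
    )
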