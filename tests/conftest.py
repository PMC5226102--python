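import numpy as np
import pandas as pd
import pytest

from domgen.band_data import BandMatrix
from domgen.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def toy_matrix() -> BandMatrix:
    """3 samples x 4 bands, two primers, no missing data."""
    values = np.array(
        [
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    return BandMatrix(
        samples=["s1", "s2", "s3"],
        band_ids=["b1", "b2", "b3", "b4"],
        primer_ids=["P1", "P1", "P2", "P2"],
        primer_types=["ISSR", "ISSR", "SCoT", "SCoT"],
        values=values,
    )


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "plant_id": ["PI1", "PI2", "PI3"],
            "name": ["a", "b", "c"],
            "ecotype": ["UL", "UL", "LL"],
            "origin": ["x", "y", "z"],
        }
    )


def small_sim_config(**overrides) -> SimConfig:
    """A fast two-subpopulation config used across tests."""
    base = dict(
        n_samples=80,
        group_sizes=(45, 35),
        n_primers={"ISSR": 8},
        bands_per_primer={"ISSR": 14.0},
        fst=0.3,
        admixture_alpha=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Deterministic two-subpopulation dataset with no admixture."""
    cfg = small_sim_config(seed=7)
    return simulate_dataset(cfg)
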