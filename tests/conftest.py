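import numpy as np
import pandas as pd
import pytest

from gpcrtracer import synthetic
from gpcrtracer.synthetic import SyntheticChemConfig


@pytest.fixture(scope="session")
def two_family_table() -> pd.DataFrame:
    cfg = SyntheticChemConfig(n_families=2, compounds_per_family=10, seed=1)
    return synthetic.generate_interaction_table(cfg)


@pytest.fixture(scope="session")
def four_family_table() -> pd.DataFrame:
    cfg = SyntheticChemConfig(n_families=4, compounds_per_family=50, seed=2)
    return synthetic.generate_interaction_table(cfg)


@pytest.fixture(scope="session")
def toy_raw_table() -> pd.DataFrame:
    """10 records: 3 non-human, 1 missing compound id -> 6 retained."""
    rows = [
        ("C1", "CCO", "FAM01_R1", "human", "FAM01"),
        ("C2", "c1ccccc1", "FAM01_R1", "human", "FAM01"),
        ("C3", "CCN", "FAM01_R2", "mouse", "FAM01"),
        ("C4", "CCC", "FAM02_R1", "human", "FAM02"),
        ("C5", "CCCl", "FAM02_R1", "rat", "FAM02"),
        (None, "CCBr", "FAM02_R2", "human", "FAM02"),
        ("C7", "CCI", "FAM02_R2", "human", "FAM02"),
        ("C8", "CCF", "FAM01_R3", "mouse", "FAM01"),
        ("C9", "CC(C)O", "FAM02_R3", "human", "FAM02"),
        ("C10", "CC(C)N", "FAM01_R4", "human", "FAM01"),
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "smiles", "receptor", "species", "family"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
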