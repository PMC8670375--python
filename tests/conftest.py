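import numpy as np
import pandas as pd
import pytest

import subproteo as sp


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-protein synthetic dataset shared by read-only tests."""
    cfg = sp.SimConfig(n_proteins=300, seed=11)
    table, maps, truth = sp.generate_quant_dataset(cfg)
    return cfg, table, maps, truth


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Qualification, presence and classed differential table for it."""
    cfg, table, maps, truth = small_dataset
    qs = sp.qualify_proteins(table, maps)
    presence = sp.call_presence(qs)
    classed = sp.differential_analysis(
        sp.log_transform(table), qs, presence, sp.TestConfig(seed=11)
    )
    return qs, presence, classed


def toy_quant_table(rows):
    """Build a validated-shape long table from (protein, strain, condition,
    fraction, replicate, intensity, unique_peptides) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "strain",
            "condition",
            "fraction",
            "replicate",
            "intensity",
            "unique_peptides",
        ],
    )
    df.attrs["is_log2"] = False
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(42)
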