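import numpy as np
import pandas as pd
import pytest

from betamarkers.io import ExpressionMatrix, OrthologMap, sample_table
from betamarkers.simulate import SimConfig, simulate_atlas


def make_matrix(values: dict[str, list[float]], probes: list[str],
                species: str = "rat", genes: list[str] | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {sample_name: column} mappings."""
    df = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"))
    symbols = pd.Series(genes, index=df.index) if genes else None
    return ExpressionMatrix(values=df, samples=sample_table(df.columns),
                            species=species, gene_symbols=symbols)


@pytest.fixture(scope="session")
def default_atlas():
    """One default synthetic atlas shared by read-only tests."""
    return simulate_atlas(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def noiseless_atlas():
    return simulate_atlas(SimConfig(noise_sd=0.0, probe_offset_sd=0.0), seed=11)
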