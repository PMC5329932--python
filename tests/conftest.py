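import numpy as np
import pandas as pd
import pytest

from coldacc.containers import CountMatrix, SampleDesign, SimulationConfig


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Four genes x four samples with easy round numbers."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 500, 100],
            "s2": [20, 5, 400, 80],
            "s3": [12, 1, 450, 90],
            "s4": [18, 4, 480, 95],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    lengths = pd.Series([2000, 1000, 1500, 500], index=counts.index, name="length")
    return CountMatrix(counts=counts, lengths=lengths)


@pytest.fixture
def tiny_design() -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {"group": ["T2", "T2", "T18", "T18"], "temperature_C": [2.0, 2.0, 18.0, 18.0]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
        )
    )


@pytest.fixture
def two_group_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=1000,
        n_samples_per_group=3,
        groups={"T2": 2.0, "T18": 18.0},
        seed=42,
    )
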