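import numpy as np
import pandas as pd
import pytest

from sialoquant.readmap import LIBRARIES, CdsRecord, CountMatrix
from sialoquant.synthio import SyntheticConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def small_config():
    """Desk-scale generator settings for fast unit tests."""
    return SyntheticConfig(
        n_cds=40,
        cds_length_range=(150, 300),
        library_depths={"FSG": 3000, "MSG": 1000, "FWB": 800, "MWB": 800},
        per_base_error_rate=0.0,
        low_quality_tail_prob=0.0,
        rng_seed=4242,
    )


@pytest.fixture
def toy_counts():
    """Hand-sized count matrix with one dominant CDS in FSG."""
    counts = pd.DataFrame(
        {
            "FSG": [500, 100, 20, 0],
            "MSG": [50, 90, 20, 0],
            "FWB": [5, 80, 20, 2],
            "MWB": [5, 85, 20, 3],
        },
        index=["CDS1", "CDS2", "CDS3", "CDS4"],
    )
    counts.index.name = "cds_id"
    return CountMatrix(counts)


@pytest.fixture
def toy_lengths():
    return pd.Series([1000, 500, 2000, 800], index=["CDS1", "CDS2", "CDS3", "CDS4"])
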