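import numpy as np
import pandas as pd
import pytest

from rhizoprot.io_formats import AbundanceMatrix


def make_matrix(values, proteins=None, samples=None, species="sp"):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"p{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return AbundanceMatrix(
        data=pd.DataFrame(values, index=proteins, columns=samples), species=species)


def make_meta(samples, seasons, species="sp", year=2022, batches=None):
    batches = batches or ["b1"] * len(samples)
    return pd.DataFrame({
        "sample_id": samples, "species": [species] * len(samples),
        "season": seasons, "year": [year] * len(samples), "batch": batches,
    })


@pytest.fixture
def four_v_four():
    """8-sample single-species layout: 4 winter then 4 summer."""
    samples = [f"w{i}" for i in range(1, 5)] + [f"s{i}" for i in range(1, 5)]
    seasons = ["winter"] * 4 + ["summer"] * 4
    return samples, make_meta(samples, seasons)
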