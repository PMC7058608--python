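import numpy as np
import pandas as pd
import pytest

from braakmap.atlas_io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_donor(rng, n_genes=30, samples_per_region=3, donor="donor1"):
    """Small single-donor dataset with labels 1-6 and pure-noise expression."""
    labels = np.repeat(np.arange(1, 7), samples_per_region)
    n = labels.size
    sample_ids = [f"{donor}_s{i:02d}" for i in range(n)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    data = pd.DataFrame(
        rng.normal(7, 1, (n_genes, n)), index=genes, columns=sample_ids
    )
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "donor_id": donor,
        "structure_name": [f"structure_{r}a" for r in labels],
        "braak_region": pd.array(labels, dtype="Int64"),
    })
    return ExpressionMatrix(data), samples


@pytest.fixture
def toy_donor(rng):
    return make_donor(rng)
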