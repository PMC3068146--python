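import numpy as np
import pytest

from tissuesig import SyntheticConfig, generate_paired
from tissuesig.datasets import ExpressionDataset


@pytest.fixture(scope="session")
def small_paired():
    """Paired datasets with a clear normal-only signal (30 patients, 60 genes)."""
    cfg = SyntheticConfig(
        n_patients=30,
        n_genes=60,
        n_informative=5,
        effect_size=2.0,
        signal_tissue="normal",
        seed=11,
        endpoints=("gleason",),
    )
    return generate_paired(cfg)


@pytest.fixture(scope="session")
def null_paired():
    """Paired datasets with no planted signal anywhere."""
    cfg = SyntheticConfig(
        n_patients=30,
        n_genes=40,
        n_informative=0,
        seed=23,
        endpoints=("gleason",),
    )
    return generate_paired(cfg)


def make_dataset(x, y, tissue="normal", endpoint="gleason", patients=None):
    """Wrap a plain (samples x genes) array and labels into a dataset."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    patients = patients or [f"P{i:03d}" for i in range(n)]
    return ExpressionDataset(
        matrix=x,
        gene_ids=[f"G{i:03d}" for i in range(p)],
        sample_ids=[f"{pid}_{tissue[0]}" for pid in patients],
        tissue=tissue,
        labels={endpoint: np.asarray(y, dtype=int)},
        patient_id=list(patients),
    )
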