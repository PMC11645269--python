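import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dissocsig import CellAnnotations, CountMatrix, SimConfig, log_normalize, simulate_dataset


def make_counts(dense, genes=None, barcodes=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(genes, barcodes, sp.csr_matrix(dense))


def make_annotations(barcodes, sample_ids, groups, cell_class=None, **covariates):
    df = pd.DataFrame({"barcode": barcodes, "sample_id": sample_ids, "group": groups})
    if cell_class is not None:
        df["cell_class"] = cell_class
    for name, values in covariates.items():
        df[name] = values
    return CellAnnotations(df)


@pytest.fixture(scope="session")
def null_sim():
    """One group, four replicates, no activation program spiked."""
    cfg = SimConfig(
        seed=11, n_genes=600, groups=("CTRL",), samples_per_group=4,
        cells_per_sample=400, activated_fraction={},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def spiked_sim():
    """Two groups; 30% of one group's myeloid cells carry the program."""
    cfg = SimConfig(
        seed=12, n_genes=800, groups=("CTRL", "DISS"), samples_per_group=3,
        cells_per_sample=500, activated_fraction={("DISS", "myeloid"): 0.3},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_norm(null_sim):
    m, ann, _ = null_sim
    return log_normalize(m), ann


@pytest.fixture(scope="session")
def spiked_norm(spiked_sim):
    m, ann, _ = spiked_sim
    return log_normalize(m), ann
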