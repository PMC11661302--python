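import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from intraseq import CountMatrix, MoleculeTable, PanelManifest, default_config, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 400-cell dataset under the default study conditions (session-cached)."""
    return generate_dataset(default_config(n_cells=400, n_genes=80, seed=11))


@pytest.fixture
def tiny_matrix():
    counts = np.array(
        [[4, 0, 1],
         [0, 3, 0],
         [2, 2, 2]]
    )
    return CountMatrix(cells=["c1", "c2", "c3"], features=["g1", "g2", "g3"],
                       counts=sp.csr_matrix(counts), modality="RNA")


@pytest.fixture
def small_molecules():
    rows = [
        ("c1", "g1", "u0", 3),
        ("c1", "g1", "u1", 1),
        ("c1", "g2", "u0", 2),
        ("c2", "g1", "u0", 5),
        ("c2", "g2", "u0", 1),
    ]
    return MoleculeTable(records=pd.DataFrame(rows, columns=list(MoleculeTable.COLUMNS)))


@pytest.fixture
def tiny_panel():
    rows = [
        ("abA", "GeneA", "surface", None),
        ("abB", "GeneB", "intracellular", None),
        ("p-abB", "GeneB", "PTM", "abB"),
    ]
    return PanelManifest(entries=pd.DataFrame(rows, columns=list(PanelManifest.COLUMNS)))
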