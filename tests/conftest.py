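import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from fateseg import AtlasConfig, generate_atlas
from fateseg.io import DEFAULT_STAGES


def make_adata(values, genes, cells=None, obs=None) -> AnnData:
    """Dense toy matrix -> AnnData with optional obs columns."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    if cells is None:
        cells = [f"c{i}" for i in range(n_cells)]
    adata = AnnData(
        X=sp.csr_matrix(values),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene_id")),
    )
    if obs:
        for k, v in obs.items():
            adata.obs[k] = v
    if "stage" in adata.obs:
        adata.obs["stage"] = pd.Categorical(
            adata.obs["stage"], categories=list(DEFAULT_STAGES), ordered=True
        )
    return adata


@pytest.fixture(scope="session")
def atlas():
    """One mid-sized synthetic atlas shared across tests."""
    return generate_atlas(AtlasConfig(n_cells_per_stage=1000, seed=11))


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(AtlasConfig(n_cells_per_stage=300, seed=7))
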