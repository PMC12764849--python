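import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from archetrack import ExpressionMatrix, SimConfig, generate_cohort


@pytest.fixture
def toy_counts():
    """3 cells x 4 genes with 5 nonzeros."""
    dense = np.array(
        [
            [5, 0, 2, 0],
            [0, 3, 0, 0],
            [1, 0, 0, 4],
        ]
    )
    return ExpressionMatrix(
        sp.csr_matrix(dense), ["gA", "gB", "gC", "gD"], ["c1", "c2", "c3"]
    )


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "patient": ["P1"] * 3,
            "cycle": [1, 2, 3],
            "biopsy_site": ["site_A"] * 3,
            "cell_type": ["epithelial"] * 3,
            "ploidy": ["aneuploid", "diploid", "not.defined"],
            "n_features": [500, 400, 600],
            "pct_mt": [1.0, 2.0, 3.0],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort (session-scoped; treat as read-only)."""
    cfg = SimConfig(cells_per_cycle=120, n_genes=800, seed=7)
    return cfg, generate_cohort(cfg)
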