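import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from paretocell import ExpressionAtlas, generate_atlas, random_archetype_spec


@pytest.fixture
def tiny_atlas() -> ExpressionAtlas:
    """Hand-sized atlas: 10 cells x 6 genes with known structure.

    Gene layout: g0-g2 protein-coding, g3 mitochondrial, g4 artifact,
    g5 non-coding. Cell 9 is all-zero.
    """
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(10, 6))
    counts[9] = 0
    counts[0, 1] = 0  # gene support varies
    cell_meta = pd.DataFrame(
        {
            "donor": ["D1"] * 5 + ["D2"] * 5,
            "tissue": ["T1"] * 10,
            "cell_type": ["alpha"] * 10,
        },
        index=pd.Index([f"c{i}" for i in range(10)], name="cell_id"),
    )
    gene_meta = pd.DataFrame(
        {
            "is_protein_coding": [True, True, True, True, True, False],
            "is_mitochondrial": [False] * 3 + [True, False, False],
            "is_artifact": [False] * 4 + [True, False],
        },
        index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
    )
    return ExpressionAtlas(sp.csr_matrix(counts), cell_meta, gene_meta)


@pytest.fixture(scope="session")
def small_synthetic_atlas():
    """3 donors x 2 tissues x 2 cell types (one polytopal, one null)."""
    spec = random_archetype_spec(3, 120, markers_per_archetype=5, seed=5)
    atlas, truth = generate_atlas(
        n_donors=3,
        n_tissues=2,
        cell_types={"poly": spec, "null": None},
        cells_per_stratum=(60, 90),
        seed=7,
    )
    return atlas, truth
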