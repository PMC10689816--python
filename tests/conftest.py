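import numpy as np
import pandas as pd
import pytest

from cellprs import SimulationConfig, simulate_study
from cellprs.specificity import ExpressionMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        seed=42,
        n_genes=400,
        n_specific_per_type=20,
        n_individuals=300,
        n_variants=800,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture()
def toy_expression() -> ExpressionMatrix:
    """4 genes x 6 cells over two types with hand-checkable counts."""
    counts = np.array([
        #  g0  g1  g2  g3
        [4, 0, 1, 0],
        [2, 0, 1, 0],
        [0, 0, 1, 0],   # type A cells
        [0, 3, 1, 0],
        [0, 1, 1, 0],
        [0, 2, 1, 0],   # type B cells
    ])
    return ExpressionMatrix(
        counts=counts,
        gene_ids=np.array(["g0", "g1", "g2", "g3"], dtype=object),
        cell_types=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
    )


@pytest.fixture()
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["g0", "g1", "g2", "g3"],
        "chrom": ["chr1", "chr1", "chr2", "chr19"],
        "start": [100, 400, 100, 44_000_000],
        "end": [200, 500, 300, 44_001_000],
    }))
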