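import numpy as np
import pandas as pd
import pytest

from hubdrug.expression import ExpressionMatrix
from hubdrug.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A fast synthetic study: 300 genes, 12+12 samples, 30 DE genes."""
    return SimulationConfig(
        n_genes=300,
        n_platforms=2,
        panel_overlap=0.7,
        n_primary=12,
        n_metastatic=12,
        n_de=30,
        hub_community_size=10,
        n_drugs=8,
        planted_drug_targets=2,
        seed=7,
    )


@pytest.fixture
def two_group_matrix():
    """Deterministic 6-gene, 4+4-sample matrix with one strong DE gene."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(6)]
    primary = [f"P{i}" for i in range(4)]
    metastatic = [f"M{i}" for i in range(4)]
    values = pd.DataFrame(
        rng.normal(7.0, 0.3, (6, 8)), index=genes, columns=primary + metastatic
    )
    values.loc["g0", metastatic] += 3.0
    matrix = ExpressionMatrix(values=values, platform="PLT1")
    annotation = pd.DataFrame(
        {
            "sample": primary + metastatic,
            "group": ["primary"] * 4 + ["metastatic"] * 4,
            "platform": "PLT1",
        }
    )
    return matrix, annotation
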