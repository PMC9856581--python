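import numpy as np
import pandas as pd
import pytest

import immunoaging as ia


@pytest.fixture(scope="session")
def small_config() -> ia.SimulationConfig:
    """Desk-scale study conditions used by most unit tests."""
    return ia.SimulationConfig(
        n_genes=300, n_cancers=2, n_tumor=30, n_normal=30,
        n_driver_genes=10, n_tumor_dysregulated=40, n_age_dysregulated=40,
        network_nodes=300, network_attach=2, n_pathways=5, pathway_size=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ia.SyntheticCohort:
    return ia.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_network(small_config, small_cohort) -> ia.PPINetwork:
    g = ia.generate_network(small_config.network_nodes, small_config.network_attach,
                            drivers=small_cohort.truth["drivers"], seed=7)
    return ia.PPINetwork.from_graph(g)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    """4-gene single-sample matrix behind the hand-computed ssGSEA value."""
    return pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]},
                        index=["g1", "g2", "g3", "g4"])
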