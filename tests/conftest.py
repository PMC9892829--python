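import numpy as np
import pandas as pd
import pytest

from gscproteo.io import ExpressionMatrix, GeneSetCollection, SampleAnnotation
from gscproteo.simulate import (
    SimulationConfig,
    generate_discovery_panel,
    generate_toy_transcriptome,
    generate_validation_panel,
)


@pytest.fixture(scope="session")
def toy_transcriptome():
    return generate_toy_transcriptome(seed=7)


@pytest.fixture(scope="session")
def small_config():
    # scaled-down panel for fast unit checks of the machinery
    return SimulationConfig(
        n_proteins=800, n_gpc_planted=40, n_gm_planted=60, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_discovery_panel(small_config)


@pytest.fixture(scope="session")
def small_validation(small_config, small_panel):
    _, _, truth = small_panel
    return generate_validation_panel(
        small_config, truth, flip_fraction_gpc=0.25, flip_fraction_gm=0.25
    )


@pytest.fixture
def tiny_matrix():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0, 1.1, 2.1, 3.1], [0.5, np.nan, 1.5, 0.4, 1.2, 1.6]],
        index=["PA", "PB"],
        columns=["L1_R1", "L1_R2", "L1_R3", "L2_R1", "L2_R2", "L2_R3"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def tiny_annotations():
    return [
        SampleAnnotation(f"L{li}_R{r}", f"L{li}", r, "gsc" if li == 1 else "control")
        for li in (1, 2)
        for r in (1, 2, 3)
    ]


@pytest.fixture
def two_sets():
    return GeneSetCollection(
        sets={"S1": ["A", "B", "C"], "S2": ["D", "E"]},
        descriptions={"S1": "first", "S2": "second"},
    )
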