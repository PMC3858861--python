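import numpy as np
import pytest

from panelselect import (
    ClassifierSpec,
    LabeledExpressionMatrix,
    SimulationConfig,
    generate_dataset,
    split_groups,
)


@pytest.fixture
def toy_matrix() -> LabeledExpressionMatrix:
    """4 probes x 6 samples, 3 cases / 3 controls, log2 scale."""
    values = np.array(
        [
            [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [1.0, 4.0, 2.0, 8.0, 3.0, 9.0],
            [0.5, 1.5, 2.5, 3.5, 4.5, 5.5],
        ]
    )
    return LabeledExpressionMatrix(
        ["P1", "P2", "P3", "P4"],
        ["S1", "S2", "S3", "S4", "S5", "S6"],
        values,
        np.array([1, 1, 1, 0, 0, 0]),
        scale="log2",
    )


@pytest.fixture(scope="session")
def planted_small():
    """Compact planted dataset: 200 probes, 130 samples, strong 5-probe panel."""
    cfg = SimulationConfig(n_probes=200, effect_size=2.0, seed=42)
    m, truth = generate_dataset(cfg)
    return m, truth


@pytest.fixture(scope="session")
def planted_split(planted_small):
    m, _ = planted_small
    return split_groups(m, seed=42, fraction_a=0.5, stratified=True, k=5)


@pytest.fixture
def default_spec() -> ClassifierSpec:
    return ClassifierSpec()
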