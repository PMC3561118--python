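import numpy as np
import pandas as pd
import pytest

from hypoxdep import ExpressionMatrix, SimulationConfig
from hypoxdep.simulate import generate_expression


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Small factorial design with all three single-factor classes planted."""
    return SimulationConfig(
        n_probes=600,
        noise_sd=0.25,
        seed=11,
        class_fractions={"HD": 0.05, "HI": 0.05, "ED": 0.05},
        effect_log2=(1.5, 3.0),
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate_expression(planted_config)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3-vs-3 control design, 12 probes, deterministic values."""
    rng = np.random.default_rng(5)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "genotype": ["control"] * 6,
            "oxygen": ["normoxia"] * 3 + ["hypoxia"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )
    values = pd.DataFrame(
        rng.normal(7, 1, size=(12, 6)),
        index=pd.Index([f"p{i}" for i in range(12)], name="probe_id"),
        columns=samples["sample_id"],
    )
    values.iloc[0, 3:] += 3.0  # one strongly induced probe
    return ExpressionMatrix(values=values, samples=samples)
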