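import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_cohort():
    """One harmonized synthetic cohort shared across read-only tests."""
    from casurv import SyntheticConfig, gen_cohort_inputs, harmonize_studies

    cfg = SyntheticConfig(seed=11)
    matrices, annotations, truth = gen_cohort_inputs(cfg)
    cohort = harmonize_studies(matrices, annotations)
    return cfg, cohort, truth


@pytest.fixture()
def tiny_probe_matrix():
    from casurv import ProbeMatrix

    values = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 7.0, 1.0, 3.0],
            "s2": [2.0, 5.0, 8.0, 3.0, 1.0],
        },
        index=["G1_a", "G1_b", "G2_a", "G3_a", "G3_b"],
    )
    values["s3"] = [3.0, 6.0, 9.0, 2.0, 2.0]
    pmap = pd.Series(
        ["G1", "G1", "G2", "G3", "G3"],
        index=["G1_a", "G1_b", "G2_a", "G3_a", "G3_b"],
    )
    return ProbeMatrix(dataset_id="d1", values=values, probe_gene_map=pmap)
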