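import numpy as np
import pandas as pd
import pytest

from togcn.data import (
    ExpressionMatrix,
    PipelineConfig,
    SampleDesign,
    stage_mean_matrix,
    tpm_from_counts,
)
from togcn.simulate import CascadeParams, simulate_cascade


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down cascade used by most integration-level tests."""
    return CascadeParams(
        structural_per_level=10, n_noise_genes=400, rng_seed=1
    )


@pytest.fixture(scope="session")
def small_cascade(small_params):
    return simulate_cascade(small_params)


@pytest.fixture(scope="session")
def small_stage_means(small_cascade):
    counts, design, catalog, sites, truth = small_cascade
    lengths = (catalog.table["end0"] - catalog.table["start0"]).astype(float)
    tpm = tpm_from_counts(counts, lengths)
    return stage_mean_matrix(tpm, design, "fruit")


@pytest.fixture()
def toy_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["f1_r1", "f1_r2", "f2_r1", "f2_r2", "f3_r1"],
                "tissue": "fruit",
                "stage_index": [1, 1, 2, 2, 3],
                "replicate": [1, 2, 1, 2, 1],
            }
        )
    )


@pytest.fixture()
def toy_expr():
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "f1_r1": [2.0, 1.0],
                "f1_r2": [4.0, 3.0],
                "f2_r1": [6.0, 5.0],
                "f2_r2": [8.0, 7.0],
                "f3_r1": [10.0, 9.0],
            },
            index=["gA", "gB"],
        )
    )
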