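import numpy as np
import pandas as pd
import pytest

from stresstrata.io import ExpressionMatrix
from stresstrata.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort with its latent truth."""
    matrix, meta, truth = generate_cohort(CohortSpec(rng_seed=11))
    return matrix, meta, truth


@pytest.fixture()
def small_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return ExpressionMatrix(df)


def random_expression(rng: np.random.Generator, n_genes: int, n_samples: int) -> ExpressionMatrix:
    vals = rng.gamma(2.0, 10.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )
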