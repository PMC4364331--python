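import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import growthsig as gs

settings.register_profile(
    "reproducible",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def phenotype_cohort():
    """Default planted phenotype cohort (48 steers, target r = 0.7)."""
    config = gs.SimulationConfig(seed=11)
    matrix, samples, truth = gs.generate_phenotype_cohort(config)
    return config, matrix, samples, truth


@pytest.fixture(scope="session")
def development_cohort():
    """Default planted development cohort (10 stages x 2 genotypes x 4)."""
    config = gs.SimulationConfig(seed=11)
    matrix, samples, truth = gs.generate_development_cohort(config)
    return config, matrix, samples, truth


@pytest.fixture()
def tiny_matrix():
    frame = pd.DataFrame(
        [[1.0, 2.5], [3.25, -4.0]],
        index=pd.Index(["geneA", "geneB"], name="gene"),
        columns=["s1", "s2"],
    )
    return gs.ExpressionMatrix(frame)


def random_expression(n_genes: int, n_samples: int, seed: int) -> gs.ExpressionMatrix:
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene"),
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return gs.ExpressionMatrix(frame)
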