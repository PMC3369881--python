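import numpy as np
import pandas as pd
import pytest

from oscillome import GenomeFixtureConfig, OscillomeSpec, generate_genome_fixture, generate_oscillome


@pytest.fixture(scope="session")
def small_oscillome():
    """Two small simulated experiments plus planted truth (shared across tests)."""
    spec = OscillomeSpec(n_genes=300, seed=11)
    exp1, exp2, truth = generate_oscillome(spec)
    return spec, exp1, exp2, truth


@pytest.fixture(scope="session")
def labels_7():
    """A deterministic 7-cohort + background labeling over 600 genes."""
    rng = np.random.default_rng(5)
    genes = [f"g{i:05d}" for i in range(600)]
    cohorts = ["A", "AB", "B", "B.C", "C", "B.D", "D"]
    labs = rng.choice(cohorts + ["bg"], size=600, p=[0.1] * 7 + [0.3])
    return pd.Series(labs, index=pd.Index(genes, name="gene"))


@pytest.fixture(scope="session")
def genome_fixture(labels_7):
    return generate_genome_fixture(labels_7, GenomeFixtureConfig(seed=7))
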