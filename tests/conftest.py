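import numpy as np
import pytest

from pwmconsensus import (
    DNA,
    MotifGeneratorConfig,
    random_motifs,
    worked_example_motifs,
)

P73_COLUMN = np.array([0.077, 0.0, 0.726, 0.197])  # A, C, G, T
NEAR_UNIFORM_COLUMN = np.array([0.26, 0.25, 0.25, 0.24])


@pytest.fixture(scope="session")
def fixtures():
    p73, near_uniform, gata2 = worked_example_motifs()
    return {"p73": p73, "near_uniform": near_uniform, "gata2": gata2}


@pytest.fixture(scope="session")
def random_dna_motifs():
    return random_motifs(
        MotifGeneratorConfig(alphabet=DNA, width=8, concentration=0.5, count=20, seed=42)
    )


def random_columns(n_chars: int, count: int, seed: int, concentration: float = 0.5):
    rng = np.random.default_rng(seed)
    return rng.dirichlet([concentration] * n_chars, size=count)
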