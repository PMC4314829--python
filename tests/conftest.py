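import numpy as np
import pytest

from dhqforge import (
    AssayConfig,
    build_weights,
    load_usage_tables,
    synthetic_seeds,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def usage_tables():
    """The packaged synthetic two-host usage tables."""
    return load_usage_tables()


@pytest.fixture(scope="session")
def weights(usage_tables):
    return build_weights(list(usage_tables), floor=0.10)


@pytest.fixture(scope="session")
def seeds():
    return synthetic_seeds()


@pytest.fixture()
def assay_config():
    return AssayConfig(enzyme_conc=0.05, protein_mass=0.001)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))
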