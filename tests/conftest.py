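import numpy as np
import pytest

from seasonscan import OtuTable, SyntheticConfig, generate_community


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 taxa x 2 samples with taxonomy strings."""
    return OtuTable(
        counts=np.array([[5, 0], [3, 2], [0, 7]]),
        taxon_ids=["t1", "t2", "t3"],
        sample_ids=["s1", "s2"],
        taxonomy=["Bacteria;A", "Bacteria;B", ""],
    )


@pytest.fixture(scope="session")
def default_survey():
    """One synthetic survey drawn under the default study design."""
    return generate_community(SyntheticConfig(), seed=20130107)


def random_table(rng: np.random.Generator, n_taxa: int = 10, n_samples: int = 8,
                 lam: float = 5.0) -> OtuTable:
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    return OtuTable(
        counts=counts,
        taxon_ids=[f"t{i}" for i in range(n_taxa)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )
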