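import numpy as np
import pytest

from ncdlink import AssociationDataset, generate_synthetic


@pytest.fixture
def tiny_ds() -> AssociationDataset:
    """4 ncRNAs x 3 drugs, hand-built."""
    return AssociationDataset(
        ncrnas=["miR-a", "miR-b", "miR-c", "miR-d"],
        drugs=["cisplatin", "paclitaxel", "sorafenib"],
        pairs={(0, 0), (0, 1), (1, 0), (2, 2), (3, 1), (3, 2)},
    )


@pytest.fixture(scope="session")
def block_sim():
    """The planted 2-block benchmark dataset (shared across tests)."""
    return generate_synthetic(m=100, n=30, k_blocks=2,
                              density_in=0.5, density_out=0.02, seed=7)


def random_dataset(m: int, n: int, density: float, seed: int) -> AssociationDataset:
    """Erdos-Renyi bipartite dataset for oracle tests."""
    rng = np.random.default_rng(seed)
    pairs = {(i, j) for i in range(m) for j in range(n)
             if rng.random() < density}
    return AssociationDataset(
        ncrnas=[f"u{i}" for i in range(m)],
        drugs=[f"v{j}" for j in range(n)],
        pairs=pairs,
    )
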