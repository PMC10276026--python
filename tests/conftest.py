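import numpy as np
import pytest

from gblupad import (
    SimulationConfig,
    additive_kernel,
    allele_frequency,
    dominance_kernel,
    identity_kernel,
    qc_filter,
    simulate_dataset,
)


def spawn_seeds(root: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 from one root."""
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@pytest.fixture(scope="session")
def small_dataset():
    """A small additive+dominance dataset with missing genotype calls."""
    config = SimulationConfig(
        n_individuals=40,
        n_markers=120,
        missing_rate=0.03,
        sigma2_a=0.4,
        sigma2_d=0.2,
        sigma2_e=0.4,
        seed=1,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    """(G, D, I) built from the QC'd small panel."""
    post, _ = qc_filter(small_dataset.genotypes)
    freqs = allele_frequency(post)
    return (
        additive_kernel(post, freqs),
        dominance_kernel(post, freqs),
        identity_kernel(post.individual_ids),
    )
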