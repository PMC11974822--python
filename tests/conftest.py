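import numpy as np
import pytest

from pausekinetics.kinetics import RateSet
from pausekinetics.simulate import generate_condition_pair, sample_gene_rates

FIG_RATES = RateSet(k_init=0.5, k_pre=1.7, k_rel=0.25, k_elong=2000.0)


@pytest.fixture(scope="session")
def fig_rates() -> RateSet:
    """Representative per-gene rate set (initiation 0.5 RNAP/min, termination
    1.7/min, release 0.25/min, elongation 2 kb/min)."""
    return FIG_RATES


@pytest.fixture(scope="session")
def small_dataset():
    """Two-condition simulated dataset: 250 genes, 40 with k_rel doubled,
    uneven library sizes, two replicates."""
    genes = sample_gene_rates(250, seed=7)
    perturbed = [g.gene_id for g in genes[:40]]
    dataset = generate_condition_pair(
        genes,
        {gid: (1.0, 2.0) for gid in perturbed},
        depth=2e5,
        seed=8,
        library_multipliers={
            ("control", "rep1"): 1.0,
            ("control", "rep2"): 1.5,
            ("treatment", "rep1"): 0.7,
            ("treatment", "rep2"): 1.2,
        },
    )
    return dataset, perturbed


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
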