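import numpy as np
import pandas as pd
import pytest

from clonalpop import GenotypeMatrix, SampleMeta


def make_matrix(dosages, chrom=None, pos=None, samples=None, **meta_kwargs):
    """Build a GenotypeMatrix from a plain dosage array with default sites."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = list(range(1, m + 1))
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ["A"] * m, "alt": ["T"] * m}
    )
    if samples is None:
        samples = [SampleMeta(f"s{i}", **meta_kwargs) for i in range(n)]
    return GenotypeMatrix(dosages, sites, samples)


@pytest.fixture(scope="session")
def default_collection():
    """One simulated collection under the default survey conditions."""
    from clonalpop import SimulationConfig, simulate_collection

    config = SimulationConfig(n_sites=3000, seed=11)
    G, truth = simulate_collection(config)
    return config, G, truth
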