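import numpy as np
import pandas as pd
import pytest

from divescan.containers import GenotypeMatrix


def make_gm(calls, populations, positions=None, chrom="chr1"):
    """Build a small GenotypeMatrix from a (samples x variants) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 1000
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n_samples)],
            "population": list(populations),
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_variants,
            "pos": positions,
            "id": [f"v{j}" for j in range(n_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(calls=calls, samples=samples, variants=variants)


@pytest.fixture(scope="session")
def null_panel():
    """Three-population drift panel with no selection (shared across tests)."""
    from divescan.simulate import SimulationParams, simulate_panel

    params = SimulationParams(n_snps=4000, seed=11)
    return simulate_panel(params)


@pytest.fixture(scope="session")
def null_gm(null_panel):
    from divescan.simulate import sample_genotypes

    return sample_genotypes(null_panel, seed=12)


@pytest.fixture(scope="session")
def null_scan(null_gm):
    from divescan.scan import scan_genome

    return scan_genome(null_gm, focal="JEJ", outgroup="CHS")
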