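import numpy as np
import pandas as pd
import pytest

from appendhom import AnalysisConfig, SimConfig, simulate_dataset
from appendhom.io import CountMatrix


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One small three-taxon dataset with truth labels, shared across tests."""
    sim_cfg = SimConfig(n_genes=600, rng_seed=42)
    datasets, truth = simulate_dataset(sim_cfg)
    return sim_cfg, datasets, truth


def two_group_dataset(seed, G=2000, n_per=3, phi=0.1, log2fc=0.0, mu_range=(3, 9)):
    """Minimal test-vs-somatic dataset: one appendage tissue vs one somatic organ."""
    rng = np.random.default_rng(seed)
    mu0 = 2.0 ** rng.uniform(*mu_range, G)
    fc = 2.0 ** np.full(G, log2fc)
    mu = np.column_stack([np.tile(mu0 * fc, (n_per, 1)).T, np.tile(mu0, (n_per, 1)).T])
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu), size=mu.shape)
    cm = CountMatrix(
        [f"g{i:05d}" for i in range(G)], [f"s{j}" for j in range(2 * n_per)], counts
    )
    meta = pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "taxon": "t",
            "tissue": ["appendage_tissue"] * n_per + ["muscle"] * n_per,
            "role": ["appendage"] * n_per + ["somatic"] * n_per,
            "age": "adult",
            "sex": ["m", "f", "m"][:n_per] * 2,
            "species": "x",
            "replicate": list(range(1, n_per + 1)) * 2,
        }
    )
    nf = pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "tmm_factor": 1.0,
            "effective_libsize": np.full(2 * n_per, float(counts.sum(0).mean())),
        }
    )
    return cm, meta, nf
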