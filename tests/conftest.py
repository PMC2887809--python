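import numpy as np
import pandas as pd
import pytest

from asearray import SimConfig


def clean_config(**overrides) -> SimConfig:
    """A noise-free, background-free configuration for closed-form checks."""
    base = dict(
        n_snps=8, n_beads_per_snp=5, mixture_proportions=(0.36, 0.5, 0.64),
        n_replicates=1, noise_sd=0.0, outlier_rate=0.0,
        background_mean=0.0, background_sd=0.0, background_est_sd=0.0,
        nonspecific_scale=0.0, nonspecific_log2_sd=0.0,
        probe_affinity_log2_sd=0.0, snp_scale_log2_sd=0.0, nn_rate=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def ab_pair():
    """Genotype table: every SNP is (AA, BB) — maximal built-in imbalance."""
    idx = pd.Index([f"snp{i:05d}" for i in range(8)], name="snp_id")
    return pd.DataFrame({"ind1": ["AA"] * 8, "ind2": ["BB"] * 8}, index=idx)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
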