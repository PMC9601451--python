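import numpy as np
import pandas as pd
import pytest

from rnamsnp.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    """A quick bundle: 300 SNPs in 30 blocks, 800 individuals."""
    return SimulationConfig(
        n_individuals=800,
        n_blocks=30,
        snps_per_block=10,
        n_causal=10,
        heritability_x=0.5,
        rho=0.6,
        seed=20221018,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture()
def gwas_frame():
    """Hand-written 6-SNP association table in canonical form."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(1, 7)],
            "chrom": ["1", "1", "1", "2", "2", "3"],
            "pos": [100, 50_100, 2_100_100, 500, 900_500, 42],
            "effect_allele": list("AACGTA"),
            "other_allele": list("GGTAAC"),
            "eaf": [0.1, 0.2, 0.3, 0.4, 0.25, 0.5],
            "beta": [0.5, -0.3, 0.02, 0.4, -0.02, 0.01],
            "se": [0.05, 0.04, 0.03, 0.05, 0.04, 0.05],
            "pvalue": [1e-23, 6.6e-14, 0.5, 1.3e-15, 0.6, 0.84],
            "n": [1000] * 6,
        }
    )


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture()
def rng():
    return np.random.default_rng(20221018)
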