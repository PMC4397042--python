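import numpy as np
import pandas as pd
import pytest

from modqtl import SimConfig, simulate_dataset
from modqtl.pipeline import analyze


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted-module dataset at seed 1."""
    cfg = SimConfig(seed=1)
    geno, esim, pheno = simulate_dataset(cfg)
    return cfg, geno, esim, pheno


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full pipeline result on the default dataset (computed once)."""
    _, geno, esim, pheno = default_dataset
    return analyze(
        geno.dosage, geno.snp_map, esim.expression, esim.probe_map,
        esim.covariates, pheno,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_covariates(rng, n):
    """Small random covariate table matching the pipeline's layout."""
    return pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], n),
            "sire": rng.choice([f"sire{i}" for i in range(4)], n),
            "ryr1": rng.choice(["NN", "Nn", "nn"], n),
            "weight": rng.normal(95, 10, n),
            "batch": rng.choice([f"day{i}" for i in range(3)], n),
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample"),
    )
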