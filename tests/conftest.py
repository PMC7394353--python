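import numpy as np
import pandas as pd
import pytest

from ribointerplay.config import PipelineConfig
from ribointerplay.synthetic import (
    SimulationParams,
    make_design,
    make_truth,
    simulate_paired_counts,
)


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_sim(design):
    """One paired-count simulation at the default study conditions."""
    params = SimulationParams(seed=3)
    truth = make_truth(params)
    mrna, ribo, mrna_tpm, ribo_tpm = simulate_paired_counts(params, truth, design)
    return {"params": params, "truth": truth, "mrna": mrna, "ribo": ribo,
            "mrna_tpm": mrna_tpm, "ribo_tpm": ribo_tpm}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_counts(rng, n_genes=20, n_samples=4, lam=50.0) -> pd.DataFrame:
    data = rng.poisson(lam, size=(n_genes, n_samples))
    return pd.DataFrame(data,
                        index=pd.Index([f"g{i:03d}" for i in range(n_genes)],
                                       name="gene_id"),
                        columns=[f"s{j}" for j in range(n_samples)])
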