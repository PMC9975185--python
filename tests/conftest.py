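"""Shared fixtures: small synthetic datasets and cached fits."""

import numpy as np
import pytest
import scipy.sparse as sp

from mrci.data import SummaryDataset
from mrci.em import FitConfig
from mrci.params import ModelParams
from mrci.simulate import scenario, simulate_summary_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_params():
    """Admissible full-model parameters at a hand-friendly scale."""
    return ModelParams(
        pi1=0.1,
        pi2=0.2,
        piC=0.3,
        sigma1_sq=0.5,
        sigma2_sq=0.4,
        sigmaC1_sq=0.3,
        sigmaC2_sq=0.2,
        rhoC1C2=0.1,
        delta12=0.1,
        delta21=0.05,
        a1=0.01,
        a2=0.02,
        rho0=0.005,
    )


@pytest.fixture()
def tiny_dataset():
    """Five SNPs, a 3-SNP LD chain plus two isolated SNPs."""
    adj = sp.csr_matrix(
        np.array(
            [
                [1, 1, 1, 0, 0],
                [1, 1, 1, 0, 0],
                [1, 1, 1, 0, 0],
                [0, 0, 0, 1, 0],
                [0, 0, 0, 0, 1],
            ],
            dtype=np.int8,
        )
    )
    return SummaryDataset(
        snp_ids=[f"rs{i}" for i in range(5)],
        tau1=[0.01, -0.005, 0.002, 0.03, 0.0],
        tau2=[0.004, 0.012, -0.001, 0.0, -0.02],
        ld_score=[2.0, 2.5, 2.0, 1.0, 1.0],
        adjacency=adj,
        n1=10_000,
        n2=20_000,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest bi-directional full-model simulation shared across tests."""
    scn = scenario("his-bi", M=4000, block_size=20)
    data, truth = simulate_summary_dataset(scn, seed=7)
    return data, truth


@pytest.fixture(scope="session")
def quick_config():
    return FitConfig(seed=3, max_em_iter=25, cl_tol=0.05, nm_max_eval=80)
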