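import numpy as np
import pytest

from snpnoise import SynConfig, run_qc, simulate

# One fixed master seed for the shared synthetic fixture used across the suite.
FIXTURE_SEED = 123


@pytest.fixture(scope="session")
def syn_config():
    return SynConfig()


@pytest.fixture(scope="session")
def fixture(syn_config):
    """Default synthetic population with rare markers and missingness applied."""
    return simulate(syn_config, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def qc_data(fixture):
    """QC'd genotypes (123 x 175), phenotypes, and the QC report."""
    G, pheno = fixture
    G_qc, report = run_qc(G)
    return G_qc, pheno, report


@pytest.fixture(scope="session")
def Xy(qc_data):
    G_qc, pheno, _ = qc_data
    return G_qc.dosage.astype(float), pheno.label
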