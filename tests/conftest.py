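import warnings

import numpy as np
import pytest

from straindyn.crm import CrmScenario, serial_passage
from straindyn.simulate import (
    DepthModel,
    TruthConfig,
    generate_genes,
    generate_truth,
    observe_snps,
)


@pytest.fixture(scope="session")
def truth_community():
    """One well-powered community: 4 species, 8 time points, driven strain
    frequencies, >=25 differentiating SNPs each."""
    cfg = TruthConfig(
        strain_process="random-walk",
        walk_sd=0.12,
        diff_snp_range=(25, 60),
        shared_snp_range=(20, 40),
    )
    return generate_truth(1, 4, seed=11, config=cfg)[0]


@pytest.fixture(scope="session")
def observed_snps(truth_community):
    """High-depth binomial observations of the truth community's SNPs."""
    return observe_snps(truth_community, DepthModel(mean_depth=150), seed=7)


@pytest.fixture(scope="session")
def gene_fixture():
    return generate_genes(n_genes=30, length_codons=60, seed=3)


@pytest.fixture(scope="session")
def crm_small_results():
    """A reduced strain-specific scenario reused by cheap structural tests."""
    scenario = CrmScenario(n_communities=2, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return serial_passage(scenario)


@pytest.fixture(scope="session")
def crm_discrimination():
    """Full study-scale model discrimination: both hypotheses, 5 seeds each."""
    from straindyn.crm import evaluate_hypotheses

    return evaluate_hypotheses(base_seed=1, n_seeds=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
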