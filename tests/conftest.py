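import warnings

import numpy as np
import pandas as pd
import pytest

from oncoage.synthetic import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort with planted truth (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def signature_run(default_cohort):
    """One full signature-pipeline run on the default cohort."""
    from oncoage.signature import run_signature_pipeline

    cohort, truth = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panel = run_signature_pipeline(cohort)
    return cohort, truth, panel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, n_genes, n_samples, dispersion=0.1, base=None, log2_effects=None):
    """Small NB count matrix helper: mean = 2**(base + effects)."""
    if base is None:
        base = rng.uniform(4, 9, n_genes)
    mu = np.exp2(base[:, None] + (log2_effects if log2_effects is not None else 0.0))
    mu = np.broadcast_to(mu, (n_genes, n_samples)).copy()
    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    return pd.DataFrame(
        rng.poisson(lam),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
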