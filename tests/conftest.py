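import numpy as np
import pytest

from carnitrend import model, synthetic
from carnitrend.covariates import impute_covariates


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset with injected missingness and imputation."""
    cfg = synthetic.SyntheticConfig(
        n_populations=180, n_species=20, n_genera=10, n_countries=15,
        n_subregions=5, frac_qualitative=0.15, seed=101,
    )
    trend, cov, truth = synthetic.generate_dataset(cfg)
    cov_missing = synthetic.inject_missingness(cov, cfg.missing_rate, seed=102)
    cov_imputed = impute_covariates(cov_missing, seed=103)
    return {"config": cfg, "trend": trend, "cov": cov, "cov_missing": cov_missing,
            "cov_imputed": cov_imputed, "truth": truth}


@pytest.fixture(scope="session")
def small_inputs(small_dataset):
    return model.build_design(small_dataset["trend"], small_dataset["cov_imputed"])


@pytest.fixture(scope="session")
def small_fit(small_inputs):
    """A quick posterior fit shared by model/diagnostics/scenario tests."""
    mcmc = model.McmcConfig(n_chains=2, n_iterations=1500, n_burnin=500,
                            thin=2, seed=104)
    return model.sample_posterior(small_inputs, mcmc=mcmc)
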